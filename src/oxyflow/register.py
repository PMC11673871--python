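"""Rigid intensity-based motion correction.

Every frame is aligned to the first frame of the acquisition with a rigid
transform (rotation about the frame center plus translation).  The metric
is normalized cross-correlation; the optimum is found by a coarse sweep
over rotation angles — translation solved at each angle by FFT phase
correlation — followed by local refinement of the angle.  The transform
is estimated on the 826 nm channel (both wavelengths are acquired by the
same camera and move together) and applied to both channels and to the
calibration reference, so tissue/reference ratios stay co-located.

Pixels resampled from outside the frame are filled with 0 and flagged
invalid; they never enter downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation
from skimage.transform import EuclideanTransform, warp

from .io import CalibrationFrame, ReflectanceStack

__all__ = ["RigidTransform", "register_frame", "register_stack"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Rotate by ``rotation_deg`` about the frame center, then shift.

    ``tx`` is the column shift and ``ty`` the row shift, in pixels.
    Applying the transform to a moving image maps it into the fixed
    frame's geometry.
    """

    rotation_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.tx == 0.0 and self.ty == 0.0

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 homogeneous forward map in (x, y) = (col, row) coordinates."""
        H, W = shape
        cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        M = np.array(
            [
                [c, -s, cx + self.tx - (c * cx - s * cy)],
                [s, c, cy + self.ty - (s * cx + c * cy)],
                [0.0, 0.0, 1.0],
            ]
        )
        return M

    def apply(
        self, image: np.ndarray, order: int = 1, valid: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Resample ``image`` under the transform (bilinear by default).

        Returns ``(warped, valid_out)`` where ``valid_out`` is False for
        pixels mapped from outside the source frame or, when a source
        ``valid`` mask is given, from invalid source pixels.
        """
        image = np.asarray(image, dtype=float)
        tform = EuclideanTransform(matrix=self.matrix(image.shape))
        warped = warp(image, tform.inverse, order=order, cval=0.0, preserve_range=True)
        src_ok = np.ones_like(image) if valid is None else valid.astype(float)
        # clip=False: warp's default clipping would snap the partially
        # covered border values of an all-ones image back to 1
        coverage = warp(
            src_ok, tform.inverse, order=order, cval=0.0, preserve_range=True, clip=False
        )
        return warped, coverage > 0.999

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        # p = R^-1 (p' - c0 - t) + c0  =>  rotation -theta, translation -R^-1 t
        tx, ty = self.tx, self.ty
        return RigidTransform(
            rotation_deg=-self.rotation_deg,
            tx=-(c * tx + s * ty),
            ty=-(-s * tx + c * ty),
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        tx = c * other.tx - s * other.ty + self.tx
        ty = s * other.tx + c * other.ty + self.ty
        return RigidTransform(rotation_deg=self.rotation_deg + other.rotation_deg, tx=tx, ty=ty)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _shift_at_angle(
    moving: np.ndarray,
    fixed: np.ndarray,
    angle_deg: float,
    moving_valid: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Best integer translation at a fixed rotation angle, with its NCC score.

    Uses masked phase correlation so that zero-filled wedges — from the
    candidate rotation or from invalid pixels of the moving frame itself —
    cannot anchor the correlation peak.
    """
    rot = RigidTransform(rotation_deg=angle_deg)
    rotated, rot_valid = rot.apply(moving, valid=moving_valid)
    shift, _, _ = phase_cross_correlation(
        fixed,
        rotated,
        reference_mask=np.ones_like(fixed, dtype=bool),
        moving_mask=rot_valid,
    )
    tform = RigidTransform(rotation_deg=angle_deg, tx=float(shift[1]), ty=float(shift[0]))
    aligned, valid = tform.apply(moving, valid=moving_valid)
    return tform, _ncc(aligned, fixed, valid)


def register_frame(
    moving: np.ndarray,
    fixed: np.ndarray,
    max_rotation_deg: float = 5.0,
    coarse_step_deg: float = 1.0,
    refine: bool = True,
    moving_valid: np.ndarray | None = None,
    rotation_center_deg: float = 0.0,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Coarse sweep over rotation angles — the translation at each angle is
    solved to integer precision by masked phase correlation and scored by
    normalized cross-correlation — followed by a joint sub-pixel
    Nelder-Mead refinement of (rotation, tx, ty) on the NCC metric.
    ``moving_valid`` marks trustworthy pixels of the moving frame; invalid
    pixels are excluded from both the shift estimate and the metric.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed frames must share a shape")
    if np.ptp(fixed) == 0:
        raise ValueError("fixed frame has zero variance; cannot register against it")

    angles = rotation_center_deg + np.arange(
        -max_rotation_deg, max_rotation_deg + 1e-9, coarse_step_deg
    )
    best_t, best_score = None, -np.inf
    for ang in angles:
        t, score = _shift_at_angle(moving, fixed, float(ang), moving_valid=moving_valid)
        if score > best_score:
            best_t, best_score = t, score

    tform = best_t
    if refine:

        def neg_ncc(p: np.ndarray) -> float:
            cand = RigidTransform(rotation_deg=float(p[0]), tx=float(p[1]), ty=float(p[2]))
            aligned, valid = cand.apply(moving, valid=moving_valid)
            return -_ncc(aligned, fixed, valid)

        x0 = np.array([best_t.rotation_deg, best_t.tx, best_t.ty])
        simplex = np.vstack([x0, x0 + np.diag([0.5, 0.5, 0.5])])
        res = minimize(
            neg_ncc,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 0.01,
                "fatol": 1e-8,
                "maxiter": 300,
                "initial_simplex": simplex,
            },
        )
        if -res.fun >= best_score:
            tform = RigidTransform(
                rotation_deg=float(res.x[0]), tx=float(res.x[1]), ty=float(res.x[2])
            )

    # snap numerically negligible components to an exact identity
    if abs(tform.rotation_deg) < 5e-3 and abs(tform.tx) < 5e-3 and abs(tform.ty) < 5e-3:
        return RigidTransform()
    return tform


def register_stack(
    stack: ReflectanceStack,
    calibration: CalibrationFrame,
    max_rotation_deg: float = 5.0,
    reference_wavelength_nm: int = 826,
) -> tuple[ReflectanceStack, CalibrationFrame, list[RigidTransform]]:
    """Align every frame to frame 0 and propagate transforms to the reference.

    One transform per time point is estimated on the 826 nm channel and
    applied to both wavelength channels and to the calibration image, so
    that the per-frame tissue/reference intensity ratio stays pinned to
    the same physical location.  A frame that fails to register falls back
    to the identity transform with a warning.
    """
    ref_chan = stack.channel(reference_wavelength_nm)
    fixed = ref_chan[0]
    T, (H, W) = stack.n_frames, stack.frame_shape

    prior_valid = stack.validity()
    transforms: list[RigidTransform] = [RigidTransform()]
    for i in range(1, T):
        try:
            # warm start: motion is smooth frame to frame, so scan a narrow
            # angle band around the previous frame's rotation first
            t = register_frame(
                ref_chan[i],
                fixed,
                max_rotation_deg=min(2.0, max_rotation_deg),
                moving_valid=prior_valid[i],
                rotation_center_deg=transforms[-1].rotation_deg,
            )
            aligned, v = t.apply(ref_chan[i], valid=prior_valid[i])
            if _ncc(aligned, fixed, v) < 0.5:  # warm start failed; full sweep
                t = register_frame(
                    ref_chan[i],
                    fixed,
                    max_rotation_deg=max_rotation_deg,
                    moving_valid=prior_valid[i],
                )
            transforms.append(t)
        except Exception as exc:  # degenerate frame: keep it unwarped
            warnings.warn(f"registration failed for frame {i} ({exc}); using identity")
            transforms.append(RigidTransform())

    frames_out = np.empty_like(np.asarray(stack.frames, dtype=float))
    valid_out = np.ones((T, H, W), dtype=bool)
    cal_static = calibration.images if not calibration.per_frame else calibration.images[:, 0]
    cal_out = np.empty((2, T, H, W), dtype=float)
    for i, t in enumerate(transforms):
        for ch in range(2):
            if t.is_identity:
                frames_out[ch, i] = stack.frames[ch, i]
                cal_out[ch, i] = cal_static[ch]
            else:
                frames_out[ch, i], v = t.apply(stack.frames[ch, i], valid=prior_valid[i])
                cal_out[ch, i], _ = t.apply(cal_static[ch])
                valid_out[i] &= v
        if t.is_identity:
            valid_out[i] &= prior_valid[i]

    registered = ReflectanceStack(
        frames=np.clip(frames_out, 0.0, None),
        timestamps_s=stack.timestamps_s,
        wavelengths_nm=stack.wavelengths_nm,
        valid=valid_out,
        meta={**stack.meta, "registered": True},
    )
    logger.info("registered %d frames; %d non-identity transforms", T, sum(not t.is_identity for t in transforms))
    return registered, CalibrationFrame(images=cal_out), transforms
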