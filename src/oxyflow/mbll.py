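"""Modified Beer-Lambert law (mBLL) tissue oximetry.

Dual-wavelength diffuse reflectance is converted to attenuation against a
uniformly diffusing calibration sheet,

    dOD(lambda, x, y, t) = log10( I_cal(lambda, x, y) / I(lambda, x, y, t) ),

and the 2x2 extinction system is inverted per pixel and frame to give
effective oxy- (HbO) and deoxy- (HbR) hemoglobin concentrations:

    [dOD_682, dOD_826]^T = E . [HbO, HbR]^T,   E_ij = eps_j(lambda_i) * L,

with the differential pathlength x geometry factor L fixed at 1: only
percent changes and correlations are consumed downstream, and both are
invariant to that global scale.  Total hemoglobin is HbT = HbO + HbR and
oxygen saturation StO2 = HbO / HbT, guarded against near-zero HbT.

Using the calibration sheet (rather than the first tissue frame) as the
attenuation reference makes the recovered HbO/HbR behave like positive
absolute-style effective concentrations, so the saturation ratio is
well-defined; temporal "delta" profiles are taken later relative to
breath-hold onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import WAVELENGTHS_NM, CalibrationFrame, ReflectanceStack

__all__ = [
    "ExtinctionMatrix",
    "HemodynamicMaps",
    "attenuation",
    "invert_mbll",
    "compute_hemodynamics",
    "STO2_HBT_GUARD",
]

#: |HbT| below this (effective a.u.) makes StO2 undefined rather than clipped.
STO2_HBT_GUARD = 1e-6


@dataclass(frozen=True)
class ExtinctionMatrix:
    """Molar extinction coefficients for (HbO, HbR) at (682, 826) nm.

    Rows follow the wavelength order (682, 826); columns are (HbO, HbR).
    Default values are compiled-hemoglobin-spectra numbers in cm^-1 M^-1;
    they are configuration, not physics baked into the code — any
    well-conditioned invertible pair yields identical downstream percent
    changes and correlations.
    """

    eps_hbo: tuple[float, float] = (320.0, 900.0)
    eps_hbr: tuple[float, float] = (2180.0, 720.0)
    wavelengths_nm: tuple[int, int] = WAVELENGTHS_NM

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.eps_hbo[0], self.eps_hbr[0]],
                [self.eps_hbo[1], self.eps_hbr[1]],
            ],
            dtype=float,
        )

    @property
    def inverse(self) -> np.ndarray:
        E = self.matrix
        det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
        if not np.isfinite(det) or det == 0.0:
            raise ValueError("extinction matrix is singular; cannot invert the mBLL system")
        return np.array([[E[1, 1], -E[0, 1]], [-E[1, 0], E[0, 0]]]) / det

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": list(self.wavelengths_nm),
            "eps_hbo": list(self.eps_hbo),
            "eps_hbr": list(self.eps_hbr),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtinctionMatrix":
        return cls(
            eps_hbo=tuple(float(x) for x in d["eps_hbo"]),
            eps_hbr=tuple(float(x) for x in d["eps_hbr"]),
            wavelengths_nm=tuple(int(x) for x in d.get("wavelengths_nm", WAVELENGTHS_NM)),
        )


@dataclass
class HemodynamicMaps:
    """Per-pixel time series of effective hemoglobin parameters.

    ``hbo``, ``hbr``, ``hbt`` are (T, H, W) in effective arbitrary units;
    ``sto2`` is the dimensionless oxyhemoglobin fraction.  ``valid`` marks
    pixels/frames where the inversion is trustworthy; ``sto2_valid``
    additionally excludes pixels where |HbT| falls below the guard.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    hbt: np.ndarray
    sto2: np.ndarray
    valid: np.ndarray
    sto2_valid: np.ndarray
    timestamps_s: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.hbo.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.hbo.shape[1], self.hbo.shape[2]

    def parameter(self, name: str) -> np.ndarray:
        if name not in ("hbo", "hbr", "hbt", "sto2"):
            raise ValueError(f"unknown hemoglobin parameter {name!r}")
        return getattr(self, name)

    def parameter_valid(self, name: str) -> np.ndarray:
        return self.sto2_valid if name == "sto2" else self.valid


def attenuation(stack: ReflectanceStack, calibration: CalibrationFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength attenuation dOD = log10(I_cal / I), shape (2, T, H, W).

    Pixels where either the tissue intensity or the reference is
    non-positive are marked invalid (returned mask, shape (T, H, W)) and
    carry dOD = 0 so that downstream masking decides, not NaNs.
    """
    frames = np.asarray(stack.frames, dtype=float)
    cal = calibration.images
    if calibration.per_frame:
        if cal.shape[1:] != frames.shape[1:]:
            raise ValueError("per-frame calibration shape does not match the stack")
        ref = cal
    else:
        if cal.shape[1:] != frames.shape[2:]:
            raise ValueError("calibration frame shape does not match the stack")
        ref = cal[:, None, :, :]
    if not np.any(ref > 0):
        raise ValueError("calibration reference is non-positive everywhere")
    valid = (frames > 0).all(axis=0) & (np.broadcast_to(ref > 0, frames.shape)).all(axis=0)
    valid &= stack.validity()
    dod = np.zeros_like(frames)
    np.divide(ref, frames, out=dod, where=valid[None])
    np.log10(dod, out=dod, where=valid[None])
    dod[:, ~valid] = 0.0
    return dod, valid


def invert_mbll(
    dod: np.ndarray,
    extinction: ExtinctionMatrix,
    valid: np.ndarray | None = None,
    timestamps_s: np.ndarray | None = None,
    saturation_index: str = "ratio",
) -> HemodynamicMaps:
    """Solve the 2x2 mBLL system per pixel/frame and derive HbT and StO2.

    ``saturation_index`` selects the oxygenation index stored in ``sto2``:
    ``"ratio"`` (default) is the saturation fraction HbO/HbT, guarded
    against near-zero HbT; ``"difference"`` is the oxy-deoxy balance
    HbO - HbR, an alternative index that needs no guard.
    """
    dod = np.asarray(dod, dtype=float)
    if dod.ndim != 4 or dod.shape[0] != 2:
        raise ValueError(f"dOD must have shape (2, T, H, W), got {dod.shape}")
    if saturation_index not in ("ratio", "difference"):
        raise ValueError(f"saturation_index must be 'ratio' or 'difference', got {saturation_index!r}")
    Einv = extinction.inverse
    # (2, T, H, W) -> (2, T, H, W): c_k = sum_l Einv[k, l] * dOD_l
    conc = np.einsum("kl,lthw->kthw", Einv, dod)
    hbo, hbr = conc[0], conc[1]
    hbt = hbo + hbr
    if valid is None:
        valid = np.ones(hbo.shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool).copy()
    if saturation_index == "ratio":
        sto2_valid = valid & (np.abs(hbt) >= STO2_HBT_GUARD)
        sto2 = np.zeros_like(hbt)
        np.divide(hbo, hbt, out=sto2, where=sto2_valid)
    else:
        sto2_valid = valid.copy()
        sto2 = hbo - hbr
    if timestamps_s is None:
        timestamps_s = np.arange(hbo.shape[0], dtype=float)
    return HemodynamicMaps(
        hbo=hbo,
        hbr=hbr,
        hbt=hbt,
        sto2=sto2,
        valid=valid,
        sto2_valid=sto2_valid,
        timestamps_s=np.asarray(timestamps_s, dtype=float),
        meta={"extinction": extinction.to_dict(), "saturation_index": saturation_index},
    )


def compute_hemodynamics(
    stack: ReflectanceStack,
    calibration: CalibrationFrame,
    extinction: ExtinctionMatrix | None = None,
    saturation_index: str = "ratio",
) -> HemodynamicMaps:
    """Attenuation + inversion in one step (the pipeline's oximetry stage)."""
    extinction = extinction or ExtinctionMatrix()
    dod, valid = attenuation(stack, calibration)
    return invert_mbll(
        dod,
        extinction,
        valid=valid,
        timestamps_s=stack.timestamps_s,
        saturation_index=saturation_index,
    )
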