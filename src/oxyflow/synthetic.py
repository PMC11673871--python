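"""Synthetic dual-wavelength reflectance scenes with a programmable breath-hold response.

The generator is the pipeline's test bed: no subject imaging data is
distributable, so every stage is exercised against scenes whose ground
truth is known exactly.  A scene is a set of disjoint tissue regions on a
foot-shaped mask, each with its own breath-hold hemodynamic response,
static melanin attenuation, and sensor noise level, plus optional
fiducial-marker squares and per-frame rigid motion.

The forward model inverts the pipeline's oximetry stage: per pixel,

    I(lambda, t) = I_cal(lambda) * melanin * 10^-(eps_HbO(lambda) * HbO(t)
                                                 + eps_HbR(lambda) * HbR(t))

with multiplicative Gaussian noise on the effective concentrations (drawn
per pixel and frame, shared across wavelengths, so the rendered channels
stay physically consistent).  Running the modified Beer-Lambert inversion
on a noise-free, motion-free rendering recovers the programmed
concentration series to floating-point accuracy.

The default response emulates the breath-hold physiology this pipeline
measures: deoxyhemoglobin rises during the 20 s hold (peripheral
vasoconstriction), then oxyhemoglobin overshoots and deoxyhemoglobin
undershoots during the hyperemic recovery, settling to a new baseline
about 2 % above (HbO) / 2.5 % below (HbR) the hold-onset level around the
100th second.  Wound-like tissue delays this response by tens of seconds;
non-healing tissue inverts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    WAVELENGTHS_NM,
    CalibrationFrame,
    Paradigm,
    ReflectanceStack,
    RoiMask,
    dump_yaml,
    write_calibration,
    write_mask,
    write_stack,
)
from .mbll import ExtinctionMatrix
from .register import RigidTransform

__all__ = [
    "BreathHoldResponseSpec",
    "Region",
    "SceneSpec",
    "simulate_response",
    "render_stack",
    "control_response",
    "delayed",
    "inverted",
    "control_scene",
    "split_scene",
    "wound_scene",
    "scene_from_config",
    "write_scene_bundle",
]

#: Calibration-sheet intensity (arbitrary camera units).
CAL_INTENSITY = 10000.0
#: Non-tissue background reflectance relative to the calibration sheet.
BACKGROUND_REFLECTANCE = 0.05
#: Fiducial squares render near zero.
FIDUCIAL_REFLECTANCE = 1e-3


@dataclass(frozen=True)
class BreathHoldResponseSpec:
    """Programmable breath-hold hemodynamic response of one tissue region.

    Baselines are effective concentrations (arbitrary units) against the
    white calibration sheet and must be positive.  Fractional parameters
    express the hold-phase HbR rise and the recovery-phase HbO overshoot /
    HbR undershoot relative to baseline.  ``response_delay_s`` shifts the
    whole response (0 for control-like tissue; tens of seconds for
    wound-like tissue whose recovery lands at 80-100 s instead of
    60-80 s).  ``plateau_time_s`` is when the new baseline is reached.
    ``noise_sd`` is the multiplicative sensor-noise sd applied at render
    time; the concentration curves themselves are deterministic.
    """

    baseline_hbo: float = 2.0e-4
    baseline_hbr: float = 1.0e-4
    hold_hbr_rise: float = 0.02
    recovery_hbo_overshoot: float = 0.02
    recovery_hbr_undershoot: float = 0.025
    response_delay_s: float = 0.0
    plateau_time_s: float = 100.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hbo <= 0 or self.baseline_hbr <= 0:
            raise ValueError("baseline concentrations must be positive")
        if self.response_delay_s < 0:
            raise ValueError("response_delay_s must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def control_response(noise_sd: float = 0.01, seed: int = 0, **overrides) -> BreathHoldResponseSpec:
    """Control-like response: no delay, ~2 % recovery changes, 100 s plateau."""
    return BreathHoldResponseSpec(noise_sd=noise_sd, seed=seed, **overrides)


def delayed(spec: BreathHoldResponseSpec, delay_s: float) -> BreathHoldResponseSpec:
    """Same response shifted later in time (wound-like delayed recovery)."""
    return replace(spec, response_delay_s=spec.response_delay_s + delay_s)


def inverted(spec: BreathHoldResponseSpec) -> BreathHoldResponseSpec:
    """Sign-flipped response (asynchronous, non-healing-like tissue)."""
    return replace(
        spec,
        hold_hbr_rise=-spec.hold_hbr_rise,
        recovery_hbo_overshoot=-spec.recovery_hbo_overshoot,
        recovery_hbr_undershoot=-spec.recovery_hbr_undershoot,
    )


def simulate_response(
    spec: BreathHoldResponseSpec, paradigm: Paradigm
) -> tuple[np.ndarray, np.ndarray]:
    """Clean (HbO(t), HbR(t)) series, one sample per acquisition frame.

    HbR ramps linearly during the (possibly delayed) hold; after hold
    cessation both parameters approach their recovery targets
    exponentially and hold them exactly from ``plateau_time_s`` on.
    Deterministic: sensor noise enters only at rendering.
    """
    t = paradigm.timestamps()
    hold_start = paradigm.onset_s + spec.response_delay_s
    hold_end = hold_start + paradigm.hold_s
    plateau = spec.plateau_time_s + spec.response_delay_s
    if hold_end >= paradigm.total_s:
        warnings.warn(
            f"response delay {spec.response_delay_s} s pushes the response past the "
            f"{paradigm.total_s:.0f} s acquisition; it will be truncated"
        )
    plateau = max(plateau, hold_end + 1.0 / paradigm.sampling_hz)

    hbo = np.full_like(t, spec.baseline_hbo)
    hbr = np.full_like(t, spec.baseline_hbr)

    in_hold = (t > hold_start) & (t <= hold_end)
    frac = (t[in_hold] - hold_start) / paradigm.hold_s
    hbr[in_hold] = spec.baseline_hbr * (1.0 + spec.hold_hbr_rise * frac)

    after = t > hold_end
    tau = (plateau - hold_end) / 4.0
    decay = np.exp(-(t[after] - hold_end) / tau)
    hbo_target = spec.baseline_hbo * (1.0 + spec.recovery_hbo_overshoot)
    hbr_peak = spec.baseline_hbr * (1.0 + spec.hold_hbr_rise)
    hbr_target = spec.baseline_hbr * (1.0 - spec.recovery_hbr_undershoot)
    hbo[after] = hbo_target + (spec.baseline_hbo - hbo_target) * decay
    hbr[after] = hbr_target + (hbr_peak - hbr_target) * decay

    at_plateau = t >= plateau
    hbo[at_plateau] = hbo_target
    hbr[at_plateau] = hbr_target
    return hbo, hbr


@dataclass
class Region:
    """One tissue region: a mask, a response, and a melanin factor."""

    label: str
    mask: np.ndarray
    response: BreathHoldResponseSpec
    melanin_factor: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0.0 < self.melanin_factor <= 1.0):
            raise ValueError(
                f"melanin_factor must lie in (0, 1], got {self.melanin_factor} for {self.label!r}"
            )


@dataclass
class SceneSpec:
    """Full description of a synthetic acquisition."""

    height: int
    width: int
    regions: list[Region]
    paradigm: Paradigm = field(default_factory=Paradigm)
    fiducials: list[tuple[tuple[int, int], int]] = field(default_factory=list)
    motion: list[RigidTransform] | None = None

    def __post_init__(self) -> None:
        occupancy = np.zeros((self.height, self.width), dtype=int)
        for reg in self.regions:
            if reg.mask.shape != (self.height, self.width):
                raise ValueError(f"region {reg.label!r} mask shape does not match the scene")
            occupancy += reg.mask
        if np.any(occupancy > 1):
            raise ValueError("region masks must be disjoint")
        if self.motion is not None and len(self.motion) != self.paradigm.n_frames:
            raise ValueError("motion must supply one rigid transform per frame")

    @property
    def foot_mask(self) -> np.ndarray:
        m = np.zeros((self.height, self.width), dtype=bool)
        for reg in self.regions:
            m |= reg.mask
        return m

    def fiducial_mask(self) -> np.ndarray:
        m = np.zeros((self.height, self.width), dtype=bool)
        for (r0, c0), size in self.fiducials:
            m[r0 : r0 + size, c0 : c0 + size] = True
        return m


def render_stack(
    scene: SceneSpec,
    optics: ExtinctionMatrix | None = None,
    seed: int | None = None,
) -> tuple[ReflectanceStack, CalibrationFrame, dict[str, RoiMask], pd.DataFrame]:
    """Render a scene into a dual-wavelength reflectance stack.

    Returns the stack, the (uniform) calibration frame, the mask bundle
    (foot, fiducial, one mask per region), and the sidecar ground truth:
    a tidy frame of the clean programmed concentration series
    (t_s, region, hbo_eff, hbr_eff) so tests never re-derive it.
    """
    optics = optics or ExtinctionMatrix()
    E = optics.matrix  # rows = wavelengths, cols = (HbO, HbR)
    paradigm = scene.paradigm
    T = paradigm.n_frames
    H, W = scene.height, scene.width
    rng = np.random.default_rng(None if seed is None else seed)

    frames = np.full((2, T, H, W), CAL_INTENSITY * BACKGROUND_REFLECTANCE, dtype=float)
    truth_rows = []
    for reg in scene.regions:
        hbo, hbr = simulate_response(reg.response, paradigm)
        n_px = int(reg.mask.sum())
        sd = reg.response.noise_sd
        # noise is multiplicative on the effective hemodynamic signal and
        # shared across wavelengths: each pixel carries one noisy
        # concentration pair per frame, rendered consistently at 682 and
        # 826 nm, so the mBLL inversion sees physiological-scale noise
        hbo_px = np.repeat(hbo[:, None], n_px, axis=1)
        hbr_px = np.repeat(hbr[:, None], n_px, axis=1)
        if sd > 0:
            hbo_px = hbo_px * (1.0 + sd * rng.standard_normal((T, n_px)))
            hbr_px = hbr_px * (1.0 + sd * rng.standard_normal((T, n_px)))
        for ch in range(2):
            od = E[ch, 0] * hbo_px + E[ch, 1] * hbr_px  # (T, n_px)
            frames[ch][:, reg.mask] = CAL_INTENSITY * reg.melanin_factor * 10.0 ** (-od)
        truth_rows.append(
            pd.DataFrame(
                {
                    "t_s": paradigm.timestamps(),
                    "region": reg.label,
                    "hbo_eff": hbo,
                    "hbr_eff": hbr,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else pd.DataFrame(
        columns=["t_s", "region", "hbo_eff", "hbr_eff"]
    )

    fid = scene.fiducial_mask()
    if fid.any():
        frames[:, :, fid] = CAL_INTENSITY * FIDUCIAL_REFLECTANCE

    valid = None
    if scene.motion is not None:
        valid = np.ones((T, H, W), dtype=bool)
        for i, tform in enumerate(scene.motion):
            if tform.is_identity:
                continue
            for ch in range(2):
                frames[ch, i], v = tform.apply(frames[ch, i])
            valid[i] = v

    np.clip(frames, 0.0, None, out=frames)
    stack = ReflectanceStack(
        frames=frames,
        timestamps_s=paradigm.timestamps(),
        valid=valid,
        meta={"synthetic": True, "seed": seed},
    )
    calibration = CalibrationFrame(images=np.full((2, H, W), CAL_INTENSITY, dtype=float))
    masks = {"foot": RoiMask(scene.foot_mask, "foot"), "fiducial": RoiMask(fid, "fiducial")}
    for reg in scene.regions:
        masks[reg.label] = RoiMask(reg.mask, reg.label)
    return stack, calibration, masks, truth


# ---------------------------------------------------------------------------
# Scene factories
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], margin_frac: float = 0.15) -> np.ndarray:
    H, W = shape
    r = np.arange(H)[:, None]
    c = np.arange(W)[None, :]
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    ar, ac = (0.5 - margin_frac) * H, (0.5 - margin_frac) * W
    return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0


def _default_fiducials(shape: tuple[int, int]) -> list[tuple[tuple[int, int], int]]:
    H, W = shape
    size = max(3, H // 20)
    return [((2, 2), size), ((2, W - size - 2), size)]


def control_scene(
    shape: tuple[int, int] = (128, 128),
    paradigm: Paradigm | None = None,
    noise_sd: float = 0.01,
    melanin_factor: float = 1.0,
    response: BreathHoldResponseSpec | None = None,
    motion: list[RigidTransform] | None = None,
) -> SceneSpec:
    """Healthy-foot scene: one synchronous tissue region over the whole foot."""
    paradigm = paradigm or Paradigm()
    response = response or control_response(noise_sd=noise_sd)
    foot = _ellipse_mask(shape)
    return SceneSpec(
        height=shape[0],
        width=shape[1],
        regions=[Region("foot", foot, response, melanin_factor)],
        paradigm=paradigm,
        fiducials=_default_fiducials(shape),
        motion=motion,
    )


def split_scene(
    shape: tuple[int, int] = (128, 128),
    paradigm: Paradigm | None = None,
    noise_sd: float = 0.01,
    melanin_factors: tuple[float, float] = (1.0, 0.4),
    responses: tuple[BreathHoldResponseSpec, BreathHoldResponseSpec] | None = None,
    motion: list[RigidTransform] | None = None,
) -> SceneSpec:
    """Foot split into two background halves (B1 left, B2 right).

    With identical responses and differing melanin factors this is the
    skin-pigmentation scenario: a static attenuation difference that the
    temporal analysis must cancel.
    """
    paradigm = paradigm or Paradigm()
    if responses is None:
        base = control_response(noise_sd=noise_sd)
        responses = (base, replace(base, seed=1))
    foot = _ellipse_mask(shape)
    left = foot.copy()
    left[:, shape[1] // 2 :] = False
    right = foot & ~left
    return SceneSpec(
        height=shape[0],
        width=shape[1],
        regions=[
            Region("B1", left, responses[0], melanin_factors[0]),
            Region("B2", right, responses[1], melanin_factors[1]),
        ],
        paradigm=paradigm,
        fiducials=_default_fiducials(shape),
        motion=motion,
    )


def wound_scene(
    shape: tuple[int, int] = (128, 128),
    paradigm: Paradigm | None = None,
    noise_sd: float = 0.01,
    wound_delay_s: float = 20.0,
    wound_inverted: bool = False,
    wound_area_frac: float = 0.3,
    melanin_factor: float = 1.0,
    motion: list[RigidTransform] | None = None,
) -> SceneSpec:
    """Foot with a circular wound region whose response is delayed and/or inverted.

    ``wound_area_frac`` is the wound's share of the foot area (default 30 %).
    """
    paradigm = paradigm or Paradigm()
    foot = _ellipse_mask(shape)
    base = control_response(noise_sd=noise_sd)
    wspec = delayed(base, wound_delay_s) if wound_delay_s else base
    if wound_inverted:
        wspec = inverted(wspec)
    wspec = replace(wspec, seed=7)

    H, W = shape
    r = np.arange(H)[:, None]
    c = np.arange(W)[None, :]
    target = wound_area_frac * foot.sum()
    radius = np.sqrt(target / np.pi)
    # wound sits off-center toward the distal (top) end of the foot
    wr, wc = int(0.40 * H), int(0.45 * W)
    wound = (((r - wr) ** 2 + (c - wc) ** 2) <= radius**2) & foot
    background = foot & ~wound
    return SceneSpec(
        height=H,
        width=W,
        regions=[
            Region("background", background, base, melanin_factor),
            Region("wound", wound, wspec, melanin_factor),
        ],
        paradigm=paradigm,
        fiducials=_default_fiducials(shape),
        motion=motion,
    )


def scene_from_config(cfg: dict) -> SceneSpec:
    """Build a scene from a small YAML/JSON-friendly config.

    ``kind`` selects the factory (control | split | wound); the remaining
    keys are that factory's keyword arguments, with ``paradigm`` given as
    a mapping.
    """
    cfg = dict(cfg)
    kind = cfg.pop("kind", "control")
    if "paradigm" in cfg and isinstance(cfg["paradigm"], dict):
        cfg["paradigm"] = Paradigm.from_dict(cfg["paradigm"])
    if "shape" in cfg:
        cfg["shape"] = tuple(int(x) for x in cfg["shape"])
    if "melanin_factors" in cfg:
        cfg["melanin_factors"] = tuple(float(x) for x in cfg["melanin_factors"])
    factories = {"control": control_scene, "split": split_scene, "wound": wound_scene}
    if kind not in factories:
        raise ValueError(f"unknown scene kind {kind!r}; expected one of {sorted(factories)}")
    return factories[kind](**cfg)


def write_scene_bundle(
    outdir: str | Path,
    scene: SceneSpec,
    optics: ExtinctionMatrix | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Render a scene and write the full on-disk bundle.

    Stack TIFFs (one per wavelength), calibration TIFFs, 8-bit masks,
    the ground-truth CSV sidecar, and the scene config (when given).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, calibration, masks, truth = render_stack(scene, optics=optics, seed=seed)
    paths: dict[str, Path] = {}
    stack_paths = {wl: outdir / f"stack_{wl}nm.tif" for wl in WAVELENGTHS_NM}
    write_stack(stack, stack_paths)
    paths.update({f"stack_{wl}": p for wl, p in stack_paths.items()})
    cal_paths = {wl: outdir / f"calibration_{wl}nm.tif" for wl in WAVELENGTHS_NM}
    write_calibration(calibration, cal_paths)
    paths.update({f"calibration_{wl}": p for wl, p in cal_paths.items()})
    for label, roi in masks.items():
        p = outdir / f"mask_{label}.png"
        write_mask(roi, p)
        paths[f"mask_{label}"] = p
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path
    if config is not None:
        cfg_path = outdir / "scene.yaml"
        dump_yaml({**config, "seed": seed}, cfg_path)
        paths["config"] = cfg_path
    return paths
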