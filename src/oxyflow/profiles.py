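"""ROI concentration profiles: smoothing, averaging, onset normalization.

A pixel's hemoglobin time series is smoothed with a Savitzky-Golay filter
(polynomial least-squares in a sliding window — preserves trend shape while
suppressing frame-to-frame sensor noise), averaged over a region of
interest, and expressed as the percent change from breath-hold onset:

    profile(t) = 100 * (S(t) - S(t0)) / |S(t0)|,   t >= t0 = rest_s,

so 0 % at onset by construction.  Grand averages pool profiles across
subjects and repetitions with a pointwise mean and standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .io import Paradigm, RoiMask
from .mbll import HemodynamicMaps

__all__ = [
    "ConcentrationProfile",
    "smooth_pixelwise",
    "roi_profile",
    "normalize_at_onset",
    "grand_average",
]

PARAMETERS = ("hbo", "hbr", "hbt", "sto2")


@dataclass
class ConcentrationProfile:
    """Scalar hemoglobin time series averaged over one ROI."""

    values: np.ndarray
    timestamps_s: np.ndarray
    parameter: str
    roi_label: str = ""
    normalized: bool = False
    t0_s: float | None = None
    n_pixels_per_frame: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.values.shape != self.timestamps_s.shape:
            raise ValueError("values and timestamps must have equal length")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"parameter must be one of {PARAMETERS}, got {self.parameter!r}")

    def __len__(self) -> int:
        return self.values.size


def smooth_pixelwise(maps: HemodynamicMaps, window: int = 11, polyorder: int = 3) -> HemodynamicMaps:
    """Savitzky-Golay filter each pixel's time series (all four parameters).

    ``window`` must be odd, larger than ``polyorder`` and no longer than
    the series.  Edges use the standard polynomial-fit handling rather
    than truncation.  HbT is recomputed from the filtered HbO and HbR so
    the HbT = HbO + HbR identity is exact after filtering (the filter is
    linear, so this equals filtering HbT directly up to rounding).
    Validity masks are unchanged.
    """
    T = maps.n_frames
    if window % 2 == 0:
        raise ValueError(f"Savitzky-Golay window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > T:
        raise ValueError(f"window ({window}) exceeds series length ({T})")

    def sg(a: np.ndarray) -> np.ndarray:
        return savgol_filter(a, window_length=window, polyorder=polyorder, axis=0, mode="interp")

    hbo = sg(maps.hbo)
    hbr = sg(maps.hbr)
    return HemodynamicMaps(
        hbo=hbo,
        hbr=hbr,
        hbt=hbo + hbr,
        sto2=sg(maps.sto2),
        valid=maps.valid,
        sto2_valid=maps.sto2_valid,
        timestamps_s=maps.timestamps_s,
        meta={**maps.meta, "savgol": {"window": window, "polyorder": polyorder}},
    )


def roi_profile(maps: HemodynamicMaps, roi: RoiMask, parameter: str) -> ConcentrationProfile:
    """Per-frame mean of one hemoglobin parameter over the valid ROI pixels."""
    data = maps.parameter(parameter)
    valid = maps.parameter_valid(parameter)
    if roi.mask.shape != maps.frame_shape:
        raise ValueError("ROI shape does not match the maps")
    sel = valid[:, roi.mask]  # (T, n_roi)
    counts = sel.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError(
            f"ROI {roi.label!r} has no valid pixels in {int((counts == 0).sum())} frame(s)"
        )
    vals = data[:, roi.mask]
    profile = np.where(sel, vals, 0.0).sum(axis=1) / counts
    return ConcentrationProfile(
        values=profile,
        timestamps_s=maps.timestamps_s,
        parameter=parameter,
        roi_label=roi.label,
        n_pixels_per_frame=counts,
    )


def normalize_at_onset(profile: ConcentrationProfile, paradigm: Paradigm) -> ConcentrationProfile:
    """Percent change from breath-hold onset, keeping t >= t0 only.

    The onset sample S(t0) at t0 = rest_s anchors the profile:
    output(t) = 100 * (S(t) - S(t0)) / |S(t0)|.  The absolute value in
    the denominator keeps the sign convention stable for negative
    effective values.  A zero onset value is a normalization error.
    """
    t0 = paradigm.onset_s
    if profile.normalized:
        if profile.t0_s == t0:
            return replace(profile, values=profile.values.copy())
        raise ValueError(
            f"profile already normalized at t0={profile.t0_s} s; cannot re-normalize at {t0} s"
        )
    idx0 = int(np.flatnonzero(np.isclose(profile.timestamps_s, t0))[0]) if np.any(
        np.isclose(profile.timestamps_s, t0)
    ) else paradigm.frame_index(t0)
    if not (0 <= idx0 < len(profile)):
        raise ValueError(f"onset t0={t0} s outside the profile")
    s0 = profile.values[idx0]
    if s0 == 0:
        raise ValueError(f"profile {profile.roi_label!r} is exactly 0 at onset; cannot normalize")
    keep = slice(idx0, None)
    values = 100.0 * (profile.values[keep] - s0) / abs(s0)
    return ConcentrationProfile(
        values=values,
        timestamps_s=profile.timestamps_s[keep],
        parameter=profile.parameter,
        roi_label=profile.roi_label,
        normalized=True,
        t0_s=t0,
        n_pixels_per_frame=None
        if profile.n_pixels_per_frame is None
        else profile.n_pixels_per_frame[keep],
        meta=dict(profile.meta),
    )


def grand_average(
    profiles: list[ConcentrationProfile],
) -> tuple[ConcentrationProfile, ConcentrationProfile]:
    """Pointwise mean and standard error (sd/sqrt(n), sample sd) across profiles.

    The "average of averages" across subjects and repetitions.  All
    profiles must share the parameter and length.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    params = {p.parameter for p in profiles}
    if len(params) > 1:
        raise ValueError(f"cannot average mixed parameters: {sorted(params)}")
    lengths = {len(p) for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have mixed lengths: {sorted(lengths)}")
    arr = np.stack([p.values for p in profiles])
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    template = profiles[0]
    mk = lambda vals, label: ConcentrationProfile(
        values=vals,
        timestamps_s=template.timestamps_s,
        parameter=template.parameter,
        roi_label=label,
        normalized=template.normalized,
        t0_s=template.t0_s,
        meta={"n_profiles": n},
    )
    return mk(mean, "grand_average"), mk(se, "standard_error")
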