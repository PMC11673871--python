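"""Pixel-wise oxygenation-flow correlation maps.

Each foot pixel's StO2 time series is compared against a reference signal
with the zero-lag Pearson correlation coefficient

    PCC = sum_i (X_i - Xbar)(Y_i - Ybar)
          / sqrt( sum_i (X_i - Xbar)^2 * sum_i (Y_i - Ybar)^2 ),

evaluated over the analysis window that brackets the breath-hold response:
by default the 20 s hold plus the first 20 s of recovery (frames at
t = 41..80 s for the 40/20/60 s paradigm at 1 Hz, n = 40).  The reference
is the whole-foot mean StO2 for healthy feet, or a user-chosen background
ROI away from the wound for wound cases.  The resulting map lies in
[-1, +1]: +1 synchronous oxygenated flow, -1 asynchronous.

PCC is invariant to affine rescaling of either series, so the map is the
same whether computed on raw, onset-normalized, or pathlength-scaled StO2;
it is computed here on the smoothed, unnormalized series, which avoids
onset-division failures.  Zero-variance pixels are marked invalid (NaN)
rather than set to 0 — a 0 would bias the synchrony index toward
"uncorrelated".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Paradigm, RoiMask
from .mbll import HemodynamicMaps
from .profiles import ConcentrationProfile

__all__ = [
    "ReferenceSignal",
    "CorrelationMap",
    "pearson",
    "default_correlation_window",
    "build_reference",
    "correlation_map",
    "pairwise_roi_correlations",
]


def default_correlation_window(paradigm: Paradigm) -> tuple[float, float]:
    """Analysis window (start_s, end_s), inclusive of both endpoints.

    Covers the hold phase plus an equally long slice of early recovery:
    frames with rest_s < t <= rest_s + 2*hold_s.  For the default
    40/20/60 s paradigm at 1 Hz this is t = 41..80 s, 40 frames.
    """
    start = paradigm.rest_s + 1.0 / paradigm.sampling_hz
    end = paradigm.rest_s + 2.0 * paradigm.hold_s
    return start, end


def _window_slice(timestamps_s: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    idx = np.flatnonzero((timestamps_s >= start - 1e-9) & (timestamps_s <= end + 1e-9))
    if idx.size < 3:
        raise ValueError(
            f"analysis window {window} covers only {idx.size} frame(s); need at least 3"
        )
    return idx


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag Pearson correlation coefficient of two equal-length series.

    Returns NaN (the invalid marker) if either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    r = float((xc * yc).sum() / denom)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class ReferenceSignal:
    """The comparator time series for the correlation map."""

    values: np.ndarray
    timestamps_s: np.ndarray
    source: str  # "global_mean" or "roi:<label>"
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference signal must be finite")
        if np.ptp(self.values) == 0:
            raise ValueError("reference signal has zero variance over the window")


@dataclass
class CorrelationMap:
    """2D Pearson-coefficient field against a declared reference."""

    pcc: np.ndarray
    reference: ReferenceSignal
    window: tuple[float, float]
    parameter: str = "sto2"
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.pcc)

    def valid_values(self) -> np.ndarray:
        return self.pcc[self.valid]


def build_reference(
    maps: HemodynamicMaps,
    mode: str = "global_mean",
    foot_mask: RoiMask | None = None,
    roi: RoiMask | None = None,
    window: tuple[float, float] | None = None,
    paradigm: Paradigm | None = None,
) -> ReferenceSignal:
    """Reference StO2 series: whole-foot mean or a background-ROI mean.

    ``mode="global_mean"`` (healthy feet) averages over ``foot_mask``;
    ``mode="roi"`` (wound cases) averages over the supplied background
    ROI, which the caller must choose away from the wound — it is never
    auto-selected.  The series is restricted to the analysis window.
    """
    if window is None:
        if paradigm is None:
            raise ValueError("supply either a window or a paradigm to derive it from")
        window = default_correlation_window(paradigm)
    if mode == "global_mean":
        if foot_mask is None:
            raise ValueError("global_mean reference requires a foot mask")
        pixels, src = foot_mask, "global_mean"
    elif mode == "roi":
        if roi is None:
            raise ValueError("roi reference requires a background ROI (chosen away from the wound)")
        pixels, src = roi, f"roi:{roi.label}"
        rr, cc = np.nonzero(roi.mask)
        centroid = (float(rr.mean()), float(cc.mean())) if rr.size else (np.nan, np.nan)
    else:
        raise ValueError(f"unknown reference mode {mode!r}")

    idx = _window_slice(maps.timestamps_s, window)
    valid = maps.sto2_valid[idx][:, pixels.mask]
    counts = valid.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("reference pixel set has no valid pixels in some window frames")
    vals = maps.sto2[idx][:, pixels.mask]
    series = np.where(valid, vals, 0.0).sum(axis=1) / counts
    ref = ReferenceSignal(
        values=series, timestamps_s=maps.timestamps_s[idx], source=src, window=window
    )
    if mode == "roi":
        ref.__dict__["centroid"] = centroid
    return ref


def correlation_map(
    maps: HemodynamicMaps,
    reference: ReferenceSignal,
    foot_mask: RoiMask,
    exclusions: list[RoiMask] | None = None,
) -> CorrelationMap:
    """Pearson coefficient of every valid foot pixel's StO2 vs the reference.

    Fiducial and other exclusion masks, pixels outside the foot, and
    pixels invalid at any window frame are NaN in the output and never
    enter downstream statistics.
    """
    idx = _window_slice(maps.timestamps_s, reference.window)
    if idx.size != reference.values.size:
        raise ValueError("reference window does not match the maps' frames")
    include = foot_mask.mask.copy()
    for excl in exclusions or []:
        include &= ~excl.mask
    include &= maps.sto2_valid[idx].all(axis=0)

    H, W = maps.frame_shape
    pcc = np.full((H, W), np.nan)
    if include.any():
        Y = maps.sto2[idx][:, include]  # (n, m)
        yc = Y - Y.mean(axis=0)
        xc = reference.values - reference.values.mean()
        denom = np.sqrt((xc * xc).sum() * (yc * yc).sum(axis=0))
        num = xc @ yc
        vals = np.full(num.shape, np.nan)
        ok = denom > 0
        vals[ok] = np.clip(num[ok] / denom[ok], -1.0, 1.0)
        pcc[include] = vals
    return CorrelationMap(
        pcc=pcc,
        reference=reference,
        window=reference.window,
        meta={"n_window_frames": int(idx.size), "reference_source": reference.source},
    )


def pairwise_roi_correlations(
    maps: HemodynamicMaps,
    rois: list[RoiMask],
    window: tuple[float, float] | None = None,
    paradigm: Paradigm | None = None,
) -> pd.DataFrame:
    """Pearson coefficient between ROI-mean StO2 profiles, all unordered pairs.

    Returns a tidy frame (roi_a, roi_b, pcc) — the synthetic analogue of
    comparing wound vs background and background vs background regions.
    """
    if len(rois) < 2:
        raise ValueError("need at least two ROIs for pairwise correlations")
    if window is None:
        if paradigm is None:
            raise ValueError("supply either a window or a paradigm to derive it from")
        window = default_correlation_window(paradigm)
    idx = _window_slice(maps.timestamps_s, window)
    series = {}
    for roi in rois:
        valid = maps.sto2_valid[idx][:, roi.mask]
        counts = valid.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError(f"ROI {roi.label!r} has frames with no valid pixels in the window")
        vals = maps.sto2[idx][:, roi.mask]
        series[roi.label] = np.where(valid, vals, 0.0).sum(axis=1) / counts
    rows = [
        {"roi_a": a, "roi_b": b, "pcc": pearson(series[a], series[b])}
        for a, b in itertools.combinations([r.label for r in rois], 2)
    ]
    return pd.DataFrame(rows)


def profile_correlation(a: ConcentrationProfile, b: ConcentrationProfile) -> float:
    """Pearson coefficient between two extracted profiles (same grid)."""
    if len(a) != len(b):
        raise ValueError("profiles must share length")
    return pearson(a.values, b.values)
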