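"""The Oxygenation Flow Index (OFI) and its healing-status threshold.

The OFI summarizes a flow-correlation map as the median of its valid
Pearson-coefficient distribution, expressed in percent.  The median is
preferred over the mean because correlation distributions over a foot are
routinely skewed (a wound or vein can drag a long tail); the median still
reads as the central synchrony tendency.

A configurable threshold classifies the index: OFI below the threshold
flags asynchronous oxygenated flow (non-healing tendency).  The shipped
default of 28 % comes from a separate multi-case ulcer study and is
configuration with provenance, not a value this package validates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flowcorr import CorrelationMap
from .io import RoiMask

__all__ = ["OFIResult", "compute_ofi", "classify_ofi", "DEFAULT_OFI_THRESHOLD_PCT"]

#: Healing-status threshold in percent (external-study default; configurable).
DEFAULT_OFI_THRESHOLD_PCT = 28.0


@dataclass
class OFIResult:
    """Median flow-correlation index with distribution summaries."""

    ofi_pct: float
    n_valid: int
    q1_pct: float
    q3_pct: float
    min_pct: float
    max_pct: float
    mask_descriptor: str
    meta: dict = field(default_factory=dict)


def compute_ofi(
    cmap: CorrelationMap,
    mask: RoiMask | None = None,
    wound: RoiMask | None = None,
    exclude_wound: bool = True,
) -> OFIResult:
    """Median of the valid PCC distribution under the mask, in percent.

    ``mask`` restricts the statistic (default: every valid map pixel, i.e.
    the foot minus exclusions already applied when the map was built).
    When a ``wound`` mask is given and ``exclude_wound`` is set, wound
    pixels are removed first — the threshold convention is defined on the
    foot excluding the wound.  Even pixel counts take the mean of the two
    central order statistics (the standard median).
    """
    values = cmap.pcc
    include = cmap.valid
    descriptor = "map"
    if mask is not None:
        include = include & mask.mask
        descriptor = mask.label
    if wound is not None and exclude_wound:
        include = include & ~wound.mask
        descriptor += f" minus {wound.label}"
    vals = values[include]
    if vals.size == 0:
        raise ValueError(f"no valid correlation pixels under mask {descriptor!r}")
    pct = 100.0 * vals
    return OFIResult(
        ofi_pct=float(np.median(pct)),
        n_valid=int(vals.size),
        q1_pct=float(np.percentile(pct, 25)),
        q3_pct=float(np.percentile(pct, 75)),
        min_pct=float(pct.min()),
        max_pct=float(pct.max()),
        mask_descriptor=descriptor,
        meta={"reference_source": cmap.reference.source, "window": list(cmap.window)},
    )


def classify_ofi(result: OFIResult | float, threshold_pct: float = DEFAULT_OFI_THRESHOLD_PCT) -> str:
    """"below" iff OFI < threshold (strictly), else "above".

    The boundary value itself classifies "above": the criterion is the
    strict inequality OFI < threshold.
    """
    if not (-100.0 <= threshold_pct <= 100.0):
        raise ValueError(f"threshold must lie in [-100, 100] percent, got {threshold_pct}")
    ofi = result.ofi_pct if isinstance(result, OFIResult) else float(result)
    return "below" if ofi < threshold_pct else "above"
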