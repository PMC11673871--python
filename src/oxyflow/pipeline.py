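"""End-to-end orchestration: stack -> registration -> oximetry -> profiles
-> flow-correlation map -> OFI, with reproducible on-disk artifacts.

Every stage is a pure function of (inputs, config, seed); the run merely
composes them and persists intermediates.  The default configuration
needs zero overrides for a paradigm-faithful run: 40/20/60 s at 1 Hz,
Savitzky-Golay window 11 / order 3, the 41-80 s correlation window, and
the 28 % OFI threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import tifffile

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import flowcorr, ofi as ofi_mod, profiles as prof_mod
from .io import CalibrationFrame, Paradigm, ReflectanceStack, RoiMask, dump_yaml
from .mbll import ExtinctionMatrix, HemodynamicMaps, compute_hemodynamics
from .register import RigidTransform, register_stack

__all__ = ["RunConfig", "RunResult", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    paradigm: Paradigm = field(default_factory=Paradigm)
    extinction: ExtinctionMatrix = field(default_factory=ExtinctionMatrix)
    savgol_window: int = 11
    savgol_polyorder: int = 3
    saturation_index: str = "ratio"  # or "difference" (HbO - HbR)
    register: bool = True
    reference_mode: str = "global_mean"  # or "roi"
    correlation_window: tuple[float, float] | None = None  # None -> paradigm default
    ofi_threshold_pct: float = ofi_mod.DEFAULT_OFI_THRESHOLD_PCT
    exclude_wound: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_polyorder:
            raise ValueError("savgol_window must be odd and exceed savgol_polyorder")
        if self.reference_mode not in ("global_mean", "roi"):
            raise ValueError(f"reference_mode must be global_mean or roi, got {self.reference_mode!r}")
        if self.saturation_index not in ("ratio", "difference"):
            raise ValueError(f"saturation_index must be ratio or difference, got {self.saturation_index!r}")
        if not (-100.0 <= self.ofi_threshold_pct <= 100.0):
            raise ValueError("ofi_threshold_pct must lie in [-100, 100]")

    def resolved_window(self) -> tuple[float, float]:
        if self.correlation_window is not None:
            return tuple(self.correlation_window)
        return flowcorr.default_correlation_window(self.paradigm)

    def to_dict(self) -> dict:
        d = {
            "paradigm": self.paradigm.to_dict(),
            "extinction": self.extinction.to_dict(),
            "savgol_window": self.savgol_window,
            "savgol_polyorder": self.savgol_polyorder,
            "saturation_index": self.saturation_index,
            "register": self.register,
            "reference_mode": self.reference_mode,
            "correlation_window": list(self.resolved_window()),
            "ofi_threshold_pct": self.ofi_threshold_pct,
            "exclude_wound": self.exclude_wound,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "paradigm" in d:
            d["paradigm"] = Paradigm.from_dict(d["paradigm"])
        if "extinction" in d:
            d["extinction"] = ExtinctionMatrix.from_dict(d["extinction"])
        if d.get("correlation_window") is not None:
            d["correlation_window"] = tuple(float(x) for x in d["correlation_window"])
        return cls(**d)


@dataclass
class RunResult:
    """Everything one run produced, in memory."""

    maps: HemodynamicMaps
    smoothed: HemodynamicMaps
    transforms: list[RigidTransform]
    reference: flowcorr.ReferenceSignal
    correlation: flowcorr.CorrelationMap
    ofi: ofi_mod.OFIResult
    classification: str
    profiles: dict[str, prof_mod.ConcentrationProfile]
    config: RunConfig


def run(
    config: RunConfig,
    stack: ReflectanceStack,
    calibration: CalibrationFrame,
    foot_mask: RoiMask,
    wound_mask: RoiMask | None = None,
    reference_roi: RoiMask | None = None,
    fiducial_mask: RoiMask | None = None,
    profile_rois: list[RoiMask] | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Run the full analysis on one acquisition.

    ``reference_roi`` is required in "roi" reference mode (wound cases):
    the background region for the reference signal is a deliberate user
    choice, never auto-selected.  When ``outdir`` is given, all artifacts
    (maps, profiles, correlation map, OFI table, transforms, resolved
    config) are written there.
    """
    paradigm = config.paradigm
    if stack.n_frames != paradigm.n_frames:
        raise ValueError(
            f"stage 'inputs': stack has {stack.n_frames} frames, paradigm expects {paradigm.n_frames}"
        )

    # Step 1 — motion correction
    if config.register:
        stack, calibration, transforms = register_stack(stack, calibration)
    else:
        transforms = [RigidTransform() for _ in range(stack.n_frames)]

    # Step 2 — mBLL oximetry
    maps = compute_hemodynamics(
        stack, calibration, config.extinction, saturation_index=config.saturation_index
    )

    # Step 3 — pixel-wise smoothing and ROI profiles
    smoothed = prof_mod.smooth_pixelwise(maps, config.savgol_window, config.savgol_polyorder)
    rois = list(profile_rois or [])
    if all(r.label != foot_mask.label for r in rois):
        rois = [foot_mask] + rois
    out_profiles: dict[str, prof_mod.ConcentrationProfile] = {}
    for roi in rois:
        for parameter in ("hbo", "hbr", "hbt", "sto2"):
            p = prof_mod.roi_profile(smoothed, roi, parameter)
            out_profiles[f"{roi.label}:{parameter}"] = prof_mod.normalize_at_onset(p, paradigm)

    # Step 4 — flow-correlation map
    window = config.resolved_window()
    reference = flowcorr.build_reference(
        smoothed,
        mode=config.reference_mode,
        foot_mask=foot_mask,
        roi=reference_roi,
        window=window,
    )
    exclusions = [m for m in (fiducial_mask,) if m is not None]
    cmap = flowcorr.correlation_map(smoothed, reference, foot_mask, exclusions=exclusions)

    # Step 5 — OFI and classification
    result = ofi_mod.compute_ofi(cmap, wound=wound_mask, exclude_wound=config.exclude_wound)
    classification = ofi_mod.classify_ofi(result, config.ofi_threshold_pct)

    out = RunResult(
        maps=maps,
        smoothed=smoothed,
        transforms=transforms,
        reference=reference,
        correlation=cmap,
        ofi=result,
        classification=classification,
        profiles=out_profiles,
        config=config,
    )
    if outdir is not None:
        write_artifacts(out, Path(outdir))
    return out


def write_artifacts(result: RunResult, outdir: Path) -> None:
    """Persist one run's artifact bundle."""
    outdir.mkdir(parents=True, exist_ok=True)
    dump_yaml(result.config.to_dict(), outdir / "run_config.yaml")

    pd.DataFrame(
        [
            {"frame": i, "rotation_deg": t.rotation_deg, "tx": t.tx, "ty": t.ty}
            for i, t in enumerate(result.transforms)
        ]
    ).to_csv(outdir / "transforms.csv", index=False)

    for name in ("hbo", "hbr", "hbt", "sto2"):
        tifffile.imwrite(outdir / f"map_{name}.tif", result.maps.parameter(name).astype(np.float32))
    tifffile.imwrite(outdir / "map_valid.tif", result.maps.valid.astype(np.uint8))

    rows = []
    for key, p in result.profiles.items():
        roi_label, parameter = key.rsplit(":", 1)
        for t, v in zip(p.timestamps_s, p.values):
            rows.append({"t_s": t, "value_pct": v, "parameter": parameter, "roi": roi_label})
    pd.DataFrame(rows).to_csv(outdir / "profiles.csv", index=False)

    tifffile.imwrite(outdir / "correlation_map.tif", result.correlation.pcc.astype(np.float32))
    _plot_correlation_map(result.correlation, outdir / "correlation_map.png")
    _plot_profiles(result.profiles, result.config.paradigm, outdir / "profiles.png")

    o = result.ofi
    pd.DataFrame(
        [
            {
                "mask": o.mask_descriptor,
                "ofi_pct": o.ofi_pct,
                "n_valid": o.n_valid,
                "q1_pct": o.q1_pct,
                "q3_pct": o.q3_pct,
                "min_pct": o.min_pct,
                "max_pct": o.max_pct,
                "threshold_pct": result.config.ofi_threshold_pct,
                "classification": result.classification,
            }
        ]
    ).to_csv(outdir / "ofi.csv", index=False)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(
            {
                "seed": result.config.seed,
                "reference_source": result.reference.source,
                "window_s": list(result.correlation.window),
                "n_window_frames": result.correlation.meta.get("n_window_frames"),
                "ofi_pct": o.ofi_pct,
                "classification": result.classification,
            },
            fh,
            indent=2,
        )


def _plot_correlation_map(cmap: flowcorr.CorrelationMap, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(cmap.pcc, cmap="RdBu_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="Pearson correlation")
    ax.set_title(f"Flow correlation vs {cmap.reference.source}")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _plot_profiles(
    profile_map: dict[str, prof_mod.ConcentrationProfile], paradigm: Paradigm, path: Path
) -> None:
    params = ("hbo", "hbr", "hbt", "sto2")
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.2), sharex=True)
    for ax, parameter in zip(axes, params):
        for key, p in profile_map.items():
            if key.endswith(":" + parameter):
                ax.plot(p.timestamps_s, p.values, label=key.rsplit(":", 1)[0])
        ax.axvspan(paradigm.onset_s, paradigm.hold_end_s, color="0.85", label=None)
        ax.set_title(parameter)
        ax.set_xlabel("t (s)")
    axes[0].set_ylabel("% change from onset")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
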