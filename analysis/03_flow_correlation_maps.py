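#!/usr/bin/env python
"""Flow-correlation maps and pairwise ROI correlations for the three scenes.

Reads the scene bundles written by 01_simulate_scenes.py, runs oximetry +
smoothing, builds the reference signal (whole-foot mean for the control,
a background ROI for the wound scenes), and writes each scene's Pearson
correlation map (32-bit TIFF + diverging-colormap PNG) plus a pairwise
ROI correlation table under <out>/flowcorr/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

import oxyflow as ox
from oxyflow.io import WAVELENGTHS_NM, read_calibration, read_mask, read_stack
from oxyflow.pipeline import _plot_correlation_map
from oxyflow.profiles import smooth_pixelwise

SCENES = ("control", "healing", "nonhealing")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)  # kept for interface symmetry
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    outdir = args.out / "flowcorr"
    outdir.mkdir(parents=True, exist_ok=True)
    paradigm = ox.Paradigm()

    tables = []
    for name in SCENES:
        indir = args.out / "scenes" / name
        if not indir.exists():
            raise SystemExit(f"{indir} missing; run 01_simulate_scenes.py first")
        stack = read_stack({wl: indir / f"stack_{wl}nm.tif" for wl in WAVELENGTHS_NM}, paradigm)
        cal = read_calibration({wl: indir / f"calibration_{wl}nm.tif" for wl in WAVELENGTHS_NM})
        foot = read_mask(indir / "mask_foot.png", "foot")
        fid = read_mask(indir / "mask_fiducial.png", "fiducial")
        sm = smooth_pixelwise(ox.compute_hemodynamics(stack, cal))

        H, W = foot.mask.shape
        if name == "control":
            ref = ox.build_reference(sm, "global_mean", foot_mask=foot, paradigm=paradigm)
            rois = [
                ox.make_rect_roi((int(0.3 * H), int(0.4 * W)), 20, (H, W), "B1"),
                ox.make_rect_roi((int(0.6 * H), int(0.25 * W)), 20, (H, W), "B2"),
                ox.make_rect_roi((int(0.6 * H), int(0.6 * W)), 20, (H, W), "B3"),
            ]
            for roi in rois:
                roi.mask &= foot.mask
        else:
            background = read_mask(indir / "mask_background.png", "background")
            wound = read_mask(indir / "mask_wound.png", "wound")
            bgref = ox.make_rect_roi((int(0.65 * H), int(0.3 * W)), 12, (H, W), "bgref")
            bgref.mask &= background.mask
            ref = ox.build_reference(sm, "roi", roi=bgref, paradigm=paradigm)
            b1 = ox.make_rect_roi((int(0.6 * H), int(0.2 * W)), 16, (H, W), "B1")
            b1.mask &= background.mask
            b2 = ox.make_rect_roi((int(0.6 * H), int(0.62 * W)), 16, (H, W), "B2")
            b2.mask &= background.mask
            rois = [b1, b2, ox.RoiMask(wound.mask, "W")]

        cm = ox.correlation_map(sm, ref, foot, exclusions=[fid])
        tifffile.imwrite(outdir / f"{name}_correlation_map.tif", cm.pcc.astype(np.float32))
        _plot_correlation_map(cm, outdir / f"{name}_correlation_map.png")

        table = ox.pairwise_roi_correlations(sm, rois, paradigm=paradigm)
        table.insert(0, "scene", name)
        tables.append(table)
        frac_neg = float((cm.valid_values() < 0).mean())
        print(f"{name}: reference={ref.source}, negative-PCC fraction={frac_neg:.2%}")
        for r in table.itertuples():
            print(f"  {r.roi_a} vs {r.roi_b}: PCC = {100 * r.pcc:.1f}%")

    pd.concat(tables, ignore_index=True).to_csv(outdir / "pairwise_roi_correlations.csv", index=False)
    print(f"wrote maps and pairwise_roi_correlations.csv to {outdir}")


if __name__ == "__main__":
    main()
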