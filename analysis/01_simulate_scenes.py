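#!/usr/bin/env python
"""Render the three study scenes: control, healing-like, non-healing-like.

Each scene bundle (dual-wavelength stack TIFFs, calibration frames, masks,
ground-truth CSV, scene config) is written under <out>/scenes/<name>/.
The control scene is fully synchronous tissue; the healing-like scene
delays the wound's breath-hold response by 20 s; the non-healing-like
scene inverts it.
"""

import argparse
from pathlib import Path

import oxyflow as ox

SCENES = {
    "control": {"kind": "control", "shape": [128, 128], "noise_sd": 0.01},
    "healing": {
        "kind": "wound",
        "shape": [128, 128],
        "noise_sd": 0.01,
        "wound_delay_s": 20.0,
        "wound_inverted": False,
    },
    "nonhealing": {
        "kind": "wound",
        "shape": [128, 128],
        "noise_sd": 0.01,
        "wound_delay_s": 0.0,
        "wound_inverted": True,
    },
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    for i, (name, cfg) in enumerate(SCENES.items()):
        scene = ox.scene_from_config(cfg)
        outdir = args.out / "scenes" / name
        paths = ox.write_scene_bundle(outdir, scene, seed=args.seed + i, config=cfg)
        print(f"{name}: wrote {len(paths)} files to {outdir}")


if __name__ == "__main__":
    main()
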