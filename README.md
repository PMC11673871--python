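# oxyflow

Breath-hold near-infrared spectroscopic (NIRS) imaging analysis for
peripheral tissue perfusion — from dual-wavelength diffuse-reflectance
image stacks to hemoglobin oxygenation maps, breath-hold response
profiles, pixel-wise oxygenation-flow correlation maps, and the
**Oxygenation Flow Index (OFI)**.

## The problem

A breath-hold triggers peripheral vasoconstriction followed by a
hyperemic recovery. A non-contact dual-wavelength (682 / 826 nm) NIRS
imager pointed at a foot captures this response at 1 Hz across the whole
imaged tissue, which makes it possible to ask not just *how much* oxygen
the tissue carries but *how synchronously* the oxygenated flow responds
across the foot. In diabetic foot ulcers, asynchronous flow in and around
the wound is a candidate marker of a wound that will not heal. This
package implements that analysis for people working with such acquisitions
(or simulations of them): wound-care imaging researchers and
biomedical-optics students.

## The method

1. **Motion correction** — every frame is rigidly registered (rotation +
   translation, normalized cross-correlation metric) to the first frame;
   the transforms are propagated to the calibration reference.
2. **Oximetry (modified Beer–Lambert law)** — per pixel and frame, the
   attenuation against a white calibration sheet,
   `ΔOD(λ) = log10(I_cal(λ) / I(λ))`, is inverted through the 2×2
   extinction system to give effective ΔHbO and ΔHbR (pathlength factor
   set to 1), with ΔHbT = ΔHbO + ΔHbR and StO₂ = HbO / HbT.
3. **Profiles** — each pixel's time series is Savitzky–Golay filtered
   (window 11 frames, order 3), averaged over a region of interest, and
   normalized to percent change from breath-hold onset (t = 40 s).
4. **Flow-correlation map** — each foot pixel's StO₂ series is compared
   with a reference signal (whole-foot mean for healthy feet, a
   user-chosen background ROI for wound cases) by the Pearson correlation
   coefficient

   ```
   PCC = Σᵢ (Xᵢ − X̄)(Yᵢ − Ȳ) / sqrt( Σᵢ(Xᵢ − X̄)² · Σᵢ(Yᵢ − Ȳ)² )
   ```

   over the 40 s window spanning the 20 s hold and the first 20 s of
   recovery (t = 41…80 s for the default 40/20/60 s paradigm at 1 Hz).
5. **OFI** — the median of the valid PCC distribution, in percent.
   A configurable threshold (default 28 %, from a companion multi-case
   ulcer study) flags feet whose flow response is asynchronous.

Because no subject imaging data is distributable, the package ships a
synthetic scene generator (`oxyflow.synthetic`) that renders
NIROS-like dual-wavelength stacks with a programmable breath-hold
response, per-region melanin attenuation, fiducial markers, rigid motion
and sensor noise — with exact ground truth alongside, so the entire
pipeline is testable end to end.

## Worked example

```bash
python analysis/01_simulate_scenes.py --seed 0        # render 3 scenes
python analysis/02_breath_hold_profiles.py --seed 0   # grand averages
python analysis/03_flow_correlation_maps.py           # correlation maps
python analysis/04_ofi_summary.py                     # OFI table
```

The second step simulates 3 control "subjects" × 3 repetitions and pools
the whole-foot percent-change profiles:

```
hbo: plateau change (t >= 100 s) = +2.00 %
hbr: plateau change (t >= 100 s) = -2.54 %
hbt: plateau change (t >= 100 s) = +0.48 %
sto2: plateau change (t >= 100 s) = +1.51 %
```

i.e. oxyhemoglobin overshoots to a new baseline ≈2 % above the hold-onset
value, deoxyhemoglobin undershoots by ≈2.5 %, and total hemoglobin moves
only ≈0.5 % (it is the sum of the two opposing changes). The third and
fourth steps then print, for the three scenes:

```
control: reference=global_mean, negative-PCC fraction=0.00%
nonhealing: reference=roi:bgref, negative-PCC fraction=29.95%
  B1 vs B2: PCC = 100.0%
  B1 vs W: PCC = -100.0%
control     [foot             ] OFI =   95.8%  -> above threshold
nonhealing  [foot             ] OFI =   94.5%  -> above threshold
```

Background regions correlate near-perfectly with each other while the
inverted wound anti-correlates with them; the wound covers 30 % of the
foot, so the *median*-based OFI (robust by design) drops only slightly at
this noise level — the separation grows with sensor noise and wound
extent.

There is also a CLI over the same library (`oxyflow simulate`,
`oxyflow run`, `oxyflow ofi`, plus single-stage commands):

```bash
oxyflow simulate --config scene.yaml --out bundle/ --seed 1
oxyflow run --in bundle/ --out out/ --no-register
# OFI = 95.9% over 6320 pixels (above the 28% threshold)
```

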