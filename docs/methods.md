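# Methods

This note documents the models, conventions and numerical choices behind
`oxyflow`, and what the synthetic test bed does and does not establish.

## Breath-hold paradigm and conventions

The stimulus paradigm is 40 s rest, 20 s end-exhalation breath-hold, 60 s
recovery, sampled at 1 Hz per wavelength (`Paradigm`, configurable).
All stages share one convention: 0-based (row, col) indexing, time in
seconds since acquisition start, frame index = round(t · sampling_hz).
The analysis onset t₀ is the end of rest (t = 40 s); the hold window is
the half-open interval (40, 60] s.

## Oximetry model

Attenuation is computed against the white calibration sheet rather than
against the first tissue frame:

    ΔOD(λ, x, y, t) = log10( I_cal(λ, x, y) / I(λ, x, y, t) ).

This makes the recovered ΔHbO/ΔHbR behave like positive absolute-style
effective concentrations, so the saturation ratio StO₂ = HbO/(HbO+HbR) is
well defined per frame; the temporal "Δ" enters later, at the profile
stage, as percent change from hold onset. The 2×2 extinction system is
solved with a unit differential-pathlength × geometry factor: only
percent changes and correlation coefficients are consumed downstream, and
both are invariant to that global scale (asserted by a test). The default
extinction coefficients at 682/826 nm are compiled-hemoglobin-spectra
values (ε_HbO = 320, 900; ε_HbR = 2180, 720 cm⁻¹·M⁻¹); they are
configuration with provenance logged in the map metadata, and any
well-conditioned pair gives identical downstream results.

Degenerate pixels: intensities or references ≤ 0 are flagged invalid
rather than producing NaNs; StO₂ is additionally flagged invalid where
|HbT| < 10⁻⁶ effective units (division guard) instead of being clipped.
An alternative oxygenation index, the oxy–deoxy balance HbO − HbR, is
available behind the explicit `saturation_index="difference"` switch; it
needs no guard but is not a fraction. The ratio is the default.

## Motion correction

Rigid only (rotation about the frame center + translation), estimated on
the 826 nm channel and applied to both channels and to the calibration
reference — the two wavelengths come from the same camera 0.5 s apart, so
one transform per time point. The estimator sweeps rotation coarsely
(±5° in 1° steps; warm-started from the previous frame's angle inside a
stack), solves the translation at each angle by masked FFT phase
correlation — masking prevents zero-filled borders, either from the
candidate rotation or from previously invalidated pixels, from anchoring
the correlation peak — scores candidates by normalized cross-correlation
over valid pixels, and refines (rotation, tx, ty) jointly with
Nelder–Mead (explicit 0.5-unit initial simplex, xatol 0.01). Transforms
with all components below 5·10⁻³ snap to the exact identity so that
motion-free runs are bit-identical with registration on or off.
Resampling is bilinear; pixels mapped from outside the frame are filled
with 0 and excluded from every downstream statistic via validity masks.
Known-transform recovery on noise-free frames is accurate to ~0.02° and
~0.01 px, comfortably within the 0.5 px / 0.5° contract the tests assert.

## Profiles

Savitzky–Golay smoothing (default window 11 frames, polyorder 3 at 1 Hz)
is applied per pixel along time with polynomial edge handling
(`mode="interp"`), chosen to suppress frame-level sensor noise while
leaving 20 s-scale response features untouched; HbT is recomputed from
the filtered HbO and HbR so the HbT ≡ HbO + HbR identity stays exact.
ROI profiles are means over valid pixels only, with per-frame
contributing-pixel counts retained. Percent-change normalization divides
by |S(t₀)| so a negative effective onset value cannot flip the profile's
sign; S(t₀) = 0 is an error, not a silent skip. Re-normalizing an
already-normalized profile at the same onset is a no-op (the onset sample
is 0 % by construction, so the general formula would divide by zero).
Grand averages use the pointwise mean and standard error sd/√n with the
sample (n−1) standard deviation.

## Flow correlation and OFI

The correlation statistic is the zero-lag Pearson coefficient, computed
over the window (rest_s, rest_s + 2·hold_s] — the hold plus an equally
long slice of early recovery, i.e. frames at t = 41…80 s (n = 40) for the
default paradigm; changing the paradigm shifts the window automatically.
It is evaluated on smoothed, *unnormalized* StO₂ series: PCC is invariant
to the affine percent-change transform, so this is observationally
equivalent to correlating normalized profiles while avoiding
onset-division failures at individual pixels. Zero-variance pixels return
NaN (invalid) rather than 0 — a 0 would bias the synchrony index toward
"uncorrelated". The reference signal is the whole-foot mean StO₂ for
healthy feet and a background-ROI mean for wound cases; the background
ROI is a deliberate user choice (its centroid is logged), never
auto-selected.

The OFI is the median of the valid PCC distribution in percent — the
median rather than the mean because the distributions are routinely
skewed. Even counts take the mean of the two central order statistics.
For wound cases the wound region is excluded by default
(`exclude_wound`); both behaviors are exposed since either masking is
defensible. Classification uses the strict inequality OFI < threshold
(default 28 %, shipped as configuration whose provenance is an external
multi-case study; this package does not validate it), so the boundary
value classifies as "above".

## Synthetic scenes: what they emulate and what they don't

The generator renders the forward model of the oximetry stage exactly:
per pixel, I(λ,t) = I_cal(λ) · melanin · 10^(−ε_HbO(λ)·HbO(t) −
ε_HbR(λ)·HbR(t)), plus fiducial squares at near-zero reflectance, a
non-tissue background at 5 % reflectance, optional per-frame rigid
motion, and multiplicative Gaussian noise applied to the effective
concentrations (drawn per pixel and frame, shared across wavelengths so
the two channels stay physically consistent). Noise on the hemodynamic
signal rather than on raw intensity keeps the per-pixel signal-to-noise
ratio directly interpretable against the ~2 % response amplitude;
sensor-noise sd defaults to 0.01 (1 % of the signal).

The response curve family is deliberately simple: a linear HbR ramp
during the (possibly delayed) hold, then exponential approach (τ = ¼ of
the remaining time) to the recovery targets, held exactly from the
plateau time on. Defaults encode the control physiology: HbR rises 2 %
during the hold, HbO overshoots to +2 % and HbR undershoots to −2.5 % of
baseline, plateauing at the 100th second; baselines (2·10⁻⁴ / 1·10⁻⁴
effective units, i.e. a resting saturation of 0.67) are chosen to give
mid-range optical densities (~0.25–0.3 OD) — absolute magnitudes are not
physiologic claims, since only percent changes and correlations matter
downstream. Wound-like tissue delays the response (default 20 s, matching
recovery landing at 80–100 s instead of 60–80 s); non-healing-like tissue
inverts it. Melanin is a static multiplicative transmission factor shared
by both wavelengths: a breath-hold does not change melanin concentration,
so only its static attenuation is modeled, and the temporal analysis
cancels it (tested at factors 1.0 vs 0.4).

What the scenes do *not* emulate: layered-skin optics or wavelength-
dependent melanin spectra, scattering changes, cardiac/respiratory bands,
calibration-sheet non-uniformity, non-rigid foot deformation, and spatial
texture within a region (regions are piecewise-uniform, so rotation
estimation leans on region boundaries and fiducials). Passing tests
therefore demonstrate internal consistency of the pipeline and
qualitative fidelity of the group-level patterns — not clinical accuracy
on real feet.

One behavior worth flagging: because the OFI is a median, a wound
occupying 30 % of the foot lowers the index only modestly at low noise
(the median stays inside the synchronous majority). The strong OFI
depression seen in real non-healing feet reflects asynchrony extending
into non-wound tissue, which a scene can reproduce by assigning delayed
or inverted responses to background regions as well.

## Problem sizes

Tests run scenes at 32²–128² pixels and the standard 120-frame paradigm;
the replicate ordering study uses 100 seeded pairs at 128². The
forward/inverse consistency check runs a 120-frame 256×256 stack. These
sizes keep the full suite around a minute while exercising every code
path at realistic frame counts.
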