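# Methods

This note documents the models and numerical choices behind `cvrkit`, what the synthetic
phantoms do and do not emulate, and the known limitations.

## End-tidal CO2 extraction

A capnogram oscillates once per breath between the inspired CO2 partial pressure (trough)
and the end-expiratory value (peak). The EtCO2 curve — the upper envelope — approximates
arterial CO2, the vasoactive stimulus driving the BOLD response.

**Preprocessing.** The raw trace (native rate anywhere in 10–200 Hz) is smoothed with a
100 ms moving average and linearly resampled onto a uniform 10 Hz grid starting at t = 0.
Breathing sits below ~0.3 Hz, so 10 Hz is ample for peak timing while the smoothing
suppresses sensor noise.

**Scale-space detector.** Strict local maxima of the 10 Hz trace (plateaus report their
earliest sample; the first/last samples are never peaks) are candidates. At iteration
k = 1…30 the trace is smoothed with a centered moving average of width 2k+1 samples,
maxima are re-detected, and each one credits the *nearest* candidate within k+2 samples,
accumulating a persistence score; candidates scoring ≥ 15 (of 30, configurable) survive.
Two choices deserve comment:

- *Scale-proportional credit radius.* A breath's smoothed maximum drifts away from its
  unsmoothed position roughly in proportion to the smoothing half-width: a flat exhalation
  plateau of ~2 s drifts its detected maximum by up to k samples at scale k. A fixed
  small radius stops crediting after the first couple of scales and no candidate can reach
  the threshold on realistic waveforms; the k+2 radius tracks the drift while
  nearest-candidate crediting still starves isolated noise spikes (the nearest candidate
  to a smoothed breath maximum is the breath's own peak, never a distant spike).
- *Threshold 15/30.* The midpoint of the iteration count. On a sinusoidal trace with
  period P samples the moving average flips sign at width ≈ P, so a breath of period
  3–8 s (30–80 samples at 10 Hz) is credited for at least the first ~14–30 scales;
  the midpoint accepts all physiological periods while rejecting features that die early.

**Smooth-cross detector.** The trace crosses its own 10 s moving average about twice per
breath. Each maximal run where the trace strictly exceeds the moving average is a breath
segment and contributes its maximum (earliest sample on ties) as one peak. The 10 s window
is wide enough to span any single breath yet short enough to follow the room-air/CO2 block
transitions.

**Envelope assembly.** Each detector's peak-value sequence is median-filtered with a
5-breath window (windows shrink *symmetrically* at the ends, so monotone stretches are
untouched while a partial breath — an isolated low peak — is replaced by its neighbours'
level; the breath-time grid is kept, only values change). The filtered peaks are linearly
interpolated onto integer seconds, held constant beyond the first/last peak, and the two
1 Hz series are combined by pointwise maximum: each detector underestimates the envelope
in different places (irregular breaths for one, block transitions for the other), and the
true envelope is the upper of the two. If a detector yields fewer than 3 peaks the other
is used alone (recorded in QC); if both fail the capnogram is rejected.

**Summary statistics.** mean(EtCO2) is the arithmetic mean of the curve;
baseline(EtCO2) is the average of the ⌈0.25·N⌉ smallest values — robust to a single deep
breath in a way the minimum is not. A baseline below 25 mmHg (strict) raises the CO2-
switching warning: in slow responders the exhaled CO2 can transiently fall below the
inhaled 5% mixture, inverting what the envelope measures. No automatic correction is
attempted; the warning asks for manual review of the raw trace.

## Temporal alignment

EtCO2 is measured at the mouth and the BOLD response in the brain, so the regressor must
be shifted by ventilation-to-brain transit plus hemodynamic delay before fitting. The GLM
regresses the BOLD time course on the zero-meaned EtCO2 resampled (linear interpolation)
to recorder times s + i·TR, a linearly ascending drift term ℓ = −(N−1)/2 … (N−1)/2, and an
intercept. The shift convention: s is the recorder-time offset of the BOLD start within
the CO2 recording, so the feasible range is [0, EtCO2 duration − BOLD duration].

The search is two-step: a 1 s-step scan over the full feasible range (ties → smallest
shift), then a 100 ms-step scan over ±5 s around the coarse optimum (clipped to the
feasible range; regressor samples beyond the curve hold the terminal value, with a
warning). Two numerical choices:

- *Non-negative CO2 coefficient during scoring.* The block paradigm is nearly periodic
  (120 s period), so an anti-phase shift fits exactly as well as the true one if β1 may go
  negative — the half-period offset merely flips the regressor's sign, and the
  unconstrained residual minimum is not identifiable. Shifts whose unconstrained β1 is
  negative are therefore scored with the CO2-free (drift + intercept) residual, which a
  genuine positive-response shift always beats. Hypercapnia raises the BOLD signal, so
  only physiologically inverted fits are discarded. The final fit at the optimum is
  unconstrained.
- *Local vertex refinement.* The residual-vs-shift profile is piecewise smooth with kinks
  at 1 s spacing (the regressor is piecewise linear in the shift), so the vertex of a
  single quadratic over the full ±5 s window is biased by up to a few tenths of a second.
  The full-window quadratic is still fitted and reported (QC, convexity check), but the
  final shift is the vertex of a parabola over the fine-grid points within ±1 s of the
  grid argmin, clamped to that neighbourhood; if neither parabola is convex the grid
  argmin is used with a warning. Measured on noiseless phantoms this recovers sub-grid
  shifts (e.g. 60.35 s) to better than 0.01 s.

The partial correlation between BOLD and the optimally shifted EtCO2 — both residualized
against intercept and drift — is the run's quality index; it is invariant to affine
rescaling of either signal and to adding any multiple of ℓ to the BOLD series.

## CVR quantification

CVR = β1 / (β0 − β1·(mean − baseline)) · 100, in % BOLD change per mmHg. Because the
regressor is zero-meaned, β0 is the fitted signal at *mean* EtCO2; the denominator
reconstructs the signal at baseline EtCO2, so CVR is referenced to the room-air state.
`mean` here is the mean of the aligned, frame-sampled regressor (the EtCO2 actually
paired with the BOLD data); using the full-curve mean instead would bias the denominator
whenever the fitted window is not centered on the recording, while the windowed mean makes
the formula an exact inverse of the forward model. `baseline` stays the full-curve
bottom-25% average. Non-positive denominators (and |denominator| < 1e−9·|β0|) yield NaN.

Whole-brain CVR fits at the global shift. Regional CVR repeats the full two-step
alignment per ROI (white matter lags gray matter; a single global shift would bias late
regions) and flags ROIs under 10 voxels. Voxel-wise maps come in two forms: fitted at the
global shift, and with a per-voxel extra shift δ scanned over −5…+30 s at 1 s steps
(ties → smallest δ; window edges flagged in a boundary map) — the narrow window avoids
noise-driven false minima, and the winning δ is itself the temporal-shift map, analogous
to a bolus-arrival-time map. No polynomial refinement is done at voxel level: single-voxel
residual profiles are too noisy for sub-second precision to be meaningful. Voxels with
constant time courses are NaN. Relative maps divide by the in-mask mean (NaNs excluded);
no statistical thresholding is applied — the maps report raw CVR values.

## Resting-state relative CVR

Spontaneous CO2 and vasomotor fluctuations below ~0.1 Hz modulate the BOLD signal
globally. The whole-brain time course is linearly detrended, low-pass filtered to
[0, 0.1164] Hz, and rescaled to zero mean and 2-norm √N/2. The filter is an ideal
frequency-domain projection (rFFT bins at or below the cutoff kept, inclusive at the
cutoff bin), which is exactly idempotent and exactly testable; the 0.1164 Hz cutoff is the
band previously found to maximize spatial agreement with CO2-challenge CVR maps. The
build fails loudly when the detrended signal retains less than 1% of its norm below the
cutoff (no usable low-frequency content) or is constant.

Each voxel's raw series is regressed on the reference, the six zero-meaned motion
parameters (all-constant columns dropped), a linear trend, and an intercept;
RS-CVR = 100·β1/β0. Regressing the raw series rather than ΔBOLD/BOLD changes β1 and β0 by
the same per-voxel scale factor, which cancels in the ratio — and any remaining per-voxel
scale cancels again in the relative map (division by the in-mask mean). Only relative
RS-CVR is reported: without a CO2 recording there is no mmHg scale.

## Preprocessing

Spatial smoothing is a per-frame 3D Gaussian, default 8 mm FWHM, sigma = FWHM/√(8 ln 2)
converted to voxels per axis, reflective boundaries (no edge darkening). The brain mask
is computed from the smoothed temporal-mean image — threshold at 50% of the 98th-percentile
robust maximum, largest connected component, hole filling — because for whole-brain
averaging and relative normalization only the brain/background split matters; a
user-supplied mask on the BOLD grid always overrides. Motion correction, slice timing,
distortion correction and any registration are out of scope: the pipeline consumes
motion-corrected series and co-registered label images, and never resamples in space.
All time is in seconds; frame i is assigned onset time i·TR.

## Synthetic phantoms

The generators reproduce the standard study conditions: 60 s room-air / 60 s hypercapnia
blocks with EtCO2 40 → 48 mmHg, breath periods drawn from a clipped normal
(mean 4.5 s, bounds 3–8 s), troughs at the inspired level (≈1 mmHg room air, ≈36 mmHg
during 5% CO2), raised-cosine breath edges with a flat exhalation plateau, optional
half-amplitude partial breaths; BOLD voxels are affine in the time-shifted EtCO2 truth
(gain = CVR referenced to the baseline), plus linear drift, optional motion leakage, and
white Gaussian noise, on a 64×64×10 grid (3.44×3.44×3.5 mm voxels), TR 2 s, 210 frames.
"SNR 10" means the hypercapnic plateau contrast divided by the per-frame noise SD is 10.
The capnogram duration defaults to the longer of 7 min and shift + BOLD span + 36 s so
shifted regressors never run off the recording. The resting generator shares a latent
sum-of-sinusoids signal placed exactly on FFT bins at or below 0.1164 Hz across voxels
through a gain field.

Deliberate simplifications, and what they mean for the tests: block transitions in the
truth curve are instantaneous (real EtCO2 washes in/out over tens of seconds), breath
plateaus are exactly flat, there is no vascular dispersion of the CO2 bolus, no anatomy,
and noise is white. Passing tests therefore demonstrate correct recovery of the model the
pipeline assumes — not robustness to dispersion, colored physiological noise, or motion
artifacts beyond linear leakage. Two phantom-specific facts matter for interpreting
recovery numbers: (i) with instantaneous 1 Hz transitions and TR 2 s all frames share one
fractional sampling offset, so noiseless residuals are flat over 1 s-wide shift intervals
and sub-second shift recovery is only identifiable when the BOLD is built from a
breath-resolved (extracted) envelope — the alignment tests do exactly that; (ii) the
extracted envelope registers each block transition at the following breath, so pipeline
shifts exceed the square-wave truth shift by roughly one breath period — a constant
offset shared by all regions that cancels out of CVR and out of shift *differences*.

Everything is driven by one seeded `numpy.random.Generator`; a fixed seed gives bitwise
identical phantoms and, downstream, byte-identical tabular outputs.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run the full-size CO2 phantom (64×64×10×210,
SNR 10) once for CVR recovery, 100 seeded repetitions of whole-brain alignment at SNR 5
for shift recovery, a 32×32×6 resting phantom for two-compartment RS-CVR recovery, and
small grids (≤ 16×16×4) for exhaustive per-voxel comparisons against brute-force
reimplementations.

## Known limitations

- ANALYZE 7.5 carries no orientation; images are used in stored voxel order and all
  inputs of a run must share the BOLD grid.
- The anti-phase ambiguity resolved by the non-negative-β1 scoring assumes a positive
  CO2 response; globally inverted responses (rare pathologies) would alias by half a
  paradigm period.
- The CO2-switching check is a warning heuristic only (baseline < 25 mmHg); switching
  with a normal baseline is not detectable from the envelope.
- Absolute RS-CVR (mmHg-scaled) is out of scope, as are dispersion modeling, nonlinear
  hemodynamic response shapes, and any spatial normalization.
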