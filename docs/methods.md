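# Methods

This note documents the models, conventions and parameter choices behind
`mitophys`, and what validation on synthetic data does and does not
establish about real recordings.

## Calcium-trace quantification

**CTCF.** A cell's raw measurement is the integrated density of its ROI per
frame plus the per-frame mean intensity of each background ROI. The
corrected total cell fluorescence is

    CTCF(t) = integrated_intensity(t) − area(t) · mean_background(t),

with the background ROIs averaged at equal weight (they are drawn at equal,
constant size). The area may vary per frame (mitotic rounding) but is
constant by default. CTCF is linear in the intensities, and identically
zero when the cell ROI contains only background.

**Photobleach detrending and percent normalization.** Bleaching of the
indicator over a 2-h recording is modelled as linear; an OLS line over the
whole trace estimates the drift. Only the *slope* component is removed
(the fit is anchored at t = 0), and the result is expressed as percent
change relative to the t = 0 level:

    detrended(t) = ctcf(t) − slope·(t − t₀)
    value(t)     = 100 · (detrended(t) − detrended(t₀)) / detrended(t₀)

Subtracting the entire fitted line would leave residuals centred on zero
and make "percent change relative to time zero" numerically meaningless;
anchoring preserves that semantics while avoiding division by ≈0. A
`literal` mode performs the full-line subtraction against a user-supplied
reference level for auditing. Cells whose reference level is non-positive
or below an epsilon (default 10⁻⁶·|intercept|, configurable absolutely)
are flagged unusable and excluded with a logged count. The normalization
is invariant to a positive rescaling of the raw trace.

**Time-domain metrics.** AUC is the signed trapezoidal integral of the
percent trace (%·s); negative excursions subtract, preserving the
interpretation of AUC/duration as the mean relative calcium level. Peaks
are local maxima with prominence above a threshold; prominence follows the
standard contour definition and FWHM is the width at half-*prominence*
with linear interpolation (the convention of the common MATLAB/SciPy peak
routines). The default threshold is noise-adaptive: twice the robust SD
(MAD × 1.4826) of the first-differenced trace, ≈2.8× the sample noise SD
for white noise. No threshold was published for this step, so the default
is a documented, configurable choice; isolated noise excursions can still
exceed it, which matters little for the median-based per-cell summaries.

**Spectral metrics.** The percent trace (720 samples at 10 s ⇒ Δf =
1/7200 Hz ≈ 0.139 mHz, Nyquist 50 mHz) is Fourier-transformed without
padding; two-sided power is folded to a single-sided PSD, P(f) =
|X(f)|²/(N·fs) with interior bins doubled, so that Σ P·Δf equals the
time-domain mean square (Parseval; DC excluded it equals the variance).
The K = 15 strongest non-DC components (ties broken toward lower
frequency) define the weighted average frequency f̄ = Σf·P/ΣP. The DC bin
is excluded because the detrended percent trace is near zero-mean and DC
carries no oscillation information. f̄ is invariant to any constant
rescaling of the PSD, hence independent of the density-normalization
convention, and bounded by the selected frequencies. No taper is applied
by default; a Hann window is available but *increases* the noise
sensitivity of the top-K selection (see limitations). The literal
unnormalized mean of frequency×PSD products is available behind a flag for
auditing; it carries units of Hz×power and is not comparable across
amplitudes.

**Known limitation — near-gridline tones.** For a single dominant tone the
top-15 selection is populated by the tone's spectral-leakage bins, whose
PSD-weighted mean closely matches the tone (zero-noise recovery error
< 0.02 mHz at all tested frequencies). When the tone lies within ~0.2 bins
of an FFT gridline, leakage is weak, the selection admits a few pure-noise
bins, and — at noise of 20% of the oscillation amplitude — their pull
toward mid-band biases f̄ by ~0.1–0.35 mHz, at or above one bin. This is a
property of the estimator, not of its implementation; the recovery
property tests therefore cover tones with fractional offsets ≥ 0.25 bins,
and results for frequencies very close to a multiple of 0.139 mHz should
be interpreted with this bias in mind. Real oscillations spread power over
many components, which populates the selection and attenuates the effect.

## Microtubule plus-end dynamics

Tracks are (x, y) positions of a growing-tip comet at a fixed frame
interval (default 0.5 s) over ~1 min. Positions are projected onto the
track's dominant axis (first principal component); polarity is anchored to
the first interval whose speed exceeds the pause threshold, taken as
outward growth — comet markers exist only on growing tips, so a track
begins when a growth phase begins. Intervals are labelled growth/shrink
when the signed projected speed exceeds ±`pause_threshold` (default
1 µm·min⁻¹, configurable; unpublished) and gap otherwise; tracks shorter
than 4 frames are excluded and counted.

* growth speed — mean signed projected speed over growth intervals;
* growth length — mean start-to-end displacement per maximal growth run;
* dynamicity — growth↔shrink transitions (a gap between a growth and a
  shrink run still separates one switch) per minute of track lifetime.

All metrics are invariant to translation and rotation of the coordinates.
In real comet data shrinkage appears as detection gaps rather than inward
motion; ground-truth labels read from file (`true_phase`) can be used
directly, and the signed-speed path applies to complete trajectories such
as the simulator's. Note that dynamicity here is the verbal
switching-frequency definition; tracking suites that report a
collective-displacement-based "dynamicity" measure a different quantity.

## Spindle tilt geometry

θ = atan2(|Δz|, √(Δx²+Δy²)) in degrees ∈ [0, 90], the angle between the
inter-pole axis and the substrate plane z = 0; the pole distance is the
Euclidean 3D norm. The angle is exact (no small-angle approximation),
symmetric under pole swap, and invariant under xy-rotation, translation
and z-mirroring. Anisotropic voxel sizes must be corrected at read time
(`voxel_z` scale in the CSV reader).

## Group statistics

Two-sided Mann–Whitney U-tests: the exact permutation null when the
smaller sample has ≤ 8 observations and the pooled data are tie-free,
otherwise the normal approximation with tie and continuity corrections.
Summaries are median with IQR (mean ± SEM also reported). Percent
differences are printed in both conventions — group vs reference and
reference vs group — with the reference always labelled, because the two
are not symmetric and published effect sizes are ambiguous about the
convention. No multiple-testing correction is applied by default
(conventional for these pairwise assay comparisons); Bonferroni is
available behind a flag.

## Synthetic-data generators

All generators take an integer seed and are bit-reproducible; cohorts
derive per-cell seeds from `SeedSequence([master_seed, group_index,
cell_index])`, so any subset regenerates identically regardless of
iteration order.

**Calcium traces.** cell signal = baseline + bleach_slope·t +
Σ A·sin(2πft+φ) + Σ Gaussian transients (σ = FWHM/2.3548) + N(0, noise²),
sampled on the 10-s grid over 7200 s. Defaults are the study conditions:
baseline 100, one component at the control-group 9.19 mHz with amplitude 5
(5% of baseline), noise SD 1 (20% of amplitude), bleach −10% of baseline
over the recording, three background ROIs. Component frequencies at or
above Nyquist are rejected as aliasing errors. The cell ROI's integrated
intensity includes the background level under the cell (area × background
mean), so CTCF correction recovers the cell signal; background ROI means
carry noise at noise_sd/area (the SD of a mean over a cell-sized region
with the same per-pixel noise as the cell ROI — per-pixel-scale background
noise would be amplified by the ×area term into physical nonsense).
Background ROIs are constant-mean by default; an option lets them share
the bleach drift. The generator emulates stationary sinusoidal components,
isolated Gaussian transients and white noise only — real recordings have
nonstationary oscillation amplitude, correlated noise and cell movement,
so passing recovery tests demonstrate estimator correctness, not
robustness to those artefacts.

**MT tracks.** Two-state continuous-time dynamic instability: exponential
holding times at the catastrophe rate (growth→shrink) and rescue rate
(shrink→growth), constant speeds ±v along a straight random-azimuth axis,
positions sampled at the frame interval with isotropic Gaussian noise
(default 0.02 µm). Ground-truth interval labels record the phase occupying
the majority of each interval. Defaults: growth 19.12 µm·min⁻¹ (the
control-group value), shrink 30 µm·min⁻¹ (shrinkage is characteristically
faster), rates 2 min⁻¹ each, 1-min tracks, start in growth (as comet
tracks do). With equal rates λ the switch count over T is Poisson(λT) —
the expected dynamicity is λ, and for unequal rates the alternating-
renewal value 2/(1/λc+1/λr); mean growth-excursion length approaches
v/λc when excursions are short relative to the track (end-censoring
shortens the observed mean otherwise). Real tracks curve, pause and
fragment; none of that is emulated.

**Spindles.** Pole A at the origin in the substrate plane; pole B offset
by d·cos(tilt) in-plane at a random azimuth and d·sin(tilt) in z. Tilt may
be a constant, a per-cell sequence, or a sampling function; distance
default 10 µm, a typical metaphase spindle length.

## Numerical conventions and edge cases

* Uniform-grid validation tolerates 10⁻⁶ relative jitter; non-uniform
  input is rejected, not resampled.
* Spectral analysis requires ≥ 8 samples; peak detection ≥ 3; baseline
  fitting ≥ 2 and a non-constant time vector.
* Top-K selection requires K ≤ number of non-DC bins; all-zero selected
  PSD is an error for the normalized weighted mean.
* Empty peak sets yield NaN medians (reported as missing), not errors.
* Coincident spindle poles are an error; zero in-plane separation with
  nonzero Δz is a valid 90° tilt.
* Percent-difference requires a nonzero reference.

## Problem sizes used in validation

Recovery suites use 50-seed replicate sets per condition for the calcium
pipeline (720-sample traces), 100–300 tracks per cohort for MT dynamics,
and 1000 replicates for the Mann–Whitney type-I calibration — sizes at
which the Monte-Carlo error of each checked quantity is several times
smaller than its test tolerance.
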