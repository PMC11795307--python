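# Methods

This note documents the models, estimators, parameters and numerical
choices behind `modmap`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## The measurement chain

### Baseline and ΔF/F

Fluorescence movies are modelled as `F(t, x) = B(x)(1 + d(t))(1 + s(t, x)) + ε`,
with a slow multiplicative drift `d` and transient activity `s`.  The
baseline `F0` is a per-pixel running median over a window of 10–64 s
(default 30 s, the midpoint of the admissible range); windows outside that
range are rejected because a shorter window would track the calcium
transients themselves and a longer one would no longer follow slow drift.
Edge frames use truncated (shrinking) windows rather than reflected data, so
no fabricated samples enter the baseline.  The running median is an exact
sliding-window median (sorted-buffer insertion/deletion, compiled with
numba), not an approximation.  Activity is `ΔF/F = (F − F0)/F0`; a
nonpositive baseline inside the ROI is an error, never silently clipped.

Registration is translation-only phase correlation against the temporal
median frame (subpixel refinement ×10), with the image means removed so the
luminance pedestal cannot bias the subpixel fit.  Rotations are assumed
negligible under head fixation; the reference and similarity metric are
package choices since only "rigid" is externally specified.

### Event detection

A per-pixel threshold is fitted to each pixel's ΔF/F histogram: a Gaussian
`A exp(−(v−μ)²/2σ²)` is least-squares fitted to the bin counts, using only
bins below a truncation value so that large positive transients (the events
themselves) do not inflate μ and σ.  The truncation value is
`min + 1.5 (mode − min)` of the histogram — equal to 1.5× the modal value
for positive-support data, and a cutoff at roughly the mirror image of the
left tail for baseline-centred ΔF/F.  Bin width is Freedman–Diaconis on the
sub-95th-percentile bulk (8–128 bins); the fit is Gauss–Newton with a
log-parabola initialisation, vectorised over pixels; pixels whose fit fails
fall back to median/1.4826·MAD with a logged count.  On
N(0, 0.05) + 5% transients at +0.5 the fit recovers σ ≈ 0.050 while the
naive SD is 0.12.  The threshold is μ + 3σ; alternatively the 80th
percentile of the pixel's trace (`percentile80`), appropriate when the
ΔF/F distribution broadens with age.  Switching between the two rules
changes median wavelength and modularity by far less than 15% on synthetic
movies.

Two spatial criteria then apply per frame: active pixels outside any
8-connected component of area ≥ 0.01 mm² are discarded (8-connectivity is
the permissive standard for blob area; at 22 μm/px the rule is ≥ 21 px),
and a frame is "active" iff strictly more than 40% of ROI pixels remain
active (evaluated after the component cleanup).  Runs of active frames
become events; a run containing an interior local minimum of the ROI-mean
trace is split there, with equal-value plateaus resolved to their last
frame for determinism.  Each event's pattern is its frame of maximal
ROI-mean activity.

### Band-pass, correlation fields, surrogates

Event frames are filtered with a Gaussian difference-of-Gaussians
(defaults s_low = 30 μm — middle of the 26–41 μm range used per
experiment — and s_high = 195 μm).  Both blurs are masked: the blurred
masked frame is divided by the blurred mask, so ROI-border pixels are not
diluted by outside values.  Frames are then block-average downsampled by an
integer factor (default 4, e.g. 640×540 → 160×135); for geometries where
the canonical target grid is not an integer divisor the factor is chosen
directly.  The measured sinusoid attenuation matches the analytic DoG
transfer function `exp(−2π²s_low²f²) − exp(−2π²s_high²f²)` to better
than 1%.

Correlation fields are across-pattern Pearson correlations between a seed
pixel and every ROI pixel, computed pairwise-complete over missing values:
surrogate transforms invalidate different pixels in different patterns, and
those entries are excluded, never zero-filled (zero-filling would bias
surrogate variance downward).  Pixels with zero across-pattern variance are
NaN.  The full seed×pixel matrix is computed with masked matrix products in
float32.

The surrogate ensemble rotates each pattern independently by an angle
uniform on {0°, 10°, …, 350°} and reflects it about the x- and y-axes with
probability 0.5 each, about the center of the ROI bounding box.  Rotation
uses bilinear interpolation; output pixels whose pre-image falls outside
the original ROI are NaN.  Transform matrices are snapped to integers
within 1e−9 so exact transforms (identity, flips, multiples of 90°) remain
bit-faithful.

A caveat documented here because it shapes the null tests: on a coarse
pixel grid no resampling surrogate is exactly measure-preserving.
Resampling jitter slightly smears each pattern's radial autocorrelation,
and per-pattern invalidation reduces the effective sample size near the ROI
border.  For patterns whose single-event spatial coherence has decayed by
the ring distance (the realistic case, and the generator default) the net
effect is a mildly *conservative* long-range significance test; for
unrealistically narrow-band patterns whose self-correlation persists to
2 mm the sign reverses.  The null-calibration tests therefore assert the
false-positive bound (≤ 10% at α = 0.05) rather than exact p-uniformity.

### Wavelength, modularity, module amplitude

The spatial autocorrelation of a band-passed pattern is computed via FFT
with zero padding, masked so only pixel pairs with both ends inside the ROI
contribute (overlap-count normalisation), scaled to 1 at zero lag, and
averaged over annuli one downsampled pixel wide (the finest stable
binning).  The profile is smoothed with a 3-bin moving average (truncated
edges); the first interior strict local minimum (plateaus resolve to the
smallest radius) is refined to sub-bin precision with a 3-point parabola,
and the wavelength is twice that radius.  Modularity is the absolute
difference between the profile value at that minimum and at the subsequent
maximum, where "subsequent maximum" is the maximum of the smoothed profile
within radii up to three times the minimum radius (≈ 1.5 wavelengths): a
bounded argmax instead of the literal first local maximum, because single-bin
wiggles can otherwise masquerade as maxima of near-zero amplitude.  Profiles
with no interior minimum are flagged invalid, never guessed.

Module amplitude works on the raw (unfiltered) ΔF/F event frame: peaks are
local maxima of a Gaussian-smoothed copy (SD 2 px) under a maximum filter
of radius Λ/4, with a floor of the ROI median plus twice the pixel-noise SD
(estimated from the median absolute deviation of frame − smoothed when not
supplied), and restricted to pixels whose smoothing support lies inside the
ROI — the masked blur otherwise creates spurious maxima on the ROI border.
Background per peak is the median raw ΔF/F over an annulus at distance Λ/2
(half-width one analysis pixel, ≈ 22 μm); the event value is the mean
peak/background ratio, with nonpositive backgrounds excluded with a
warning.  Note that for generic quasi-periodic patterns the half-wavelength
annulus crosses both troughs and flanks, so the measured ratio is
systematically below the pattern's peak/trough contrast; on a radially
symmetric cosine fixture, where the annulus sits entirely in the trough,
the estimator returns the exact closed-form value.

Modularity significance: control frames are the lowest 10% of non-event
frames by ROI-mean activity; 100 sets of event-count size are drawn (with
replacement if the pool is smaller, logged), each control frame passes
through the identical band-pass → autocorrelation → modularity path
(profiles with no structure score 0), and the p-value is the
continuity-corrected one-sided fraction of control median modularities at
or above the observed median — one-sided because the hypothesis is that
events are more modular than quiescence.  Calibration on synthetic null
movies (white-noise events) gives a rejection rate of ≈ 0.09 at α = 0.05
(pooled over 180 runs; batches range 0.05–0.12): mildly above nominal
because the 100 control sets resample a finite bottom-10% pool (~90 frames
at test-scale movie lengths), which narrows the control-median
distribution, but within the 10% false-positive bound the test is held to.
Longer recordings enlarge the pool and shrink the effect.

### Long-range correlation strength

For each seed, the variance of correlation values over ROI pixels at
1.8–2.2 mm distance; the experiment value averages over all seeds with at
least two defined ring pixels (averaging over every usable seed is
symmetric and reduces estimator variance; the externally specified
procedure is silent on seed choice).  To fix the event count across
experiments, `n_use` patterns (default 100) are drawn without replacement
when available (with replacement and a flag otherwise).  The same statistic
on rotation/reflection surrogate ensembles of matched size gives the
finite-sample floor; the corrected strength is
`variance_real − variance_surrogate` (both raw values are always reported,
since the externally specified "correction" does not pin down difference
vs ratio), and significance is the continuity-corrected fraction of
surrogate variances ≥ the real one.  The surrogate count is configurable
(default 100; the scaled-down tests use 20, whose minimum attainable
p = 1/21 < 0.05 keeps the test decisive).

### Cross-validated dimensionality

Patterns are restricted to a circular region of area 0.5 Λ² (Λ = median
event wavelength) centred on the ROI centroid (placement is unspecified
externally and config-overridable).  Per subset, `subset_size` events
(default 100) are split into disjoint halves X₁/X₂ (equal halves; sizes are
not externally specified); principal axes are learned from centred X₁ by
SVD; λᵢ is the variance of X₂ (centred on its own mean) projected on axis
i; the subset dimensionality is the participation ratio `(Σλ)²/Σλ²`, and
the result averages 10 subsets.  The estimator matches an explicit
covariance-eigendecomposition oracle to machine precision on
non-degenerate spectra.

An important geometric fact, established with an independent oracle (the
participation ratio of the true component Gram matrix restricted to the
region): a region of area 0.5 Λ² has diameter ≈ 0.8 Λ — about one module —
so k equal-power global components do **not** yield d_eff ≈ k.  The oracle
PR is ≈ 2.1/2.9/4.1 for k = 3/5/10 at Λ = 1 mm, and the cross-validated
estimator tracks it within a few percent.  d_eff is therefore validated
against the oracle and by strict monotonicity in k, not by proximity to k.

## The synthetic-data generator

The generator emulates the statistics of the targeted recordings: 15 Hz
movies of a ~3.5 × 3 mm field (640×540 px at ~5.5 μm/px by default; tests
use smaller grids at coarser pitch), sparse events whose patterns are
weighted sums of K mutually uncorrelated modular components, on a flat
baseline with slow sinusoidal drift (periods 37/53/97 s ≥ 30 s, so the
10–64 s median window can follow it) and i.i.d. Gaussian pixel noise.

**Components** are Gaussian random fields with an isotropic Gaussian ring
spectrum (relative bandwidth 0.2) — quasi-periodic, "modular" textures.
The carrier frequency is calibrated numerically so that the radial
autocorrelation's first minimum falls exactly at Λ/2, i.e. the generator's
nominal wavelength agrees with the estimator's operational definition (this
differs from placing the spectral *peak* at 1/Λ: for a near-ring spectrum
the ACF is ≈ J₀(2πf₀r) times an envelope, whose first minimum is at
r ≈ 0.61/f₀, not 0.5/f₀).  The 0.2 bandwidth makes single-pattern spatial
coherence decay over a few modules and vanish by ~2 mm, as in real events;
much narrower bands would give each individual pattern millimetre-range
self-correlation, which real data do not show and which distorts the
long-range null.  Components are decorrelated exactly (QR on the centred
fields) and z-scored.

**Events** map the weighted component sum affinely onto
`[floor, 1] × amplitude` (defaults floor 0.5, amplitude 0.2 ΔF/F): peaks at
`amplitude`, troughs at `floor × amplitude`, so fluorescence is nonnegative
and the pattern's peak/trough contrast (1/floor) is known ground truth.
The time course is a 2-frame linear rise and exponential decay with
τ = 1 s, GCaMP6s-like; event supports may not overlap, and peak times are
strictly increasing with ≥ 3-frame separation enforced.  Noise SD defaults
to 0.02 ΔF/F and drift amplitude to 0.05 — small relative to events
(SNR ≈ 10) but large relative to pixel noise, typical of wide-field data.

Two null generators support calibration tests: movies whose "events" are
spatially white-noise patterns (for modularity significance), and ensembles
of mutually independent modular fields with no shared components (for
long-range strength).

**What the synthetic tests do not show:** the generator has no hemodynamic
or vascular artifacts, no photobleaching, no nonstationary noise, no ROI
irregularities beyond shape, stationary component statistics, and a single
fixed event time course.  Passing recovery tests demonstrates the
estimators are correct and calibrated under the stated statistical model;
it does not certify performance under artifact regimes real recordings can
contain.

## Problem sizes and determinism

The test suite and the acceptance script run the full machinery at reduced
scale, chosen as the package's standard small-study conditions: movies of
96×96–136×160 px at 22 μm/px (the analysis-grid pitch of the full-size
geometry), 20–30 events per movie, 100-pattern ensembles on a 40×40 grid at
88 μm/px for network statistics, 20 surrogates per significance call, and
50-run null calibrations.  Every random draw descends from a single seed
via named `SeedSequence` stages (`simulate`, `detect`, `significance`,
`strength`, `dimensionality`), so any stage re-run in isolation reproduces
the pipeline exactly and identical configs give byte-identical outputs.

## Known limitations

- The wavelength estimate carries a small negative bias (up to ~9% at
  Λ = 1.2 mm) from the fixed 195 μm high-SD analysis filter, which
  attenuates long wavelengths asymmetrically; this is a property of the
  measurement definition, shared by any reimplementation of it.
- The surrogate test's exactness degrades on coarse grids (see above);
  at the full 160×135 analysis grid with ~22 μm pixels the effect is
  negligible, and at test scale it errs conservative under realistic
  coherence.
- The bootstrap control pool for modularity significance is the bottom 10%
  of non-event frames; for short recordings the pool is small and control
  medians become correlated across the 100 sets, mildly inflating the null
  rejection rate (≈ 0.09 pooled over 180 test-scale null movies at
  α = 0.05, still under the 10% bound).
- `fit()` requires at least one detected event and at least 10 non-event
  frames; fields of view too small for the 1.8–2.2 mm ring raise a clear
  error and the remaining metrics are still computed.
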