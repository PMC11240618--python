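# Methods

This note records the models, conventions and numeric defaults behind
`caflux`, the choices made where the design was genuinely open, and the
limits of what the synthetic-data tests demonstrate.

## Trace model and acquisition

A single-cell recording is modeled as

    v(t) = [ baseline + Σᵢ A·K(t − tᵢ) + drift·t + ε(t) ] · e^(−β t)

on a uniform grid (default 5-s interval, 40-min duration, 481 samples).
`ε` is i.i.d. Gaussian noise; the multiplicative bleaching factor
`e^(−βt)` applies only in Calbryte (single-wavelength intensity) mode —
Fura-2 ratios are insensitive to bleaching because both excitation
channels fade together. Event kernels `K`:

- **transient** — difference of exponentials
  `exp(−s/τ_d) − exp(−s/τ_r)`, peak-normalized so the kernel maximum is
  exactly the requested amplitude (peak offset
  `s* = τ_r τ_d/(τ_d − τ_r)·ln(τ_d/τ_r)`; α-function in the τ_r = τ_d
  limit);
- **oscillatory** — a periodic train of such transients at a given
  frequency;
- **plateau** — a tanh-edged boxcar of width τ_d and edge constant τ_r,
  also peak-normalized.

These three shapes span the qualitative repertoire seen in calcium
recordings of drug-adapted cells: single large transients, repeated
spikes, minute-scale oscillations and sustained elevations. No
published amplitude/width distributions exist for this setting, so the
default mix is an explicit assumption: amplitudes 0.35–0.6 ratio units
(2–3.5× the 0.17 spike threshold), rise 6–15 s, decay 20–45 s,
oscillation period 90 s, plateau width 300 s, resting ratio 0.8,
noise SD 0.005 ratio units. Default Calbryte settings emulate a
baseline of ~1000 intensity units with bleach rate ~5×10⁻⁴ s⁻¹.

Populations are generated from one top-level seed that spawns an
independent substream per cell, so a cell's trace does not depend on
population size or ordering. The spiking count is exactly
`round(n · spike_fraction)` by construction — label consistency is a
generator invariant, not a sampling outcome.

## Spike classification

Five criteria, each voting "non-spiking"; under the default
*conjunction* rule a cell is non-spiking only if every applicable
criterion agrees (a disjunction mode exists because the combination is
a matter of convention). Leading-frame exclusion (default 0; 10 frames
under ATP stimulation, where buffer addition produces artifacts) is
applied before everything else.

**Baseline adjustment.** The flat-trace (B: mean < 0.05, SD < 0.01) and
amplitude (E: max ≤ 0.17) thresholds are implausible for raw 340/380
ratios, which rest near 0.2–1; both criteria therefore operate on
values minus a per-cell trailing rolling minimum (window 60 s).
A raw mode (`baseline_method="none"`) is available; which convention a
given historical dataset used cannot be asserted, so the method is
configurable and echoed in run reports.

**Criterion A (zero slope).** OLS slope of value against sample index.
Default tolerance: `|slope| ≤ max(2·SE, 0.05/n)`. The pure 2·SE rule
is a significance test and by construction condemns ~5 % of genuinely
flat noisy traces; the absolute floor declares slopes biologically
inert when the implied total drift over the whole recording stays below
the flat-mean threshold. An explicit `slope_tolerance` overrides both.

**Criterion C (feature clustering).** Catch-22 features per trace
(non-finite values imputed to 0), zero-variance features dropped,
standardized, projected onto **2 principal components**, clustered by
DBSCAN (ε = 2, minPts = 20). The cluster with the highest fraction of
members already satisfying A∧B — if that fraction is positive — is
designated non-spiking; other clusters and DBSCAN noise vote
"spiking". Two components are the default because ε = 2 is a distance
in the score space: in the 10–18 standardized dimensions needed to
reach 90 % explained variance, that radius strands borderline
quiescent cells as noise and inflates the spiking fraction (observed:
up to +5.5 percentage points on 200-trace populations). Variance-based
selection remains available (`pca_components=None`,
`pca_variance=0.9`). Degenerate cases: fewer traces than minPts, or no
DBSCAN cluster at all, make the criterion *inapplicable* (it abstains)
rather than voting against every cell. With more than two clusters only
the single max-overlap cluster is designated.

**Criterion D (periodicity).** Unnormalized DFT of the mean-subtracted
trace, DC excluded; any magnitude > 10 votes "spiking". The threshold
is unit-bearing, so the convention (no 1/N normalization,
mean-subtraction) is fixed and documented rather than inferred.

**Calbryte annotation.** Bleaching and autofocus artifacts defeat the
ratio-trace criteria, so Calbryte calls use a surrogate for manual
annotation: fit an exponential decay (rolling-median fallback), form
relative residuals `v/trend − 1` (bleaching is multiplicative, so
relative excursions are homoscedastic), estimate the noise scale
robustly from successive differences (MAD/√2), and call spiking when
any excursion exceeds 5× that scale. On synthetic bleaching traces
with 2-event transients at 15× noise SD this reproduces ground truth
without error; the 5× multiple is a sensitivity knob, not a measured
constant.

**Over-estimation.** `overestimation_rate` reports (automatic −
reference) spiking fraction against manual or ground-truth labels,
signed; automatic calling is expected to over-call modestly on real
data.

## The 22-feature embedding

`caflux.catch22` implements the published Catch-22 canonical
time-series features natively (distribution modes, outlier timing,
autocorrelation statistics, Gaussian auto-mutual information, symbolic
motif entropies, transition-matrix covariance, Wang periodicity,
2-d embedding distance exponential misfit, rectangular-window spectral
area/centroid, two-regime fluctuation-scaling fits, local-mean forecast
errors). Fixed conventions: series z-scored first (features are
scale/offset invariant), biased 1/N autocorrelation, natural
logarithms, constant series → zero vector, non-finite features imputed
to 0. Every feature is locked by an independent naive
re-implementation in the test suite (plain loops, O(N²) DFT,
`np.polyfit`, explicit B-spline least squares) with 1e-8 agreement on
heterogeneous trace zoos. Internal micro-conventions that the feature
names do not pin down (histogram bin counts, the two-regime split
minimum of 6 points, the spline knot at the series midpoint) are fixed
here and exercised by both routes.

## Bootstrap statistics

Proportions are resampled with replacement: sample size defaults to
max(50, ⌈0.2 · n⌉) and is normally set to 200 (Fura-scale annotation,
~1000 cells) or 50 (Calbryte-scale, 160–500 cells); 100 iterations;
point estimate = mean of resample proportions; interval = percentile
bootstrap. The 95 % level is a package default, not a measured value.
`sampled_mean_proportion` (1000 cells × 10 repeats, mean ± SD) is the
error model used for ppERK percentages. Calibration at study settings:
the point estimate sits within 3 binomial SE of truth and percentile
intervals over-cover slightly (measured coverage ≈ 1.0 at n = 1000,
p = 0.6 — expected, since the bootstrap sees the full 1000-cell label
set while the interval targets 200-cell sampling error).

## SOCE quantification

Baseline = mean signal over the last 120 s of the equilibration phase
(configurable window; the protocol defines phase 1 as baseline
acquisition but no window). ER content and SOCE activity are trapezoid
integrals of (value − baseline) over phases 2 (600–1080 s) and 3
(1080–1560 s). Negative excursions integrate negative — no clamping.
Only baseline subtraction is applied; no additional per-cell
normalization. The synthetic assay places raised-cosine bumps of exact
analytic area inside each phase (supports grid-aligned, inset 10 % from
phase edges), so trapezoid quadrature error is far below 1 %. An
exploratory exponential clearance fit on the post-peak phase-2 segment
reports a cytoplasmic clearance time constant; it is flagged, not part
of the core quantification.

## ppERK scoring

Filters: area ∈ [50, 4500] px² (closed interval — "between" read
inclusively) and integrated intensity < 5×10⁶ (strict, as written).
Rows failing filters are flagged and retained but excluded from every
denominator. Positivity compares integrated intensity (configurable:
mean intensity) against a background threshold — explicit, or the
0.99 quantile of a no-primary-antibody control table. Undetected cells
receive the plotting sentinel −0.5.

**Intensity score.** The combined score is
`fraction_positive × mean(log₁₀(signal/background))` over positive
cells, normalized to the 1-min reference timepoint per condition. The
two ingredients (positive fraction, positive-cell intensities) are
fixed; the functional form is this package's own, chosen to be
monotone in both and exactly invariant when intensities and background
rescale together (a raw `mean(log₁₀ intensity)` term breaks that
invariance by an additive shift). The formula is pluggable
(`PpERKConfig.score_formula`). Normalization is undefined when the
reference group has no positives; that raises with guidance rather
than returning infinities.

**Dose–response.** Four-parameter log-logistic
`f(c) = lower + (upper − lower)/(1 + (c/mid)^hill)`, fit by bounded
least squares in log-concentration space (0 ≤ lower, upper ≤ 1.2 —
responses are fractions of vehicle control; hill ∈ [10⁻³, 20]).
The conservative low-dose assumption (1 nM ≡ vehicle) enters as an
appended data point, not a fixed asymptote. Non-convergence and flat
responses are flagged results, not exceptions. Anchored fits carry a
small irreducible residual (~3×10⁻⁴) because the anchor slightly
over-states the model value at 1 nM.

## Problem sizes and what the tests show

Validation uses populations of 500 traces per spiking level for
classifier recovery, 500 bootstrap replicates for coverage, 100 SOCE
traces, 8-dose triplicate titrations × 50 seeds for dose–response —
sizes chosen to match the study-scale designs (a few hundred to ~1000
annotated cells per condition; titrations in technical triplicate)
while keeping the whole suite fast on one CPU.

Passing these tests shows the algorithms are correct and calibrated on
data satisfying the generator's assumptions: well-separated spike
amplitudes, stationary Gaussian noise, exact exponential bleaching,
static segmentation. Real recordings add focus drift, motion, uneven
illumination, overlapping cells and spike shapes outside the kernel
repertoire; the classifier's behavior there must be validated against
manual annotation (the `overestimation_rate` path). Segmentation
itself, Fura-2 calibration to absolute [Ca²⁺], biophysical channel
kinetics and spike-waveform parameterization beyond the binary call
are out of scope.
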