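# Methods

This note documents the models, conventions and numerical choices behind
`somatomap`, in the order data flows through the package.

## Stimulus space and designs

The finger dimension is a 1D axis spanning [−12.5, +12.5] arbitrary
units, split into five equal 5-unit intervals with D1 lowest (centers
−10, −5, 0, +5, +10).  The interval boundaries are a package convention:
the axis bounds and the per-digit equivalence (25 units = 5 fingers) fix
only the total extent, not where one finger ends and the next begins.

Designs are described per volume.  The travelling-wave protocol defaults
to 20 cycles × 5 fingers × 5.12 s at TR 2 s (256 volumes, 8 min 32 s),
forward (D1→D5) or reverse (D5→D1).  The constructor requires the total
duration to be an integer number of TRs and raises otherwise — some
cycle counts that look innocuous (e.g. 2 cycles of 25.6 s at TR 2 s =
25.6 volumes) are not realizable.  The blocked protocol stimulates each
finger 10 times for 5.12 s with a 2 s pause after 70% of each finger's
trials and a 6 s pause after the rest (208 volumes); the 70/30 mix is
imposed exactly per finger ("counterbalanced across fingers" admits
several readings; exact per-digit proportions is the strictest), and no
finger occurs more than twice consecutively (randomized with bounded
retries).  Stimulus positions are sampled at mid-volume times.

## Hemodynamics and BOLD simulation

The HRF is the canonical double-gamma (peak delay 6, undershoot delay 16,
ratio 6), integrated within each TR on a 16× oversampled grid and
normalized to unit peak.  Neural drive per vertex is a Gaussian in
stimulus space, gain × exp(−(s(t)−x)²/2σ²), in percent-signal units.
Travelling-wave runs are convolved **circularly** (the stimulus is
strictly periodic, so the cyclic convolution is the steady-state
response; this avoids a first-cycle transient that would bias the
fundamental's phase); blocked runs are convolved linearly.  Noise is
additive Gaussian in percent units with optional AR(1) temporal
correlation (stationary SD fixed at `noise_sd`) — the minimal temporally
correlated model; no scanner artifacts (drift, spikes, motion,
physiological regressors) are simulated, so preprocessing robustness is
out of scope and passing tests say nothing about it.  Every generator
draws from one `numpy.random.Generator` seeded per call.

Default study conditions for the generators: 10×10 vertex patch at 1 mm
spacing with the preferred position increasing linearly along rows over
the full axis, tuning widths uniform in [1, 3] units, gains uniform in
[1, 3] % signal, baseline 100; `noise_sd` defaults to 0.5% — a
conservative single-vertex SNR for high-field mapping data.

## Travelling-wave analysis

Per vertex the mean is removed and the DFT taken; the signal bin is the
cycle count.  Noise bins are all bins at or above 0.005 Hz **excluding
the signal bin and its 2nd and 3rd harmonics** — the responses are
periodic but not sinusoidal, and counting harmonic power as noise would
deflate F for exactly the most responsive vertices.  The F-ratio
signal/mean-noise power is distributed as F(2, 2·n_noise) under Gaussian
white noise (each bin contributes two real degrees of freedom), which is
the reference used for p-values; the suite verifies the implied type-I
rate empirically.  A numerically pure sinusoid is flagged `inf`, a
constant series `NaN`.  Response amplitude in percent is
|X| · 4 / N / baseline · 100 (×2 for negative frequencies, ×2 for
peak-to-peak), with the series mean as the baseline brightness.

**Phase convention.**  `phase` is the *delay phase*: the fraction of the
cycle at which the response peaks, in [0, 2π) (the negated DFT angle).
On forward runs it increases D1→D5.

**Phase origin.**  Digit assignment subtracts a phase reference before
binning the cycle into five equal intervals.  For mirror-averaged data
the correct reference is *not* the nominal hemodynamic delay: writing
τ(x) for the within-cycle time at which the sweep reaches a vertex's
preferred position, the forward run's fundamental has delay
τ − TR/2 + λ (mid-volume sampling vs DFT indexing, plus the HRF's
effective delay λ at the cycle frequency), while the time-reversed,
2-TR-shifted reverse run has delay τ − TR/2 − λ + shift.  The complex
average therefore sits at τ + (shift − TR)/2, with λ cancelled — 1 s at
TR 2 s.  `average_mirror_runs` records this value in
`meta['phase_origin_s']` and `assign_digits_from_phase` uses it by
default, falling back to the nominal 4 s when analyzing a raw single
run (for which `hrf_phase_origin_s` computes λ exactly).  With this
bookkeeping, noiseless end-to-end digit recovery is exact, which is the
package's acceptance bar for the convention.

Cluster filtering groups supra-threshold vertices (default p < 0.01) by
edge adjacency and keeps components whose summed vertex area is at least
14 mm².  Winner-take-all labels resolve ties to the lowest digit index.
The cross-subject F-ratio implements its printed formula literally,
(x̄² + ȳ²) / ([Σ(x−x̄)²/n + Σ(y−ȳ)²/n] / (2n−2)); the grouping of that
expression is typographically ambiguous in its source and is flagged as
such.  The dispersion index d = |vector mean| / mean |vectors| is
scale-invariant and bounded in [0, 1].

## pRF modeling

1D Gaussian only (center x ∈ [−12.5, 12.5], width σ ∈ [0.5, 25]; the
lower bound is one tenth of a fingertip interval).  Screening is an
omnibus F-test on five HRF-convolved digit boxcars at p < 0.05
(uncorrected).  Fitting is a coarse grid (25 centers × 12 log-spaced
widths) with gain ≥ 0 and baseline solved linearly per candidate,
refined by bounded nonlinear least squares **multi-started from the best
grid candidates at distinct centers**: with only five distinct stimulus
positions the four parameters are weakly identified and a single start
can converge to a near-degenerate optimum (narrow σ wedged between digit
centers fitting almost as well).  Centers at the extreme ends of the
axis remain weakly identified even noiselessly (only the nearest digit
constrains the Gaussian's tail); recovery tolerances are therefore
quoted for interior centers.  Retention for summaries uses variance
explained (default R² ≥ 0.2, configurable) — a deliberate replacement
for posterior-probability thresholding: this package's estimator is
least squares, and its acceptance surface is parameter recovery, not
posterior calibration.  Digits with no retained fit are reported missing,
never as zero size.

## Geometry

Vertex area is ⅓ of each incident triangle's area (total vertex area
equals total mesh area exactly).  Geodesics are edge-restricted Dijkstra
— deliberately not exact polyhedral geodesics, matching the common
surface-toolbox convention; geodesic ≥ Euclidean always.  Digit "center"
locations are statistic-weighted centroids (the cited convention leaves
the weighting unspecified); "peak" is the max-statistic vertex with ties
to the lowest index.  Dice is 2|A∩B|/(|A|+|B|), NaN when both sets are
empty.

## Similarity

Digit maps are contrasts (own digit +4, each other −1) from an OLS fit
with HRF-convolved regressors; the between-run similarity matrix
correlates run-1 digit i with run-2 digit j over masked vertices.
Neighbor summaries average **ordered** entries by default (5, 8, 6, 4, 2
entries for N0–N4), since the between-run matrix need not be symmetric;
`ordered=False` averages unordered pairs.  Resting cross-correlation is
the Pearson correlation of the overlapping segments at each lag (edge
handling is not standardized in common tools; overlap-Pearson keeps
every lag on the same scale).

## Behavior

Confusion matrices count stimulated × reported digits; zero-error digits
are genuine zeros.  The chance model distributes the observed total of
mislocalizations proportionally to the 8:6:4:2 ordered-pair weights;
fractional expectations are used in tests, rounding is display-only.
The G-test uses 2 Σ O ln(O/E) with the 0·ln 0 ≡ 0 limit and no Williams
correction; families are Holm–Bonferroni corrected.  Signal detection
pools false alarms over all non-target stimulations and applies the
log-linear correction in its standard form (+0.5 to hit/FA counts, +1 to
denominators).  One consequence worth knowing: with equal *raw* hit and
false-alarm rates, the corrected rates differ slightly because the
denominators differ (n trials vs 4n), so d′ is near, not exactly, zero.
β = exp((z_FA² − z_hit²)/2) is exactly 1 whenever |z_hit| = |z_FA|.
Both per-digit and per-total percentage normalizations of the
mislocalization distribution are emitted, as the field uses both.

Staircases implement 3-down/1-up on the discrete filament ladder
(0.008–6.0 g, analyzed in log10(0.1 mg) units), two interleaved runs
starting at 0.4 g and 0.02 g, stopping when the SD of intensities
visited after the first reversal is at most one (mean) ladder step; the
estimate is the mean of those intensities, snapped to the ladder for the
reported weight.  The rule targets the 79.4% correct point
(p³ = 0.5); ladder quantization biases simulated estimates a few percent
below that, which the acceptance script reports rather than hides.
Two-point thresholds are −b₀/b₁ of a binomial GLM; a perfect step
(complete separation, where the MLE diverges) returns the midpoint of
the bracketing distances, and all-same responses are non-estimable.

## Group statistics

Hedges' g = J·d with J = 1 − 3/(4 df − 1); CIs are percentile bootstrap
over 10,000 within-group resamples by default (the interval type is a
package choice; BCa is available behind a flag).  TOST runs two pooled-
variance one-sided tests against raw-unit bounds and reports the less
significant side.  The 33%-power equivalence bounds solve the two-sided,
pooled-df noncentral-t power function for the effect size detected with
power 0.33 — one- vs two-sidedness and the df convention are
configurable package choices, documented here because the procedure's
sources leave them open.  The factor procedure standardizes the data,
fits maximum-likelihood factors with promax rotation (statsmodels
numerics), and removes one variable per refit: first the variable with
the lowest maximal |loading| below 0.4 (ties by input order), then the
worst cross-loader; it terminates because every round removes a variable
or stops, and near-zero specific variances are reported as Heywood
cases.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 10×10 patches,
256/208-volume runs, 4,000–8,000 pure-noise vertices for calibration
rates, 500 observations for factor recovery, 600 trials per pin distance
for threshold recovery, 60 staircase runs — sizes at which Monte-Carlo
error is a small multiple of the asserted tolerances and the whole suite
completes in seconds.  Every stochastic routine takes an explicit seed
and is bit-reproducible given (parameters, seed).

## Limitations

Synthetic patches are flat rectangular grids: no cortical folding, depth
sampling, or inter-subject surface registration, so cross-subject
statistics operate on a shared mesh.  The generators produce stationary
Gaussian (optionally AR(1)) noise — conclusions about robustness to
structured artifacts do not follow.  The pRF model is 1D and the
estimator is least squares, not a posterior; no model-evidence
quantities are produced.  Resting-state simulation specifies
instantaneous correlations only (no lagged structure).  Robust
trimmed-mean ANOVAs and whole-cohort group inferences are out of scope.
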