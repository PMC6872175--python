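# Methods

This note records the models sptkit implements, the defaults it ships,
the numerical choices behind them, and what the synthetic-data tests do
and do not demonstrate about real tracking data.

## Data model and preprocessing

A trajectory is a time-ordered set of 2D positions (μm) on an integer
frame grid with nominal interval `dt` (s). Quantum-dot blinking removes
frames; detections separated by at most 10 missing frames are treated as
one continuous track, longer gaps split the track (`split_at_long_gaps`).
Before analysis, gaps are collapsed by remapping frames onto 0..n−1 and
rebuilding t = frame·dt (`reindex_blink_gaps`); the removed frame indices
are retained as metadata. Collapsing slightly distorts lag times for
heavily blinking tracks — at the default ≤10-frame gaps and the ≥50-frame
length filter the bias on lag-25 MSD is small, but it is a bias; users
with pathological blinking should split rather than collapse. Tracks
shorter than 50 frames are excluded (`filter_min_length`), both for MSD
stability and because RD needs the lag-25 MSD averaged over ≥ N/2 pairs.
Pixel-unit inputs are converted at 0.22 μm/px by default.

## MSD and the fits derived from it

`compute_msd` evaluates the time-averaged MSD over all overlapping pairs
at every lag 1..N−1. Two numerically identical paths are provided: an
explicit per-lag sum (default for N ≤ 1024) and an FFT autocorrelation
evaluation (O(N log N), default above), both verified against a
brute-force double loop to 1e−12.

* `fit_d24`: OLS of msd = 4·D₂₋₄·t + offset over lags 1–4, intercept
  free. Four points give a stable two-parameter fit; the intercept
  absorbs the localization-noise floor (≈ 4σ², i.e. 2.5×10⁻³ μm² at
  σ = 25 nm). The alternative reading of the D₂₋₄ notation (points 2–4
  only) was checked and changes no conclusion in this package's tests.
* `fit_alpha`: bounded nonlinear least squares of msd = 4·D_α·t^α
  (α ∈ [0,2], D_α > 0, initialized at α = 1, D_α = D₂₋₄, a few perturbed
  restarts). The default fits the whole curve. Caveat: the long-lag tail
  of a time-averaged MSD is both noisy and large, so an unweighted
  linear-domain fit weights it heavily; on noise-free Brownian tracks of
  600 frames the median fitted α is ≈ 0.78 rather than 1. The optional
  `max_lag` cap (e.g. N/2, median α ≈ 0.95) removes most of the bias and
  is recommended when α is the quantity of interest; the full-curve
  default is kept because it is the conventional whole-curve procedure
  and comparability matters more than bias for relative comparisons.

## Maximum-likelihood diffusion estimation

Observed displacements of a Brownian track with static localization
error σ and motion-blur coefficient R form a stationary Gaussian process
with per-dimension variance 2DΔt + 2σ² − 4RDΔt and lag-one covariance
−(σ² − 2RDΔt). `DiffusionMLE` maximizes the exact likelihood of this
tridiagonal model over D ≥ 0. The tridiagonal Toeplitz covariance is
diagonalized analytically by the orthonormal type-I discrete sine
transform (eigenvalues a + 2b·cos(πk/(n+1))), so a likelihood evaluation
is O(n log n) and the fit is a bounded 1D search (tolerance 1e−12 on D).
The likelihood was verified against a dense multivariate-normal density,
and the σ = R = 0 limit equals Σ|Δr|²/(4nΔt) exactly.

Defaults: σ = 25 nm (typical quantum-dot localization accuracy; a
per-track σ drawn from a floored Gaussian 25±10 nm is available in the
simulator), R = 1/6 (full-frame continuous exposure), both configurable.
A likelihood maximized at the boundary D = 0 is clamped and flagged, not
an error. The immobile call is strict: D_MLE < 5×10⁻⁴ μm²/s, a value
re-derivable as the 95th percentile of a user's own immobilized-emitter
null via `immobile_threshold_from_null`.

Parameter recovery on simulated data (σ = 25 nm, R = 1/6, D ∈ {0.005,
0.03, 0.1} μm²/s) is unbiased within ~1 % — provided the simulated data
actually contain motion blur. The simulator therefore supports
within-frame sub-position averaging (`SimConfig.blur_substeps`; s
sub-positions give R = (1 − 1/s²)/6, so s = 20 ≈ full-frame exposure).
Fitting blur-free data with R = 1/6 overestimates D by up to ~60 % at
D = 0.1, dt = 0.1 — a model-mismatch effect worth knowing about when
choosing R for a real camera.

## Relative-deviation motion classification

RD(N, n) = MSD(nδt) / (4·D₂₋₄·nδt) at the probe lag n = 25 compares the
observed mid-lag MSD with the Brownian extrapolation of the short-lag
slope: ≈1 for free diffusion, <1 under confinement, >1 under drift. The
null band depends on N, so `calibrate_cutoffs` simulates 1000 noise-free
Brownian tracks per length at N ∈ {100, 200, 300, 400, 500, 600}
(D = 0.1 μm²/s, dt = 0.1 s) and records the empirical 2.5th/97.5th
percentiles of RD(N, 25). A straight line is fitted to the lower
percentiles versus N and a 4th-order polynomial to the upper ones; raw
percentiles, fit coefficients and simulation parameters (including the
seed) are persisted as JSON. Classification: below the fitted lower line
→ restricted; everything else → free. Values above the upper boundary
are deliberately folded into free because directed transport is not
expected for passively diffusing membrane proteins; the upper fit is
retained for audit only. RD is dimensionless, so the boundaries are
insensitive to the calibration D and dt (verified as a property).

Two honest caveats, both verified by simulation:

* The 2.5th-percentile-vs-N curve is concave (RD dispersion shrinks with
  N), so the straight-line boundary undershoots the percentile at
  mid-range lengths and overshoots at the ends. At N = 300 roughly 1 %
  of fresh Brownian tracks fall below the *line*, versus 2.5 % below the
  *raw percentile* by construction. The line is therefore a slightly
  conservative restricted-call boundary at central N; per-length
  specificity is not uniform.
* RD presumes the short-lag slope estimates the microscopic D. When the
  one-frame diffusion length √(2DΔt) approaches the confinement size,
  the MSD saturates by lag 1, D₂₋₄ is noise, and RD is undefined or
  wildly inflated — such tracks are reported unclassifiable or misread
  as free. With the defaults this matters only for domains ≲ 150 nm
  combined with D ≳ 0.1 μm²/s at 10 Hz; faster frame rates restore the
  separation.

## Trajectory geometry

Aspect ratio uses the minimum-area rotated bounding rectangle (shapely's
rotating-calipers implementation), giving rotation invariance; collinear
tracks are flagged degenerate and reported against a 1 μm×10⁻⁶ width
floor. Explored area is the convex-hull area divided by the number of
time points. Both metrics are checked for rigid-motion invariance and
the hull ≤ bounding-box inequality.

## Displacement HMM

Per-frame displacements Δr_t are modelled as isotropic 2D Gaussians
whose per-dimension variance is 2·D_k·Δt for hidden state k (the `DV`
variant adds a per-state mean v_k·Δt), with first-order Markov
switching. Fitting is EM with the scaled forward–backward recursions;
the per-observation emission maximum is factored out so extreme
emission-probability ratios cannot underflow the scaling constants.
Initialization splits displacement magnitudes into K quantile groups
(restarts perturb the group variances log-normally); transition matrices
start sticky (0.9 diagonal). Defaults: 10 restarts, convergence at
log-likelihood gain < 1e−6, 500 iterations max; the log-likelihood is
asserted non-decreasing. Decoding is exact Viterbi. An optional
localization-noise floor adds 2σ² to each state's emission variance
(off by default, matching the plain emission model).

Model selection over K ∈ {1..K_max} and emission forms uses BIC with
(K−1) + K(K−1) + K (+2K for drift) parameters and the displacement count
as sample size. BIC is a deterministic, likelihood-based stand-in for
fuller Bayesian evidence over the same model family; it is conservative
about adding states on short sequences, which suits per-track use. On
simulated data it selects K = 1 for Brownian tracks, collapses
duplicated states, and identifies three well-separated states on
switching tracks; two-state recovery is within 20 % on D with > 85 %
Viterbi frame accuracy at realistic stickiness.

## Group statistics

Metrics are summarized as median with 25–75 % interquartile interval
(linear-interpolation percentile convention — recorded because IQR
endpoints depend on it) and compared with two-sided Mann-Whitney U
(scipy, tie-corrected, exact for small samples) and two-sample KS tests
at α = 0.01. The Mann-Whitney p-value is verified against full
enumeration of rank assignments for group sizes ≤ 8. Supplementary-style
xlsx workbooks (one metric column per group) are read into long format
for re-summarization; a strict mode fails on missing expected columns.

## Synthetic-data generator

The simulator emulates the statistical structure the analysis assumes:
Brownian walks (per-dimension step variance 2DΔt), square-well
confinement (reflective boundaries, stationary-start; long-lag
per-dimension MSD → L²/6), parabolic traps (exact Ornstein–Uhlenbeck
updates, stationary sd = trap_size/4 per dimension so ~95 % of positions
lie within the domain per axis; relaxation rate D/sd²), drift,
Markov-switching diffusivities (stationary-start chains), Gaussian
localization noise, frame blinking in runs ≤ 10 frames, and optional
motion blur by sub-position averaging. All randomness flows from
explicit seeds; fixed seeds give bit-identical output.

It does not emulate: emitter photophysics beyond frame dropout,
localization-error dependence on signal level, 3D motion projected onto
the focal plane, membrane topography, tracking-linkage errors
(mis-connections between nearby particles), or drift of the stage.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data artifacts.

## Problem sizes used in tests

The shipped tests and the reproduction script use 150–1000 tracks per
scenario, track lengths 100–600 (20 000 steps for the confinement
asymptote, where equilibration needs lags ≫ L²/D), and single
trajectories of 1500–3000 steps for HMM recovery — sizes at which the
Monte-Carlo error of each asserted quantity is several times smaller
than its test tolerance.
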