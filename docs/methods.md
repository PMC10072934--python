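# Methods

## Study system emulated by the generator

The pipeline is organised around a three-regime release design for
juvenile Egyptian vultures: wild-hatched birds fledge in summer and
migrate about a month later (observation windows of 9–64 days),
captive-hatched birds are released in spring (104–189 days before
migration) or winter (230–287 days). The synthetic generator's default
group specifications use those window envelopes, the design's sample
sizes (20 wild, 8 spring, 17 winter), and one generating curve family
per group — asymptotic for wild (immediate rise, plateau within about a
week), exponential for spring (slow start, acceleration toward
migration), late-inflection Weibull sigmoid for winter. Durations are
drawn uniformly within each envelope; the published design reports only
means and ranges, and a uniform draw is the least-informative choice
consistent with them.

## Response scale and noise model

All modelling is on log displacement (log km). The generator adds i.i.d.
Gaussian noise on that scale (default residual sd 0.8, matching the
heavy scatter typical of daily-displacement telemetry) and a shared
per-individual Gaussian level offset (default sd 0.4) applied to the
level parameters of the curve (`c`, `a`, `init`/`plateau`,
`lower`/`upper`; multiplicatively to the exponential's `a`, which scales
the whole log-curve). Both are configurable. Displacements are therefore
log-normal and strictly positive. Truth parameters per family are drawn
at magnitudes seen in juvenile vulture telemetry: early displacements
0.3–3 km, terminal daily displacements 8–25 km, rates scaled to the
observation horizon for the slow families.

What the generator does *not* emulate: weather/thermal forcing, diurnal
duty cycles, autocorrelated day-to-day residuals, GPS position error,
or behaviourally realistic within-day paths (simulated fixes follow a
schematic out-and-back track that guarantees only the max-distance
contract). Passing tests therefore demonstrate correctness of the
estimators under a clean version of the stated data-generating
assumptions, not robustness to real-data pathologies such as serial
dependence or heavy-tailed error.

## Preprocessing rules

Sphere model: haversine distance with radius 6 378 137 m (the default of
common geo-distance tooling); configurable. Resampling keeps the
earliest fix in each interval bin (deterministic and order-stable; the
choice within a bin is otherwise arbitrary). Calendar days are UTC days.
Day 1 is the fledging day (first day ≥ 200 m from the nest, inclusive at
exactly 200 m) or the release day. Days whose maximum displacement is
below 1 m are floored at 0.001 km so the log response stays finite; the
floor is configurable and the affected rows keep their fix counts.
"First location of the day" is taken after resampling.

## Curve fitting

Parameterizations are fixed as listed in the README; the Weibull sigmoid
uses the type-1 convention in which `slope < 0` gives an increasing
curve from `lower` (the continuous day→0 limit) to `upper`. Sign
constraints (`b ≥ 0`, `k ≥ 0`, `a ≥ 0` for the exponential,
`plateau ≥ init`, `upper ≥ lower`, `slope ≤ 0`, `t_infl > 0`) guarantee
nondecreasing curves and are enforced as optimizer bounds (rise-to-limit
and sigmoid families are fitted in `(level, gap ≥ 0, …)` coordinates).

Self-starts: null/linear are closed-form; the exponential rate comes
from a log-linear regression of the positive responses; the asymptotic
start takes the plateau from the series tail, the initial level from the
head, and the rate from the day the smoothed series first passes 63% of
the rise, with two deterministic rate-scaled alternative starts guarding
against the `k → 0` quasi-linear ridge; the sigmoid start infers the
inflection and slope from quartile crossings of the smoothed rise and
adds five jittered multi-starts with fixed sub-seeds. L2 fits use
trust-region least squares with analytic Jacobians; tolerances 1e-13.
L1 fits: closed form for the null (median), median quantile regression
for the linear family, and Nelder–Mead polish of the L2 solution for the
nonlinear families (L1 optima can be non-unique; ties are resolved by
whichever candidate attains the lower objective). Convergence flags are
honest — an exhausted iteration budget marks the fit non-converged and
excludes it from selection.

## Likelihood, BIC and selection

For L2 the Gaussian profile likelihood gives
`−2 logL = n·log(RSS/n) + n(1 + log 2π)`; for L1 the Laplace likelihood
with scale set to the mean absolute residual gives
`−2 logL = 2n(1 + log(2·MAE))`. The residual scale counts as one extra
parameter uniformly, so `BIC = −2 logL + (p+1)·log n`; rankings are
unaffected by the convention. A numerically perfect fit (objective
≤ 1e-10) maps to BIC −∞ and sorts as best. BICs are never compared
across objectives: population-level selection uses L1-based BIC for all
families, individual-level selection L2-based BIC for all families.
Selection: among converged fits within 2 BIC units of the minimum, the
fewest-parameter family wins, ties broken null < linear < exponential <
asymptotic < weibull4.

## Crossings and bootstrap

Crossing times are found by bisection on the (monotone) fitted curve to
0.01-day resolution; a curve at or above the threshold from day 0
crosses at the resolution step; ties at the threshold count as reached;
never reaching it within the horizon is a valid absent result. The
bootstrap resamples whole individuals by default (days within a bird are
dependent; row resampling is available), refits the selected family per
replicate, drops and counts non-converged replicates (erroring if more
than half fail), and reports pointwise 2.5/97.5 percentile bands and
crossing-time intervals.

## Variability

The MAD series pools all of a group's displacements in each centred
3-day window (minimum 3 values) — pooling, rather than averaging
per-individual MADs, reflects one variability series per group. The
consistency constant defaults to 1.4826 (Gaussian-sd calibration, the
default of standard MAD implementations) and is recorded on the result.
The temporal smoother is a fixed-df regression on log MAD — an intercept
plus `df` cubic B-spline basis functions (low-order polynomials for
`df < 3`) — not a penalized smoother, since the design specifies degrees
of freedom rather than a penalty; pointwise 95% intervals are Gaussian
OLS prediction intervals for the mean, back-transformed to km. Group
comparison flags per-day CI overlap against a reference group.

## Window mixed model

Within each 20-day window (first 20 days after fledging/release, last 20
before migration; birds need ≥ 9 observed days per window, judged
independently per window), log displacement is modelled as

    y_ij = β_{g(i)}·[1, P1(t_ij), P2(t_ij)] + u_{0i} + u_{1i}·P1(t_ij) + ε_ij

with P1, P2 orthonormal polynomials over days 1–20 (numerical stability;
the estimand is unchanged), per-individual random effects
`(u_0, u_1) ~ N(0, Ψ_g)` with the 2×2 covariance grouped by rearing
type, and `ε ~ N(0, σ_g²)` also grouped. Estimation maximises the
marginal Gaussian likelihood: fixed effects are profiled out by GLS and
L-BFGS-B runs over the per-group log-Cholesky covariance and log-sd
parameters. Reported random-effect covariances are in the orthonormal
basis. Wald CIs use the observed information (finite differences for the
variance parameters). If the full model's likelihood cannot be
evaluated, the model is refitted with intercept-only random effects and
flagged. The group mean over the window is the day-average of
`exp(fitted log curve)` with a delta-method CI — a plug-in
back-transform, deliberately without a lognormal mean correction, so it
estimates the displacement of a typical (median-level) bird; ML point
estimates and Wald intervals also differ by construction from posterior
summaries of the Bayesian analogue of this model. With ~10 individuals
per group these Wald intervals are mildly optimistic (simulated coverage
of 95% intervals is ≈ 91–95%), which is inherent to small-sample ML, not
an implementation defect.

Latency tests exclude birds whose curve never reaches the benchmark
(they are counted and reported separately), use median centring for
Levene's test (the robust Brown–Forsythe form; centring is otherwise a
free choice) and the chi-square approximation with tie correction for
Kruskal–Wallis. On very small groups that approximation is accurate to a
few percent against the exact permutation distribution.

## Problem sizes and determinism

Validation experiments use deliberately reduced designs: recovery
cohorts of 30 birds × 150 days per family, bootstrap calibration with
199 replicates × 200 simulations on 100-bird linear cohorts, window
model calibration with 200 simulations of 3 groups × 10 birds × 20
days, and 1000 null simulations for test size. Every stochastic step
takes an explicit integer seed, and fixed seeds give bit-identical
output.

## Known limitations

- Parameter precision at very low noise is bounded by the information in
  a daily series: with residual sd 0.01, median absolute errors reach
  ~1e-4–1e-3 for null/linear/exponential parameters and rate constants,
  but level parameters of the asymptotic family (~5e-3) and the sigmoid's
  slope and inflection day (~1e-2–3e-2) sit at their Fisher-information
  floor regardless of optimizer quality.
- The L1 objective for nonlinear families is optimised by direct search
  from the L2 solution; it can settle on any of several equal-objective
  median fits.
- CI-overlap comparison of MAD smooths is pointwise, not familywise.
- No outlier filtering of GPS error spikes, altitude handling, or
  behavioural annotation; Argos-style location error is out of scope.
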