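# Methods

## The model

A VO₂ reading `μ` (always L/min) from device `d` is treated as one draw
from a normal test–retest distribution `N(μ, σ_d(μ)²)`, where `σ_d` is a
polynomial (order ≤ 3) in the measured level. This encodes *differential*
measurement error: indirect-calorimetry error scales with gas flow, so a
constant coefficient of variation or standard error — the assumption
behind most single-subject reliability tools — is wrong at both ends of
the flow range. The σ polynomials are calibrated from two-day
repeatability protocols (multiple workloads per subject, each measured on
two separate days), so they capture combined biological day-to-day and
system variability, not instrument noise alone. For the same reason the
model is valid only for *between-day* comparisons; applying it to two
measures taken in one session overstates the error.

Two readings are compared by the overlapping coefficient of their two
densities, OVL = ∫ min(f₁, f₂) dx, read as the probability that they are
the same measurement. For two normals the OVL is computed analytically:

* equal σ: the densities cross once, midway between the means, and
  OVL = 2·Φ(−|μ₁−μ₂| / 2σ);
* unequal σ: the two crossing points are the roots of the quadratic
  obtained by equating log-densities; the OVL is the sum of three CDF
  segment probabilities, with the minimum density on each segment chosen
  by evaluating both **log**-densities at an interior probe point
  (log-scale comparison, because for well-separated distributions both
  raw densities underflow to zero at a probe and a naive `<=` tie then
  misclassifies every segment).

The equal-σ branch triggers at |σ₁−σ₂| ≤ 1e−12·max(σ₁,σ₂), where the
two-crossing geometry degenerates. Arguments are put in a canonical order
first, which makes the result bitwise symmetric in the two (value,
system) pairs. A brute-force trapezoidal integration (support
min(μ)−8·max(σ) to max(μ)+8·max(σ); truncated tail mass < 1e−15) is kept
in the package purely as an independent oracle; the analytic and grid
paths agree to ≤1e−5 at grid step 1e−4 across randomized sweeps.

## Verdicts

A similarity probability below the threshold (default 0.10) is labeled
"truly different", otherwise "not distinguishable"; a probability exactly
at the threshold is not below the bar and is therefore not
distinguishable. The threshold is a user decision, not a property of the
devices. Displayed probabilities are rounded to 3 decimals (1 decimal on
the percent scale); stored values keep full precision. For a cohort, the
*net probability of similarity* is the plain arithmetic mean of the
per-subject probabilities, paired by position.

## Shipped calibrations: an inverse problem

The coefficients of the original ParvoMedics 2400 TrueOne and Douglas-bag
regressions were fit to third-party raw repeatability data that was never
published — but several overlap values computed *from* them were. The
shipped defaults are therefore recovered by inverting those printed
numbers (the constraint table in `vo2overlap/data/`):

* **parvo_2400** — linear σ(μ) = c₀ + c₁μ. Only two independent
  same-system constraints exist (a cubic would be wildly
  underdetermined), and two equations in two unknowns are solved exactly
  by a multivariate root-find whose residuals pass through the analytic
  OVL; both constraints are reproduced to ≤1e−6. Recovered:
  σ(μ) ≈ 0.01915 + 0.02638·μ.
* **douglas_bag** — cubic σ(μ), matching the order used in the original
  calibration procedure. Five same-system constraints are available (two
  worked examples plus three distinct baseline/follow-up pairs from a
  published longitudinal re-analysis that assumed gold-standard
  Douglas-bag methodology; one follow-up pair is printed twice and enters
  once). Four parameters against five constraints are fit by
  `scipy.optimize.least_squares` (tolerances 1e−14, no randomness),
  seeded from equal-variance inversions σ = Δ/(2·Φ⁻¹((1+OVL)/2)·(−1)) at
  each constraint's midpoint, with a penalty keeping σ ≥ 0.001 on
  [1.0, 4.0] L/min. Constraint RMSE at the solution ≈ 3e−5.

The one published **cross-system** comparison (3.0 L/min Douglas bag vs
3.3 L/min ParvoMedics, OVL 0.231) is excluded from both fits and used as
an out-of-sample check: the recovered calibrations predict 0.216, within
the ±0.05 band expected from recovery uncertainty.

The recovery is deterministic (fixed seeding rule, fixed tolerances), and
the packaged `default_calibrations.yaml` is exactly its output;
`vo2overlap recover-defaults` regenerates it byte-identically.

Known wrinkle: the near-exact Douglas cubic peaks at μ ≈ 3.22 L/min and
declines ≈2% by 3.5. A globally non-decreasing cubic cannot reproduce all
five printed values this closely (forcing monotonicity degrades the
constraint RMSE by two orders of magnitude), so fidelity to the published
numbers was preferred; σ still rises strictly from the low-flow to the
high-flow worked examples, which is the physically meaningful trend.

## Ranges and validation

Inputs are hard-limited to 0.3–6.0 L/min (physiologic envelope from
resting to elite maximal uptake). The shipped calibrations carry a
validity range of [1.0, 4.0] L/min — a declared assumption modestly
extending the 1.5–3.5 span of the examples they were recovered from,
since the domain of the underlying protocol is not published. Between the
validity range and the envelope the polynomial is extrapolated with a
warning. Unknown device identifiers raise immediately with the list of
known devices (only an *omitted* system argument falls back to the
ParvoMedics default). A calibration that evaluates to σ ≤ 0 anywhere it
is used raises rather than returning a degenerate distribution.

## Fitting your own calibration

`fit_calibration` / `vo2overlap calibrate` run ordinary least squares of
the pair SD on powers of the pair mean — one point per subject-workload
test–retest pair, each pair summarized by its mean and its n−1 SD
(= |d₁−d₂|/√2). The regression needs at least order+1 distinct mean
levels; the fitted calibration's validity range is the observed mean
span, positivity is verified over it, and the fit diagnostics (n, RSS,
span) are recorded in the calibration's provenance field. The estimator
behind it (`SigmaPolynomialRegression`) follows the scikit-learn API, so
it can be cloned, pipelined and cross-validated like any regressor.

A statistical caveat inherited from the underlying procedure: the SD of a
*two-value* pair is a half-normal variable with mean √(2/π)·σ ≈ 0.798σ,
so this regression consistently estimates √(2/π)·σ_true rather than
σ_true. The shipped defaults are unaffected (they are recovered from
overlap values, not refit from raw data), but parameter-recovery
simulations must compare the fitted curve against √(2/π)·σ_true — and the
package's tests do.

## Synthetic protocol generator

`SyntheticProtocol` / `generate_test_retest` emulate the two-day,
multi-workload protocol: each subject × workload yields two independent
draws from `N(X, σ_true(X))` with a polynomial σ_true, truncated at zero
by resampling (a deliberate deviation from a pure normal, relevant only
at extreme noise). Defaults: 7 workloads at 1.0–4.0 L/min in 0.5 steps,
10 subjects, cubic noise model (0.02, 0.01, 0.005, 0.001) giving
σ_true ≈ 0.04 L/min at 1 L/min rising to ≈ 0.20 at 4 L/min — the
magnitude and growth typical of day-to-day VO₂ repeatability. The true
workload grid and subject count of the original protocol are not
published, so these are configurable defaults, not a reconstruction. The
generator captures flow-dependent noise but not subject-level workload
variation (every subject hits the same true VO₂ grid), drift between
days, or non-normal error tails — so passing recovery tests demonstrate
correctness of the fitting machinery, not realism of any one device.

With two observations per pair, single-replicate SD points are very noisy
(SD of the pair SD ≈ 0.6σ); at 500 pairs over 5 workloads a single
replicate's fitted curve can deviate >10% pointwise from its estimand, so
the recovery check uses the pointwise **median** curve across 20 seeded
replicates, which sits within ~4% of √(2/π)·σ_true on the central 80% of
the flow range.

## Problem sizes and tolerances used in the checks

Oracle equivalence: 1000 randomized parameter sets (μ ∈ [0.5, 4.5],
σ ∈ [0.03, 0.4], every fifth set equal-σ), analytic vs grid step 1e−4,
tolerance 1e−5; equal-σ closed form to 1e−12. Parameter recovery: 20
replicates × 500 pairs as above; noiseless polynomial data must
round-trip coefficients to 1e−10 (exact linear algebra). Worked examples:
ParvoMedics to 1e−3 (solved exactly), Douglas bag to ±0.03 (within its
least-squares residual), re-analysis percentages to ±3 points, holdout to
±0.05. Everything runs in seconds on one CPU.

## Limitations

* Only VO₂ in L/min; no body-mass normalization, no VE/VCO₂ defaults
  (the fitting API is variable-agnostic, so users with repeatability data
  for those signals can register their own calibrations).
* Two shipped devices; the defaults are inverse-recovered, not the
  original coefficients, and agree with the printed record only as well
  as the constraints determine them (the cross-system holdout above
  quantifies this).
* Day-to-day comparisons only; no hypothesis testing, confidence
  intervals, or clinically-meaningful-change thresholds.
* Normal error family only, univariate only.
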