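# Methods

## Model and assumptions

Each subject in arm `j ∈ {1, 2}` contributes one count `X ~ Po(λⱼ)` accrued
over a fixed, common observation period.  Analyses happen after every `n`
subjects per arm; the design allows up to `K` analyses, with equal
allocation between arms and complete outcome accrual between looks.  The
null hypothesis `λ₁ = λ₂` and the powered alternative `λ₁ = λ₂ + δ` are
both composite over closed rate intervals `Λ₀` and `Λ₁`, reflecting
uncertainty about the control rate; `δ > 0` encodes an anticipated rate
reduction on the treatment arm, and `δ < inf(Λ₁)` keeps the treatment rate
positive.  Out of scope: unequal allocation, variable observation times,
inference after stopping, and tests conditional on the total event count.

## Exact engine

The stage increment `T̃_k = Y₁k − Y₂k` is Skellam; the test statistic is
the running sum `T_Sk`.  Because the increment support is unbounded, the
full distribution of `T_Sk` is not computable, but its sub-density
restricted to "the trial is still running" is, by a finite recursion over
the previous continuation region `[a_{k−1}, r_{k−1})`.  The recursion is
evaluated once per stage as a vector convolution and cached per
`(n, boundaries, rates)`; acceptance/rejection probabilities are weighted
Skellam cdf/sf tail sums against the cached sub-density.

**Skellam evaluation.**  The pmf uses the exponentially scaled Bessel
function (`ive`) so the `e^{−n(λ₁+λ₂)}` prefactor is applied in log space;
nothing overflows for stage means of at least `1e4`.  The cdf goes through
the noncentral-χ² relation (each tail on its own branch, so small tail
probabilities keep absolute accuracy ~1e-12 — important because the
exhaustive search thresholds tails at `ε = 1e-7`).  A truncated-summation
fallback (window `± max(40σ, 50)` around the mean, neglected mass below
1e-300) provides an independent route, cross-checked in the tests to 1e-10.

**Maximal error rates.**  The rejection/acceptance totals have no known
monotone or unimodal structure in the shared rate, so maxima over `Λ₀`/`Λ₁`
use a 21-point equispaced scan plus bounded Brent refinement in the best
bracketing subinterval (absolute tolerance 1e-6 in λ).  A single Brent call
could miss a mode; the multi-start scan makes that practically impossible
at the printed 3-decimal precision.  Degenerate intervals are evaluated
directly.  Threshold decisions ("is the max ≤ π?") short-circuit as soon as
any grid value exceeds the threshold, then fall back to the same full
maximization, so search and verification always agree.

## Normal engine

With information `ℐ_k = kn/(λ₁+λ₂)`, the Wald statistics follow the
canonical joint normal law (covariance `√(k₁/k₂)`).  Rather than generic
multivariate rectangle quadrature, the implementation uses the Markov
structure: `S_k = √k · T_Wk` is a random walk with iid
`N((λ₁−λ₂)√ℐ₁, 1)` increments, and stage probabilities follow from a
Gauss–Legendre density recursion (96 nodes per continuation interval).
This is deterministic and accurate to ~1e-12, well inside the 1e-6 target;
tests cross-check it against `scipy.stats.multivariate_normal` rectangles.
Under the null the law does not depend on the shared rate, so the type-I
error is evaluated at the `Λ₀` midpoint (a fixed convention; any point
gives the same value to 1e-6, asserted in tests).  The type-II error is
maximized at `sup(Λ₁)`, where information is smallest; no search is run.

## Boundary derivation by error spending

Within stage `k` the efficacy boundary is solved first (it needs only the
previous stages' boundaries), then the futility boundary:

* exact: `r_k` = smallest integer with max-over-`Λ₀` stage-k rejection
  ≤ `π_Rk`; `a_k` = largest integer with max-over-`Λ₁` stage-k acceptance
  ≤ `π_Ak`.  Integer roots come from bracketed bisection on the monotone
  stage-spending function, started at the normal-approximation solution and
  widened geometrically.
* normal: the same solves with real roots (Brent's method, xtol 1e-12),
  type-I at the fixed null rate and type-II at `sup(Λ₁)`.

The final stage uses the rejection solve and sets `a_K = r_K`, which
guarantees type-I control at `α` by construction.  Edge cases return an
`Infeasible` value rather than raising: a zero spending entry at a stage
that still needs a finite boundary, rejection spending exceeding the
probability of reaching the stage, and a spending-implied `a_k ≥ r_k`
(no continuation region left).

**Group size.**  `β′(n)` is not known to be monotone for the exact engine,
so the group-size search is a plain upward scan `n = 1, 2, …, n_cap`
returning the first `n` whose derived design meets `β′ ≤ β`.  The default
cap is twice the fixed-sample group size.

## Design optimality

Designs are ranked by `w₁·ESS(λ_ESS, λ_ESS) + w₂·ESS(λ_ESS, λ_ESS−δ) +
w₃·2Kn` with `w₁ + w₂ > 0` (the maximal sample size alone cannot separate
designs).  The near-optimal search fits every spending plan on a grid and
sorts by score; ties break by smaller `2Kn`, then smaller `n`, then
lexicographically smaller `π_R`.  The packaged grids are the study
defaults: stage-1 allocations `π_A1 ∈ {0.02, …, 0.18}`,
`π_R1 ∈ {0.005, …, 0.045}` for two stages, and
`(π_A1, π_A2) ∈ {0.03, 0.06, 0.09, 0.12}²`,
`(π_R1, π_R2) ∈ {0.01, …, 0.035}²` for three.

**Exhaustive two-stage search.**  For each `n ≤ 1.5·n_fixed` the stage-1
boundaries are boxed by `a*` (largest integer whose stage-1 acceptance
probability is ≤ ε everywhere on `Λ₀`) and `r*` (smallest integer whose
stage-1 rejection probability is ≤ ε on `Λ₁`), with `ε = 1e-7` by default:
`a₁ ∈ [a*, r*−2]`, `r₁ ∈ [a₁+2, r*]`, and the final boundary
`a₂ = r₂ ∈ [a₁+a*, r₁+r*]`.  The box description does not pin down `r₂`;
this implementation takes the smallest integer in the box with `α′ ≤ α`
(one consistent reading — it spends the remaining type-I budget fully,
mirroring the `a_K = r_K` rule) and then checks `β′ ≤ β`.

Two structural facts make the search fast without changing its result.
First, for `K = 2` a trial that continues always stops at stage 2, so
`ESS = 2n(2 − p₁)` with `p₁` the stage-1 stopping probability — the
criterion depends only on `(n, a₁, r₁)`, never on the final boundary.
Candidates are therefore sorted by score and checked for feasibility in
that order; the first feasible candidate is the optimum.  Second,
feasibility is pre-screened on a small fixed grid of rates (5 points per
interval).  A grid maximum never exceeds the interval maximum, so the
screen is conservative: every truly feasible candidate survives it, and
survivors are re-verified with the full multi-start/Brent maximization.
The tests confirm the search against an independent plain-loop brute force
on a small problem, and against a widened-ε run (enlarging the box can
only improve the optimum).

## Simulation

Trials are simulated from stage totals `Y_jk ~ Po(nλⱼ)` directly
(sufficient statistics; identical in distribution to per-subject draws).
All replicates are drawn in one vectorized pass from a single seeded
generator, with a fixed draw shape, so results are bit-for-bit reproducible
given `(design, rates, replicates, seed)` and independent of the stopping
pattern.  For normal-engine designs a stage with zero events on both arms
leaves the Wald statistic undefined; the statistic is set to −∞ (the accept
branch) and the event is logged.  The empirical-validation workflow
(`gspoisson validate`) defaults to 10⁴ replicates per scenario — enough to
resolve error-rate deviations of order 0.01 at desk scale; the replicate
count is a flag.

## Defaults and units

| parameter | meaning | default |
| --- | --- | --- |
| `alpha`, `beta` | maximal type-I error, 1 − power | problem-specific (example: 0.05, 0.2) |
| `lambda_ess` | arm-1 rate (events/period) for ESS reporting | problem-specific |
| `epsilon` | stage-1 tail bound delimiting the exhaustive box | 1e-7 |
| `n_max_factor` | group-size cap as a multiple of the fixed-sample size | 1.5 (exhaustive); 2 (spending scans) |
| quadrature nodes | Gauss–Legendre points per continuation interval | 96 |
| rate-maximization | grid points / Brent tolerance | 21 / 1e-6 |
| replicates | Monte Carlo validation sample size | 10⁴ |

Reported tables round error rates and power to 3 decimal places, expected
sample sizes to 1, and real boundaries to 2; records keep full precision.

## What the example shows — and does not

The packaged moderate-OSAH problem exercises every code path at realistic
trial scale (stage means up to ~900 events, boundaries spanning hundreds of
integers).  Reproducing its design table checks the exact recursion, both
boundary solvers, and both search strategies end to end.  It does not
exercise overdispersed counts, unequal allocation, delayed outcomes, or
rates so small that the normal engine's asymptotics fail badly — the
simulation module exists precisely to quantify that last gap for any
specific design.

## Known limitations

* Exhaustive search is implemented for `K = 2` only; the design space grows
  as a 2K-dimensional integer box and the spending-grid search is the
  intended tool for `K ≥ 3`.
* Maximal error rates rely on a numerical one-dimensional search; there is
  no analytic guarantee about the location of the maxima, and stage-wise
  maximization can make spending-derived designs mildly conservative (the
  maximizing rate need not be shared across stages).
* The normal engine controls error rates only asymptotically; its empirical
  error rates can exceed nominal levels for small `nλ`.
* Spending vectors with zero entries at interim stages are rejected as
  infeasible rather than interpreted as "no stopping at this look".
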