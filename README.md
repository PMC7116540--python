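# gspoisson

Group sequential designs for two-arm experiments with Poisson distributed
outcomes: exact and normal-approximation operating characteristics,
error-spending stopping boundaries, and optimal design search.

## The problem

Count endpoints are everywhere in experimental design — seizure counts in
epilepsy trials, relapse counts in multiple sclerosis, exacerbations in
asthma, the apnea-hypopnea index (AHI) in sleep studies.  A two-arm trial
compares rates `λ₁` (control) and `λ₂` (treatment), with each subject's
count `X ~ Po(λⱼ)` over a fixed observation period.  A *group sequential*
design analyses the data at up to `K` planned looks, after `n` subjects per
arm per stage, and may stop early for efficacy or futility — cutting the
expected sample size (ESS) substantially relative to a fixed-sample trial.

The null hypothesis is composite, `H₀: λ₁ = λ₂ ∈ Λ₀`, and the trial is
powered over `λ₁ = λ₂ + δ ∈ Λ₁`, because in practice the control rate is
only known to lie in a range.  At each stage `k` a statistic `T_k` is
compared with boundaries: stop and reject `H₀` if `T_k ≥ r_k`, stop and
accept if `T_k < a_k`, continue otherwise; `a_K = r_K` forces a final
decision.

## Two engines

**Exact.**  The stage-wise difference of arm totals
`T̃_k = Y₁k − Y₂k`, `Y_jk ~ Po(nλⱼ)`, has a Skellam distribution with pmf
`g(t) = e^{−n(λ₁+λ₂)} (λ₁/λ₂)^{t/2} I_{|t|}(2n√(λ₁λ₂))`.  The running sum
`T_Sk = T̃₁ + … + T̃_k` is the test statistic.  Its sub-density on the
continuation region satisfies

    h₁(t) = g(t),    h_k(t) = Σ_{s=a_{k−1}}^{r_{k−1}−1} h_{k−1}(s) g(t − s),

which is enough to compute every stage-wise acceptance/rejection
probability, the maximal type-I error `α′ = max_{λ∈Λ₀} Σ_k R_k(λ,λ)`, the
maximal type-II error `β′ = max_{λ∈Λ₁} Σ_k A_k(λ,λ−δ)`, and
`ESS = 2n Σ_k k (A_k + R_k)` — all exactly, with guaranteed error control.

**Normal approximation.**  The Wald statistics
`T_Wk = (λ̂₁k − λ̂₂k) √(ℐ_k)` at information levels `ℐ_k = kn/(λ₁+λ₂)`
follow the canonical joint multivariate normal law with covariance
`√(k₁/k₂)`; rectangle probabilities give the same operating characteristics
asymptotically, with real-valued boundaries.

**Boundaries by error spending.**  Vectors `π_R` (summing to α) and `π_A`
(summing to β) allocate the error budgets across stages and determine the
boundaries recursively; the group size is the smallest `n` meeting
`β′ ≤ β`.  Searching a grid of spending vectors under the criterion
`w₁·ESS(null) + w₂·ESS(alt) + w₃·2Kn` yields near-optimal designs; for
`K = 2` an ε-bounded exhaustive integer search finds optimal exact designs.

## Worked example

A hypothetical moderate obstructive sleep apnea trial (AHI endpoint):
control rate anywhere in `Λ₀ = Λ₁ = [15, 30]` events/hour, powered for a
reduction of `δ = 2.25`, with `α = 0.05`, `1 − β = 0.8`, and ESS reported at
a control rate of 15.

```python
import gspoisson as gp
from gspoisson import reporting

problem = gp.moderate_osah_trial()
plan = gp.SpendingPlan(pi_A=(0.1, 0.1), pi_R=(0.015, 0.035))
design = gp.find_group_size(plan, problem, "exact", n_cap=80)
print(reporting.render_table([reporting.design_record(design, problem, plan=plan)]))
```

prints

```
 K       pi_A           pi_R  n         a          r alpha_max power ess_null ess_alt  max_n
 2 (0.1, 0.1) (0.015, 0.035) 40 (28, 116) (107, 116)     0.049 0.801     97.0   132.8    160
```

Read: splitting both error budgets evenly across two stages needs 40
subjects per arm per stage.  The trial stops at the first look if the
cumulative count difference is below 28 (accept) or at least 107 (reject),
and decides at 116 otherwise.  The maximal type-I error is 0.049 and power
0.801 — both controlled exactly — and under the null the trial enrolls 97.0
subjects on average versus 146 for the single-stage design (n = 73 per
arm), a 34% saving, at the cost of a maximal sample size of 160.

The same is available from the shell:

```bash
gspoisson design --K 2 --engine exact \
  --lambda0-min 15 --lambda0-max 30 --lambda1-min 15 --lambda1-max 30 \
  --delta 2.25 --alpha 0.05 --beta 0.2 --lambda-ess 15 \
  --piA 0.1,0.1 --piR 0.015,0.035
```

`gspoisson validate` estimates a design's stopping rates by simulation, and
YAML configs (`--config`) drive grid or exhaustive searches reproducibly.

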