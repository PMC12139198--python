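# Methods

## Decision problem and model

The package addresses the adoption decision for a new health technology A
against an incumbent B. All value is monetary: a QALY is valued at the
decision maker's willingness to pay `WTP`, so patient `i`'s net monetary
benefit is `WTP × qaly_i − cost_i`. The trial recruits in pairwise
allocations and the inferential target is the population mean per-pair
incremental NMB, `W`. Adoption of A is worth `P·W − C` to the system
(`P` patients affected, one-off switching cost `C`); the status-quo rule
adopts A iff `P·μ > C`, with ties resolved to the incumbent.

Sampling model: pair differences are i.i.d. `N(W, σ²)` with `σ` treated as
known throughout design and boundary computation (a plug-in, typically the
`n−1` sample SD of observed pair differences or a pilot estimate). The
prior is `W ~ N(μ₀, σ²/n₀)` with real-valued effective size `n₀`; the
posterior after `n` pairs has mean `(n₀μ₀ + Σx)/(n₀+n)` and effective size
`n₀+n`. The preposterior SD of the posterior mean after `m` further pairs
is `σ·√(m/(n_eff·(n_eff+m)))`, the quantity on which every value-of-
information formula rests.

Pairs are assumed independent; within-pair correlation (e.g. from
stratified randomisation) is not modelled. Bootstrap evaluation resamples
pairs, not individual patients, so the pair is the exchangeable unit
everywhere.

## Value of information

With `d = μ − C/P`, `s` the current posterior SD of `W`, and
`L(z) = φ(z) − z(1−Φ(z))` the unit normal loss:

- `EVPI = P · s · L(|d|/s)`
- `EVSI(m) = P · s_m · L(|d|/s_m)` with `s_m` the preposterior SD
- `ENBS(m) = EVSI(m) − c·m − fixed_cost·1{m>0}`

The fixed trial cost is charged only when a trial is actually run, so
"no trial" always has ENBS zero. The optimal one-stage size is found by
exhaustive integer scan (ties to the smaller size); the scan never assumes
unimodality because the fixed cost puts a step at `m = 1`. With a single
scalar unknown, the expected value of partial perfect information
coincides with EVPI and is intentionally not a separate function.

## Sequential design under delay

Outcomes lag recruitment by a fixed `Δ` pairs (steady-state recruitment;
ramp profiles are out of scope), giving three stages: recruitment before
any outcome (I), recruitment with accruing outcomes and stop/continue
decisions (II), and pipeline follow-up after recruitment stops (III).
Stopping at `n` observed pairs therefore still observes `Δ` more pairs
before the decision; the stop value is the closed-form preposterior
expectation `P·[d·Φ(d/s_Δ) + s_Δ·φ(d/s_Δ)]` with
`s_Δ = σ·√(Δ/(n_eff·(n_eff+Δ)))`.

Backward induction runs over observed-pair stages `n = T−Δ` down to 0 on
an evenly spaced posterior-mean grid:

    V_n(μ) = max( stop_value(μ), −c + E[V_{n+1}(μ′)] )

with `μ′` one-pair-preposterior normal around `μ`. The expectation uses
Gauss–Hermite quadrature (default 21 nodes) with linear interpolation of
`V_{n+1}`; quadrature nodes outside the grid fall back to the closed-form
stop value, which is asymptotically exact far from the threshold. One
observed pair per stage is the finest granularity the model defines;
coarser interim cadences are a monitoring-time concern, not a solver
concern.

Numerical choices:

- Grid default: 801 points spanning 6 prior SDs beyond both the prior mean
  and the threshold (`GridSpec.from_prior`); at least 201 points are
  enforced. If the continuation region ever touches the grid edge the
  solver raises rather than silently truncating the boundary.
- Tie-break: when continuing and stopping are exactly equal, stop — this
  avoids boundary chatter and favours the cheaper action.
- Linear interpolation of a convex value function biases the value
  slightly upward; on the standard test design the value changes by
  well under 0.1% when the 1601-point grid and quadrature order are
  doubled, and the solver is validated against an exact (grid-free)
  recursion over a 3-point outcome tree on small instances, as well as
  against a 10,000-path Monte Carlo rollout of the computed policy.
- Sunk costs: the Stage I sampling cost `c·Δ` and the fixed trial cost do
  not affect the stopping rule and are excluded from the recursion; they
  are subtracted only when design regimes are compared and in reports.

Regime classification compares, for each candidate prior mean, (i) the
immediate adoption value, (ii) that value plus the best one-stage ENBS,
and (iii) the sequential value net of `c·Δ` and the fixed cost, with ties
broken adopt > one-stage > sequential. Scanning the prior mean across the
grid yields the thresholds `B ≤ D ≤ C ≤ A` (adopt-B below B, sequential
between D and C, adopt-A above A, one-stage in the two bands between). A
non-nested pattern triggers a warning with the raw table attached —
never a silent reordering. Because "run no trial and keep the incumbent"
is exactly the adopt-B action under the status-quo decision rule, no
distinct "no trial" regime label exists.

## Monitoring and evaluation

Interims are evaluated at multiples of `interim_every_k` observed pairs
(default 10), starting at `min_pairs_first_interim` (default 20, i.e. the
first scheduled look is skipped for data sparsity; both configurable), and
always at the forced final stage `T−Δ`. The first interim at which the
posterior mean is on or outside the boundary (or at which the continuation
region is empty) halts recruitment; total recruitment is
`min(n_stop + Δ, T)`.

Operating characteristics over simulated or bootstrapped paths: expected
recruited pairs; expected cost `c·E[pairs] + fixed`; probability
cost-effective (fraction of paths whose final posterior mean exceeds
`C/P`); and expected net benefit. Net benefit values the decision actually
taken — `P·max(final_μ − C/P, 0) − trial_cost` — so a trial that correctly
rejects a non-cost-effective technology contributes zero population value
minus its costs; the "signed" alternative `P·final_μ − trial_cost` is also
computed for audit, since either reading is defensible. Frequentist
summaries (power curve, bias of the final posterior mean) are produced by
simulation per true-mean grid point; no bias adjustment of
early-stopped estimates is attempted.

Randomness contract: one root seed; replicate `i` draws from a stream
derived from `(seed, i)`, so results are independent of evaluation order.

## Synthetic data

The generator emulates per-patient QALY and care-cost outcomes: normal
QALYs, normal or gamma costs (gamma is the realistic right-skewed default
for the packaged fixture), coupled by a Gaussian copula at a configurable
correlation. It matches the first two moments of the per-pair INMB
difference exactly in expectation, which is all the normal-conjugate
model consumes. It does **not** emulate missingness, censoring,
longitudinal QALY accrual, or within-pair dependence — so passing tests
demonstrate correctness of the design machinery under its own
assumptions, not robustness to real-data pathologies (except that the
gamma option deliberately violates exact normality of pair differences at
the patient level).

### The packaged case-study-scale fixture

`hero_like_fixture()` mirrors the printed design parameters of a published
hand-osteoarthritis evaluation: WTP £30,000/QALY, maximum 124 pairs,
interims every 10 pairs with the first skipped, prior effective size
`n₀ = 2`, and an outcome delay of 74 pairs. The economics not printed in
that source were fixed once on an analytic calibration: with an
indifferent prior (`μ₀ = 0`) and per-pair SD `σ = 15,000`, setting
`dEVSI/dm = c` at `m ≈ 177` pairs gives `P ≈ 11,000` at `c = £1,500` per
pair; the fixed cost £650,000 completes a total cost near the published
trial budget at its original size. The arm models (QALY SD 0.35, gamma
costs, correlation −0.3, true mean difference £200 against a pair SD of
about £15,000) encode the weak cost-effectiveness signal characteristic of
that case study. The fixture claims scale fidelity only — it reproduces no
real-trial results, and its dataset is synthetic and seed-fixed.

## Problem sizes used in checks

The standard verification design uses `T = 166`, `Δ = 30`, `σ = 10,000`,
`n₀ = 2`, `P = 10,000`, `c = 1,000` with the maximum sample size set at
the one-stage ENBS optimum, mirroring how the case studies capped their
sequential designs. Monte Carlo cross-checks use 10⁵ draws for the VoI
closed forms, 10⁴ rollout paths for the dynamic-programming value, 2,000
paths for decision recovery, and 5,000 bootstrap replicates for the
fixture pipeline.

## Known limitations

- `σ` is fixed during the dynamic programme; re-estimating it at interims
  is a monitoring-time option the solver does not model.
- No discounting, patent-period effects, or time-varying `P`.
- Early stopping biases the final posterior mean (visible in the
  frequentist bias column); no correction is applied.
- The one-stage comparison ignores the delay (results simply arrive after
  recruitment ends), consistent with its fixed-sample framing.
- The boundary is computed on a grid; reported threshold and boundary
  values are grid points, accurate to one grid step.
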