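# Methods

## Generative model

Each simulated trial is a balanced two-arm cluster randomized design:
`n2` clusters of constant size `n1`, randomized 1:1 (the intervention
arm receives the extra cluster when `n2` is odd; which physical
clusters land in which arm is re-randomized every replication).
Outcomes follow

    Y_ij = β0 + β1 D_ij + β2 X_ij + u_j + e_ij,

with `u_j ~ N(0, ρ·v)`, `e_ij ~ N(0, (1−ρ)·v)` independent, total
residual variance `v = τ² + σ²` equal to 1 by default so that
`β1 = 0.2` is a standardized effect size. `ρ` is the intraclass
correlation *conditional on* `D` and `X`. `β0 = 0` by default: every
estimator considered is location-invariant, so the intercept carries no
information and any other choice would only shift all outcomes.

Compliance has two strata: compliers (`D = Z`) and never-takers
(`D = 0` whatever `Z`). Always-takers and defiers are excluded —
the simulated trials restrict access to the intervention, so nobody in
the control arm can receive it. Consequently `D = Z·C` elementwise and
the control arm is always analysed exactly as randomized. Because
outcomes are generated from `D`, an intervention-arm never-taker's
outcome follows the same law as a control subject with the same
covariate: the IV exclusion restriction holds by construction rather
than by assumption.

Never-taker status is driven by a baseline covariate `X` with unit
marginal variance:

* cluster-level non-compliance: one standard-normal draw per cluster,
  shared by its subjects, and one Bernoulli draw per cluster;
* subject-level non-compliance: `X_ij = B_j + W_ij` with
  `B_j ~ N(0, ρ)`, `W_ij ~ N(0, 1−ρ)` (the covariate inherits the
  outcome's ICC), and independent per-subject Bernoulli draws.

The never-taker probability is `0.5·p̄ / p̄ / 1.5·p̄` in the three
tertile bands of the standard-normal distribution. Bands are
left-closed (`[z_{1/3}, z_{2/3})` is the middle band) — a measure-zero
convention fixed for determinism. Under subject-level non-compliance
the cutoffs are still the *marginal* standard-normal tertiles, which is
exact because `B_j + W_ij` remains standard normal. Since the bands
have equal mass and the multipliers average to one, the marginal
never-taker probability equals `p̄`, and `p̄ ≤ 0.5` keeps all band
probabilities valid.

## Design rule and grid

The number of clusters per design cell solves the design-effect
sample-size formula

    n2 = 4·v·(1 + (n1−1)ρ)/n1 · ((q_{1−α/2} + q_{power}) / β1)²

rounded up, first with standard-normal quantiles, then re-evaluated
once with Student-t quantiles at `df = n2 − 2` and rounded up again.
The one-step t refinement acknowledges that the treatment effect in a
CRT is judged against a t reference with cluster-level degrees of
freedom; it raises the nine-cell grid from 35–150 to 38–152 clusters.
A `quantile_mode="normal"` flag preserves the one-stage rule for
comparison. Rounding up makes realized power slightly exceed the 80%
target, more so in cells where the ceiling bites harder. The rule is
applied under full compliance — non-compliance is deliberately ignored
at the planning stage, as it usually is in practice.

Default grid: `ρ ∈ {0.025, 0.05, 0.1}` × `n1 ∈ {10, 20, 50}` ×
level ∈ {cluster, subject} × `p̄ ∈ {0, 0.1, …, 0.5}` = 108 conditions,
deterministically ordered, each with a stable `condition_id`.

## Estimators

ITT, AT and PP fit the random-intercept model by REML (restricted
likelihood, because it debiases variance components when the number of
clusters is modest), differing only in the treatment regressor (Z vs
D) and, for PP, in dropping subjects with `D ≠ Z` first. PP drops
whole clusters under cluster-level non-compliance and individual
intervention-arm subjects under subject-level non-compliance; a fit is
flagged non-converged (not raised) if either arm retains fewer than
two clusters.

The REML engine profiles the criterion down to a one-dimensional
search over the variance ratio `λ = τ²/σ²`, using the Woodbury
identity for the compound-symmetric within-cluster covariance: every
criterion evaluation needs only the data cross-products and per-cluster
column sums, so a fit costs little more than OLS. This is what makes
~40 000 mixed fits per full test run affordable on one CPU. The search
is bounded Brent on `λ ∈ [0, 200]` with the `λ = 0` boundary checked
explicitly (an on-boundary solution is exactly OLS). Agreement with
statsmodels `MixedLM` (coefficients ~1e-8, standard errors ~1e-4
relative) is enforced in the test suite. A design whose Cholesky
pivot ratio falls below 1e-7 is treated as rank-deficient and flagged
non-converged.

IV is two-stage least squares: a linear first stage of `D` on `Z`
(plus `X` when adjusted), then `Y` on the fitted receipt. When the
covariate variant is requested, `X` enters **both** stages as an
exogenous regressor — standard 2SLS practice for exogenous controls.
Standard errors come from the Huber-White cluster-robust sandwich with
bread from the second-stage design (fitted `D`) and residuals formed
with the *observed* `D`; the finite-sample factor is CR1,
`G/(G−1)·(N−1)/(N−k)` (selectable to `"none"`), which reduces to HC1
when every cluster has one subject. The first-stage partial F is the
cluster-robust Wald statistic of the instrument coefficient (a
classical-F flag exists); it is reported with every IV fit so
weak-instrument screening against the threshold of 10 is free.

Inference convention, all approaches: 95% CI = estimate ± 1.96·se and
two-sided z p-values. Using z rather than cluster-t everywhere keeps
the CI and the power criterion mutually consistent; at the grid's
minimum of 38 clusters the difference between `z_{0.975} = 1.96` and
`t_{0.975,36} ≈ 2.03` shifts coverage/power by well under one
percentage point of their Monte-Carlo error at the replication counts
used here.

## Evaluation

Per (condition × approach × covariate-variant): mean and SD of the
point estimates, coverage of the 95% interval against the approach's
own target estimand (`β1(1−p̄)` for ITT, `β1` otherwise), and
empirical power (`p < 0.05`). Non-converged fits are excluded from all
four metrics and counted separately; nothing is imputed. Binomial
Monte-Carlo error `sqrt(p(1−p)/R)` is the yardstick for
coverage/power comparisons.

All approaches and both covariate variants are fitted to the *same*
generated dataset within a replication, so contrasts between
approaches are paired. Random streams are keyed on
`(base_seed, crc32(condition_id), rep)` via numpy's `SeedSequence`:
results are bit-identical across serial and parallel execution and
independent of scheduling order. Default seed 20191003; default
replications 5000, with the bundled drivers and checks using 200–1000
(chosen so binomial error on proportions stays near one percentage
point while a full run fits comfortably on a single CPU).

## What the generator does and does not emulate

It emulates the study conditions exactly: normal outcomes, constant
cluster sizes, 1:1 allocation, a single compliance-driving covariate at
the level where non-compliance occurs, compliers and never-takers only.
It does **not** emulate always-takers or defiers, partial or
dose-dependent compliance, missing outcomes, varying cluster sizes,
covariates at the other level, or simultaneous cluster- and
subject-level non-compliance. Conclusions drawn from these simulations
therefore speak to trials with restricted intervention access and a
well-measured compliance driver; real trials with, e.g., contaminated
controls or informative missingness are outside what passing tests
demonstrate.

## Known limitations

* The AT/PP/IV target estimands coincide at `β1` here because
  never-takers' potential outcomes follow the control model; in
  practice these estimands can differ, and the bias ranking of the
  approaches with them.
* The IV variance is single-level (robust to, not modelling,
  clustering); with very few clusters (well below the grid's minimum
  of 38) CR1-corrected sandwich SEs are known to undercover.
* z-based inference, the CR1 correction and the t-refined sample-size
  rule are documented conventions; alternatives (cluster-t inference,
  no correction, one-stage rule) are switchable where they exist but
  are not part of the default study conditions.
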