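# Methods

## Scope and data flow

The package is an analysis pipeline for the economic burden of postsurgical
complications and the budget impact of goal-directed fluid therapy (GDFT).
It operates on patient-level records (one row per surgical admission) or,
for the projection stages, directly on aggregate counts. Stages:

1. **cohort** — schema validation and CSV round-tripping for patient-level
   tables;
2. **synthetic** — a generator producing cohorts with the group-level
   statistical structure of the studied ten-procedure population;
3. **descriptives** — per-group summaries and two-group tests;
4. **adjusted** — gamma/log-link GLM for confounder-adjusted cost means;
5. **projection** — morbidity and savings projection under an odds-ratio
   effect size (the core);
6. **roi** — implementation-cost, ROI and bed-day models;
7. **pipeline / cli** — orchestration, config, report bundle.

## Effect size and its two interpretations

The GDFT effect is an odds-ratio interval, default `[0.71, 0.83]` (the 95%
CI of a meta-analytic OR 0.77 for developing ≥1 postoperative
complication). Two conventions convert it to projected morbidity:

- **count_scaling** (default): projected complications = `round(C·OR)`.
  This treats the OR as a relative risk. It is the arithmetic that produces
  the published headline values this package reproduces, so it is the
  default; a warning is emitted when baseline morbidity exceeds 20%,
  because there the OR≠RR distinction is material (at p=0.375 and OR=0.71
  the odds-correct morbidity is 29.9%, not 26.6%).
- **odds_transform**: `p' = OR·p/(1 − p + OR·p)`. Exact for a true odds
  ratio; agrees with count scaling as p→0 (relative rate difference <1% at
  p=0.01 over OR∈[0.71,1], asserted by property test).

## Savings arithmetic and rounding conventions

All conventions below were chosen to make the printed headline figures
reproduce exactly from their stated inputs, and are asserted in tests:

- counts round half-up to integers before use (`round(76,807·0.71) =
  54,533`);
- morbidity rates are percentages at one decimal;
- savings totals are *averted count × mean excess cost* (`13,057 × $11,824`
  at the weak bound); per-year divides by the period (default 2.5 years);
- per-patient savings (count-scaling mode) follow the per-procedure table
  arithmetic: `round_half_up(morbidity% at 1dp / 100 × (1−OR) × Δ)`. This
  reproduces the published $754–$1286 range; dividing the savings total by
  N instead gives $754–$1287 (the two agree within $1/patient, which is
  asserted). In odds-transform mode, where there is no printed arithmetic
  to match, per-patient savings are `round_half_up(total/N)`;
- bed-days: averted counts are rounded to integers *before* multiplying by
  the excess LOS (13,057 × 3 = 39,171); new-patient capacity rounds
  half-up at each step (days/avg LOS, then per year) — the only convention
  reproducing all four printed capacity figures;
- monitor amortization uses 52 weeks/year: `15,000/(2·52·3) = $48.08`;
- the ROI upper bound is reported at one decimal (1286/298.08 = 4.3; the
  source text rounds this to "$4").

The projection multiplies the *full* complication count, not the smaller
cost-valid subset, by the excess cost: that is the convention that
reproduces the printed per-patient range, and the excess cost itself is
estimated from cost-valid records only.

## Adjusted cost model

Costs are positive and right-skewed, so the adjusted comparison is a GLM
with gamma family and log link (multiplicative effects on mean cost),
covariates: complication status, age (years), gender, Charlson comorbidity
index (continuous — no banding is claimed by the source analysis; a
sensitivity flag adds the procedure category as a factor). Fitting is IRLS
(statsmodels), convergence at relative deviance change < 1e-8 within 100
iterations; dispersion is the Pearson statistic over residual degrees of
freedom. Records with invalid or non-positive cost are excluded from the
fit with a logged count (gamma support is strictly positive).

Least-squares means are classical balanced-grid estimated marginal means:
continuous covariates held at their (fitting-sample) means, categorical
covariates averaged with equal weight over levels, complication set to
each group in turn, predictions inverse-linked then averaged. With no
covariates the grid collapses and LS-means equal raw group means (tested).

The published adjusted means ($25,390 vs $14,841 without the procedure
factor) depend on the joint covariate distribution of the proprietary
cohort and are not reproducible from printed marginals; the package instead
verifies parameter recovery (β̂ within 3 SE of a known injected log-effect
at n = 20,000) and recovery of a known injected adjusted difference on the
$10,549 scale within 15%.

## Synthetic cohort generator

The generator emulates, per procedure and complication group, exactly what
the published tables state — nothing more:

- complication flags: independent Bernoulli at the procedure morbidity
  rate (20.2%–67.7%; patient-weighted overall 37.5%);
- costs: gamma with shape `(mean/sd)²` and scale `sd²/mean` (moment
  matching; consistent with the gamma GLM assumption and positive by
  construction), rounded to whole dollars;
- LOS: log-normal with location `ln(median)` and spread
  `(ln q75 − ln q25)/(2·0.6745)`, rounded to integer days and clamped ≥1;
- readmission and cost-validity: Bernoulli at the group rates
  (invalid-cost rates 1 − 73,108/76,807 and 1 − 127,398/127,873);
- demographics: truncated-normal age (≥18) at group mean/SD, Bernoulli
  gender and elective status, Poisson Charlson index at the group mean.

One integer seed drives everything through numpy `SeedSequence` substreams
keyed `(procedure index, role)`, role 0 = complication assignment, roles
1/2 = the with/without groups; cohorts are bit-reproducible, and `scale`
shrinks every procedure count (minimum 1) for desk-scale runs.

**What it does not emulate** — and hence what passing tests do not show
about real data: no correlation among cost, LOS, readmission or
comorbidity beyond shared group membership; no hospital-level clustering
(the 541 centers are not modeled); comorbidity prevalences do not drive
costs; and per-group *overall* quantiles are mixture properties, so e.g.
the overall with-complication LOS median of the synthetic mixture comes
out at 6 days against the printed 7 [4–10] even though every per-procedure
median matches — the shape of each LOS distribution between its printed
quartiles is unspecified. Parameter-recovery tests therefore validate the
pipeline's estimators, not the realism of any particular joint structure.

## Statistical tests

Costs: two-sample t on cost-valid records, Welch form by default (group
SDs differ ~2.7×; a pooled flag exists). LOS: Wilcoxon rank-sum,
tie-corrected normal approximation with continuity correction by default,
exact method behind a flag (the exact-mode p equals brute-force
enumeration over all assignments; the approximation is within 0.15
absolute of exact on every two-group split of n ≤ 10 with group sizes
≥ 2). Readmission: Pearson chi-squared on the 2×2 table without Yates
correction (immaterial at these cell sizes; flag available). Quartiles use
linear interpolation. Degenerate inputs (all-tied LOS, identical 2×2 rows)
return statistic 0 and p = 1; groups too small for a test raise
`InsufficientDataError`. No multiplicity adjustment is applied across
procedures.

## Problem sizes used in the test suite and acceptance script

Generator moment checks run on a 30%-scale cohort (~61k records) in the
unit suite and the full 204,680-record cohort in the acceptance script and
acceptance tests; GLM recovery uses n = 20,000 and the acceptance-script
GLM a quarter-scale cohort (~51k records). These sizes give standard errors
small enough for 3-SE assertions while keeping a full run in seconds.

## Known limitations

- The morbidity reduction is applied uniformly across procedures; no
  interaction between procedure type and GDFT effect is modeled.
- No uncertainty propagation beyond the two OR bounds (no bootstrap over
  the excess cost); the model is deterministic given its inputs.
- Complete GDFT implementation is assumed; partial rollout scales savings
  linearly only under the model's independence assumptions.
- No reimbursement or profit-margin modeling; bed-day capacity is reported
  in days and admissions, not revenue.
- The published total savings low bound ($153M) is not exactly
  reconstructible from its stated inputs (13,057 × $11,824 = $154.4M); the
  per-patient range, which does reconstruct, is the anchoring quantity.
  Likewise per-procedure per-year figures here are `n × per-patient /
  period`, which does not reproduce the published per-year bar chart for
  colectomy ($29.0–49.4M vs $32–55M); that chart's annualization is
  unstated and out of scope.
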