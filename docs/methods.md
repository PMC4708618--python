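# Methods

## Decision rules

The package targets extra-welfarist evaluation with a fixed budget: an
intervention is efficient when the health it generates exceeds the health
its funding displaces. Three equivalent formulations are implemented.

**Conventional rule.** Fund iff Δc/Δh_p < k_p, with k_p the cost per unit
of *patient* health displaced. Strict inequality throughout: an ICER
exactly at the threshold is rejected. Ties therefore never fund, and the
boundary behaviour is covered by property tests.

**Multiplier-adjusted rule.** Fund iff (Δc/Δh_p)·(m_d/m_i) < k_p, where
m_i and m_d are the ratios of total (patient + network) to patient
incremental health on the generated and displaced streams. Only the
*ratio* of spillover to patient health must be known, not the absolute
spillover volumes. The rule reduces exactly to the conventional one when
m_i = m_d.

**Direct two-stream rule.** When both streams are measured outright:
fund iff Δc/(Δh_p+Δh_n) < Δc_d/(Δh_dp+Δh_dn). Internally the comparison
is cross-multiplied, Δc·(Δh_dp+Δh_dn) < Δc_d·(Δh_p+Δh_n), which is
algebraically identical for positive totals and remains well behaved when
the generated total is zero or negative (such an intervention is simply
rejected rather than funded through a sign-flipped ratio). A non-positive
*displaced* total is an error: the implicit threshold does not exist.

Domain and error conventions:

- Health losses from illness are stored as negative utility decrements.
  Multipliers are ratios, so same-signed patient and member effects (the
  usual case) give the same value whether framed as losses or as losses
  averted; no explicit absolute values are needed in the stream form.
- Δh_p = 0 makes every multiplier undefined; the API raises an error
  directing callers to the direct rule rather than guessing.
- Negative multipliers (net-harmful spillovers) are representable; the
  ratio-form rule refuses m_i ≤ 0 because dividing by a non-positive total
  inverts the inequality.
- Currency is unit-agnostic; verdicts are invariant to re-denominating Δc
  and k_p jointly (property-tested).

## Multiplier reporting precision

Internally everything is double precision. Reported multiplier tables use
2-decimal precision with a specific policy: the per-member spillover ratio
r = |carer decrement|/|patient decrement| is rounded to 2 dp first, and
the n-member multiplier formed as 1 + n·r. This keeps a published table
internally additive — the two-member entry is exactly 1 + 2·(one-member
entry − 1) — and is the policy under which the package's reference tables
are self-consistent. The distinction matters in exactly one reference
cell: the behavioral-problems two-member multiplier is 1.5505 raw (1.55 if
the final value alone were rounded) but 1.56 under the ratio-first policy.
`multipliers_from_decrements(..., precision=None)` returns the raw ratio.

## Portfolio scenarios

A menu of equally priced care packages is evaluated under information
scenarios recognizing n = 0, 1, 2 network members. Perceived benefit is
patient benefit × the package's multiplier at n; the funding threshold is
the displaced patient units plus n × displaced per-member units for the
same spending. Funding is strictly-greater-than the threshold, package by
package — the budget is assumed non-binding beyond per-package
displacement, so this is not a knapsack problem and no combinatorial
optimization is performed (an exhaustive-enumeration test confirms the
per-package rule is optimal under the additive accounting).

Realized net benefit is always scored under **full information**, defined
as the largest recognized n in the configuration: Σ over funded packages
of (full-information perceived benefit − full-information threshold). The
displaced-spillover penalty compares the optimal full-information set with
the set chosen when the threshold is left at patient units only (m_d
forced to 1), isolating the cost of counting spillovers on only one side.

Reported perceived benefits are integers, rounded half away from zero from
the 2-dp-multiplier product (e.g. 120 × 1.28 = 153.6 → 154; 80 × 1.56 =
124.8 → 125). The reference tables contain no exact halves, so the
half-rule is a documented convention rather than an empirically forced
choice; an audit path (`rounded=False`, `--audit-rounding`) exposes the
unrounded values (187.2 behind the headline 187).

## Marginal analysis

Quantity is continuous and divisible. The patient marginal-benefit
schedule is linear, MHB_P(q) = intercept − slope·q — the minimal concrete
form of a declining schedule, sufficient for every comparative-static
conclusion — and the marginal-loss schedule MHL_P is constant, reflecting
an intervention small relative to the whole budget. Spillovers are
proportional to patient health within an intervention, so societal
schedules are scalar multiples: MHB_S = m_i·MHB_P, MHL_S = m_d·MHL_P.

- Equilibrium: q* = (intercept − mhl)/slope, clipped at zero; a flat
  benefit schedule above the loss line raises an unbounded-demand error.
- Welfare triangle: the gap MHB_S − MHL_S is linear, so the area between
  two quantities is computed in closed form; property tests check it
  against trapezoid quadrature (exact for linear integrands) to 1e-9.
- Corner test: funding to the patient-only equilibrium q1 beats no
  funding iff ∫₀^{q1}(MHB_S − MHL_S) dq ≥ 0 — geometrically, iff the gain
  triangle near the origin is at least as large as the overprovision-loss
  triangle. The check accepts any linear schedules; when MHB_S ≥ MHL_S at
  q1 the loss triangle is empty and the verdict is trivially to fund. The
  zero-net boundary returns the funding verdict (an indifference
  tie-break, analogous to the ≥ in the area comparison).

Scale invariance (common multiplier moves nothing), monotonicity (q*
non-decreasing in m_i, non-increasing in m_d) and corner-verdict agreement
with numerical integration are verified on randomized linear instances.

## Decrement estimation

One OLS model per role (patient, carer): utility index regressed on all
condition indicators jointly, adjusting for age, sex and years since
illness onset. Joint entry means each coefficient is the marginal impact
of a condition holding the others fixed, which is the interpretation the
multiplier construction needs for non-exclusive after-effects. Carers
carry their linked patient's condition flags as exposures — the carer-side
regression is otherwise unidentified. Utilities are accepted as
already-scored indices; no descriptive-system scoring is performed.

Covariates are optional (`covariates=()` gives the unadjusted model). The
design matrix is checked for full column rank before fitting; a deficient
design raises an error naming the collinear or constant columns
(incremental-rank scan), rather than silently dropping them. At least two
more observations than parameters are required so that standard errors
are estimable with slack.

Estimates are validated by parameter recovery against the synthetic
generator: exact (≤1e-11) recovery at zero noise, and 3-SE coverage in at
least 95% of 200 replicates at the reference noise level (below).

## Synthetic cohort generator

The generator emulates a family-impact survey of meningitis survivors:
dyads of one patient plus a configurable number of carers; per-dyad
condition indicators drawn independently by prevalence; utilities from a
linear model with Gaussian noise,

    utility = intercept(role) + Σ_c flag_c·decrement_c(role)
              + β_age·age + β_sex·female + β_years·years + N(0, σ²).

Defaults and the reasoning behind them:

| parameter | default | why |
|---|---|---|
| decrements | behavioral −0.109/−0.030, learning −0.041/−0.023, amputation −0.226/−0.005 (patient/carer, utility units) | the published after-effect decrements |
| noise sd σ | 0.1 utility units | typical residual spread of utility indices; the level used in recovery tests |
| prevalences | 0.25 / 0.20 / 0.05 | plausible after-effect frequencies that keep every indicator populated at moderate n |
| intercepts | patient 0.90, carer 0.92 | healthy-adult utility levels; keep the linear predictor below 1 |
| β_age, β_sex, β_years | −0.002/yr, −0.010 (female), +0.001/yr | small, realistic confounder effects so adjustment is exercised but does not dominate |
| patient age, carer age, onset | U(1, 40), U(25, 60), U(1, 25) years | survivors skew young; carers are working-age; onset in the survey's recall window |

Utilities are *not* capped at 1 by default: ceiling censoring would bias
the OLS recovery checks, and the default intercepts rarely reach 1 anyway.
A `cap_at_one` flag exists for realism-oriented use.

Randomness discipline: one spawned `SeedSequence` substream per dyad, so a
fixed seed is bit-reproducible and enlarging a cohort leaves all earlier
dyads unchanged. Empirical prevalences converge to the specification (3
binomial-SD check at 10,000 dyads).

What passing tests do and do not show: the generator realizes exactly the
linear, additive, homoscedastic world the estimator assumes — independent
dyads, correctly specified covariates, no censoring, no selection.
Recovery there demonstrates the pipeline is implemented correctly, not
that OLS on a real survey would be unbiased: real carer outcomes are
clustered within families, utilities are ceiling-censored, conditions are
not independent of covariates, and caring intensity is unobserved.

## Problem sizes

Statistical checks use 2,000 dyads × 200 replicates for Monte-Carlo
recovery, 10,000 randomized cases for decision-rule equivalences, 1,000
random linear instances for the marginal-analysis oracles, and 10,000
dyads for the prevalence calibration — sizes at which every Monte-Carlo
tolerance has comfortable slack while the whole suite runs in well under a
minute.

## Known limitations

- No cost spillovers, productivity costs or societal-perspective costing:
  the maximand is health from the health budget only.
- No welfarist family-utility modelling; spillovers are health effects
  valued like patient health, with no equity weighting.
- No budget-constrained (knapsack) optimization across unequal-cost
  packages, and no uncertainty/probabilistic sensitivity analysis.
- The displaced multiplier is a free parameter: the package derives it
  from configured displacement rates but cannot tell the user what is
  actually displaced at the margin of their system.
- Linear schedules and proportional spillovers are modelling choices;
  alternative shapes change quantities but not the qualitative regime
  conclusions, and can be explored by transforming schedules before the
  equilibrium calls.
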