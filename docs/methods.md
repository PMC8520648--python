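# Methods

This document records the statistical model behind the synthetic data, the
definition of every test in the battery, the meta-comparison machinery, the
sample-size formulas, and the numerical choices made along the way. The
API mirrors this structure: `trial_model` (domain types and IO), `simulate`
(generator), `battery` (fifteen tests), `compare` (ranking / Friedman /
Duncan / type-I error), `samplesize` (formulas and multipliers), `study` and
`cli` (orchestration).

## 1. Domain model

A **participant record** holds the randomised arm, three baseline covariates
(age in years, sex, diabetes history), the event indicator, the fatality
indicator, an optional severity attribute for non-fatal events, and optional
time-to-event data (days to event or censoring plus an observed flag).
Invariants are enforced at construction: `fatal` and `severity_attr` require
`event`, `observed` must agree with `event`, times are non-negative.

An **ordinal scale** is an ordered tuple of severity labels, always starting
at level 0 = "none" and ending at the fatal category, with 3–9 levels. A
record is *ordinalised* by: no event → 0; fatal → top level; otherwise the
severity attribute is looked up in the scale's mapping, falling back to a
configurable default non-fatal level. `collapse_to_binary` recovers the
any-event or fatal-only dichotomy from a level; by construction
`collapse(ordinalise(r)) == r.event` for every record and scale (a property
test enforces this).

A **comparator dataset** is one two-arm comparison (arms `treatment` /
`control`, each with at least 2 participants) plus free-form metadata tags.
`expand_comparisons` turns a multi-arm trial into several comparator
datasets; an arm reused across comparisons (factorial designs) is shared by
reference, not copied.

## 2. Synthetic data generator

Each participant in arm `a` (1 = treatment) with covariates `x` gets an
ordinal level from a cumulative model built in two stages:

```
p_event(x) = expit( logit(1 - p0) + b_age (age - 65) + b_sex (sex - 0.45)
                                   + b_dm (dm - 0.20) )
Q_j        = P0(severity >= j | event)            (Q_1 = 1)
P(level >= j | x, a) = expit( logit(p_event(x) * Q_j) + a * logOR )
```

where `(p0, p_1, ..., p_{k-1})` are the configured baseline (control)
category probabilities and `logOR` is the common treatment log odds ratio on
the "level ≥ j" scale (negative = benefit). Consequences used by the tests:

* Given covariates, the treatment effect is **exactly proportional-odds**:
  every cut is shifted by the same `logOR`.
* In the control arm `expit(logit(z)) = z` makes the model collapse to
  `P(level >= j | x) = p_event(x) * Q_j`: covariates move event occurrence
  only, severity given an event is independent of `x`, and the marginal
  cumulative probabilities have the closed form `E[p_event(x)] * Q_j` with
  the expectation computable by Gauss–Hermite quadrature over age and exact
  sums over the binary covariates.
* Marginally over covariates the treatment effect is slightly attenuated
  (non-collapsibility of the odds ratio); the distribution tests therefore
  compare against the quadrature oracle, not the naive baseline rate.

Default covariate effects are modest (age 0.03/yr, sex −0.2, diabetes 0.5 on
the log-odds of any event) and the default scenario is 2000 participants per
arm — the order of magnitude of the vascular prevention trials being
emulated. Event times are exponential with hazard 1/600 per day truncated at
the 5-year follow-up (administrative censoring for non-events), which gives
the proportional-hazards methods something honest to fit without modelling
severity–time dependence.

The **null generator** forces `logOR = 0` and assigns the arm label by an
independent fair coin per participant, so any apparent effect is pure
chance. The **bootstrap resampler** draws rows i.i.d. with replacement
(keeping arm labels) at the original size.

Randomness contract: every operation takes `(seed, stream)` and uses
`numpy.random.SeedSequence([seed, stream])`, so replicate streams are
reproducible independent of execution order and process. The battery derives
its internal resampling stream from a CRC-32 of the dataset id (stable
across processes, unlike Python's salted string hash).

Limitations: covariates never interact with treatment; severity is
conditionally independent of covariates; event times ignore severity;
there is no between-trial heterogeneity beyond what the scenario list
provides. These are deliberate: the generator produces the *structure the
methods assume*, so that deviations in method behaviour are attributable to
the methods, not to generator quirks.

## 3. The fifteen-test battery

All tests are two-sided at a configurable `alpha` (default 0.05) and return
a `TestResult` (p-value, effect estimate where available, diagnostics,
degeneracy flag). Data that a method cannot handle (empty contingency
cells, zero events, constant outcomes, missing times) produce a *degenerate*
result with p = 1 and a logged reason — never an exception and never a
silent drop — so that downstream ranking can include the method at the
worst possible rank.

| Code | Test | Notes |
|------|------|-------|
| CSB | chi-square, any event | 2×2, no continuity correction |
| CSF | chi-square, fatal only | 2×2 on the top category |
| CSO | chi-square, ordinal | 2×k, empty pooled columns dropped |
| CAT | Cochran–Armitage trend | equally spaced scores, hypergeometric variance; satisfies z² = (N−1)·r² |
| MWU | Mann–Whitney U | tie-corrected normal approximation without continuity correction; exact permutation enumeration when both arms ≤ 10 |
| MT | median test | chi-square on the above/below pooled-median split |
| TT | two-sample t | equal-variance, integer scores |
| OLR | ordinal logistic regression | in-house grouped proportional-odds ML fit, Wald p |
| OLR_adj | OLR + covariates | in-house individual-level PO fit |
| BLR_adj | binary logistic + covariates | statsmodels `Logit`, Wald p |
| MLR_adj | linear model + covariates | statsmodels `OLS` on scores |
| CPH | Cox proportional hazards | in-house Breslow-tie partial-likelihood Newton fit |
| CPH_adj | Cox + covariates | same fit, added columns |
| WR | win ratio | pairwise wins/losses down the severity hierarchy |
| BS | bootstrap mean-rank difference | within-arm multinomial bootstrap |

Method-specific details:

* **MWU**: for arms ≤ 10 each, the permutation distribution of U over all
  `C(n1+n2, n1)` rank assignments is enumerated (ties handled through
  midranks) because the normal approximation is unreliable there. The
  reported effect estimate is the probabilistic index
  `P(treatment better) + 0.5 P(tie)`.
* **Win ratio**: comparing two participants down the hierarchy of severity
  dichotomies is equivalent to comparing their ordinal levels, so the
  win/loss/tie counts come from the level frequencies in O(k); the identity
  `Nw + 0.5 Nt = U(control vs treatment)` is property-tested. The p-value
  uses the delta method on `log(Nw/Nl)` with a two-sample U-statistic
  projection variance; when either count is below 10 a within-arm
  multinomial bootstrap replaces the normal approximation, and when a count
  is zero a binomial sign test on the discordant pairs is reported.
* **Bootstrap mean-rank (BS)**: B within-arm multinomial resamples
  (vectorised over replicates via pooled-count midranks); two-sided p
  inverts the percentile interval, `p = 2·min(P*(d≤0), P*(d≥0))`, capped at
  1, floored at 2/B.
* **In-house ML fits** (`_ordinal.py`, `_cox.py`): the grouped and
  covariate-adjusted proportional-odds models are fitted by BFGS with
  analytic gradients (numerical Hessian for standard errors); the Cox
  partial likelihood by Newton–Raphson with risk sets as reverse-time
  cumulative sums (Breslow tie handling — exact for the continuous
  simulated times). They exist because the battery runs thousands of times
  in the comparison studies; statsmodels `OrderedModel` and lifelines
  `CoxPHFitter` are retained in the test suite as oracles and agree to
  ≥ 4 decimal places on the fixtures.
* **Proportional-odds score test**: the score of the non-proportional
  alternative (one slope per cut) evaluated at the constrained PO fit,
  chi-square with (k−2)·p degrees of freedom; undefined (NaN, df 0) for
  binary outcomes. Optional (`BatteryConfig.po_check`) because it is a
  diagnostic, not one of the fifteen tests.
* Covariates are standardised before the adjusted fits (the treatment Wald
  p is invariant to affine covariate transforms; conditioning improves by
  orders of magnitude).

## 4. Comparison engine

Within each dataset the fifteen p-values are ranked, 1 = smallest, midranks
for ties (degenerate methods enter at p = 1, hence share the worst ranks).
Row rank sums are validated to equal k(k+1)/2.

**Friedman test** with the tie correction divisor
`C = 1 − Σ(t³−t) / (n·k·(k²−1))`; a fully tied matrix (C ≤ 0) reports
statistic 0, p 1. Perfect untied agreement attains the maximum `n(k−1)`.
The chi-square reference is compared against full and Monte-Carlo
permutation oracles in the tests; agreement is good in the rejection region
and conservative in the middle of the distribution, which is the standard
behaviour of the approximation.

**Duncan's multiple range test** runs only when Friedman is significant
(otherwise all methods share letter "A" and no top group is flagged). The
error variance is the residual mean square of the two-way dataset×method
ANOVA of the rank matrix, df = (n−1)(k−1). Means are sorted; the critical
range for a span of p means is the studentized-range quantile at Duncan's
protection level `1 − (1−alpha)^(p−1)`; maximal non-significant intervals
become letter groups. The **rating table** sorts methods by mean rank
(rating 1..15) and flags the *top group*: every method sharing a letter with
the rating-1 method.

**Type-I-error assessment**: B with-replacement resamples of a neutral
dataset; within each replicate the dummy arm is **re-assigned by a fair
coin**. Keeping the original labels would condition on the observed arm
imbalance of the parent dataset and inflate the count roughly three-fold;
re-assignment makes every replicate exactly null, so a calibrated test is
significant in ≈ alpha·B replicates (the acceptance band is the 99%
binomial interval 33–68 of 1000).

## 5. Sample sizes and multipliers

All formulas return the **total** N for 1:1 allocation, two-sided alpha
0.05 and power 0.90 by default, rounded up to an even integer:

* binary proportions (unpooled z):
  `N = 2·ceil( z² (p1 q1 + p2 q2) / (p1 − p2)² )`
* Whitehead proportional-odds:
  `N = 12 z² / ( (log OR)² (1 − Σ p̄ⱼ³) )` with mean category probabilities
  p̄ across arms. The constant 12 is fixed by requiring the two-category
  collapse to agree with the binary log-odds-ratio size (within 2%, tested)
  and by the power-calibration oracle.
* Noether (Mann–Whitney): `N = z² / ( 3 (p_win − ½)² )`, no tie correction —
  ties enter only through `p_win` itself. On heavily tied ordinal data the
  returned N is conservative (simulated power ≈ 1); its calibration oracle
  is therefore the continuous shift model the formula assumes.
* t-test: `N = 2·ceil( 2 z² sd² / δ² )` on integer scores.

Each formula is calibrated by simulation under its own model: the returned
N achieves 90% ± 3 points power (acceptance criterion).

`estimate_effects` extracts all four effect quantities from a dataset (event
proportions; PO odds ratio from the grouped fit; probabilistic index from
the win/tie counts; score mean difference and pooled SD). The **multiplier**
of a method is its N divided by the binary N for the same dataset, rounded
at the printed precision of the published comparisons (two significant
figures below 0.1, two decimals otherwise); the report summarises the
median and quartiles (linear interpolation) of the rounded multipliers. The
packaged 13-row reference table reproduces exactly at this rounding
(medians 0.66 ordinal, 0.18 Mann–Whitney, 0.18 t-test — i.e. 34% and 82%
sample-size reductions).

## 6. Numerical choices

* All optimisation is on unconstrained parametrisations (cutpoints ordered
  by construction in the grouped PO fit via monotone starting values and the
  likelihood's own barrier), BFGS/Newton with analytic gradients.
* p-value floors: resampling tests cannot report below 2/B.
* `SeedSequence([seed, stream])` everywhere; no global RNG state.
* Quantile convention for multiplier summaries: NumPy `percentile`
  with linear interpolation (matches the published quartiles).
* Exact enumeration limits: MWU permutation up to 10 per arm
  (`C(20,10) ≈ 1.8·10⁵` rank sums); Friedman permutation oracles live in
  the tests, not the library.
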