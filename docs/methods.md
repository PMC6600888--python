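# Methods

This note documents the statistical conventions, model assumptions and
design choices behind `grogscreen`, in the spirit of a package methods
appendix. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Consumption conversion

A beverage entry converts to grams of ethanol as

```
grams = volume_ml × abv × fullness × share × count × 0.789
```

with 0.789 g/mL the reference density of ethanol and 10 g per Australian
standard drink. The formula is linear in every factor, so a half-shared
can is representable equivalently as `count = 0.5` or `share = 0.5`
(tested as a commuting property). Catalog files store alcohol strength as
a percent; it becomes a fraction at the I/O boundary only. `share` is a
single fraction of the poured amount — group-size arithmetic (who poured
how much for whom) is deliberately not modelled.

## Finnish-method estimators

Occasions are indexed most recent first with integer day offsets;
occasions older than 366 days are excluded before anything is computed
(the recall window is "the last 12 months"), and a person left with no
in-window occasion is treated as a past-year non-drinker. The instrument
records at most the four most recent occasions, and every summary
statistic — including the single-occasion maximum that drives short-term
risk — is computed over those records only. This understates the true
any-day maximum; it is the only per-occasion data the method has.

Frequency uses a renewal-style estimator: `k / span × 30.4375`
occasions/month, where `span` is the day offset of the *k*-th most recent
occasion, clamped to ≥ 1 day so same-day occasions do not divide by zero,
and 30.4375 = 365.25/12 is the mean month length (exposed in the
configuration). Among the candidate estimators (k/span, (k−1)/inter-span,
calendar bucketing) this one makes shortened and full variants directly
comparable — the k = 1 and k = 4 estimates agree exactly under even
spacing — which is what the retention analysis needs. For
`k_quantity = k_frequency = k` the average-daily estimate reduces
algebraically to `(sum of k quantities) / span`; the identity is asserted
to 1e-12 in the property tests. Ties in day offsets are kept as distinct
occasions in input-file order.

## Modified AUDIT-C

Item scores are the ordinal response positions 0–4. AUDIT-1m is only
asked of confirmed past-year drinkers, so a "never" response there is a
validation error. AUDIT-2m is *derived*: the continuous Finnish usual
quantity is rounded half-up to an integer drink count (the printed
categories are integer counts, so gap values such as 4.5 must resolve
somewhere; half-up keeps the mapping a right-continuous step function)
and recoded 0–2 → 0, 3–4 → 1, 5–6 → 2, 7–9 → 3, ≥ 10 → 4. The total
flags risk at ≥ 3 for women and ≥ 4 for men.

### Category midpoints

Subset risk estimation converts responses back to consumption scales via
midpoints. The frequency scale is anchored at weekly drinking =
1/7 ≈ 0.14 occasions/day. The full table (all values configurable):

| category | midpoint |
|---|---|
| never | 0 |
| less than monthly | 0.5/month (midpoint of 0–1/month) |
| 1–3 times a month | 2/month |
| a few times a week | 2/week |
| most days or every day | 5.5/week (midpoint of 4–7/week) |

The questionnaire's printed sub-labels for the "few times a week"
category are internally inconsistent across items (2–3 vs 1–3 times a
week); 2/week is used for both. Quantity midpoints for AUDIT-2m scores
are 1.5, 3.5, 5.5, 8 and — since the top category (10+) is unbounded —
10 drinks.

Risk rules from subsets: AUDIT-1m+2m flags short-term risk when the
quantity midpoint exceeds 4 drinks and the person drinks at all, and
long-term risk when frequency midpoint × quantity midpoint > 2
drinks/day. AUDIT-3mV flags short-term risk for any non-"never" response
and long-term risk when 5 drinks (the visual threshold it shows) × its
frequency midpoint > 2/day — which under the default midpoints holds
exactly for the top response category (asserted over all five
categories). A configuration switch (`short_term_min_frequency`)
tightens the subset short-term rule from "at least once in the past
year" to "at least monthly", as both readings appear in practice.

## Risk classification

NHMRC rules are strict inequalities: average > 2.0 drinks/day
(long-term), > 4.0 drinks on a single recorded day (short-term); the
boundary values themselves are not at risk. The drinker gate (preparatory
question, then a special-events check question when the answer is no)
excludes non-drinkers from all analyses. The three-item dependence screen
labels a sampling stratum only — any non-"never" rating → dependent — and
never enters risk computation.

## Concordance and retention

Cross-tabulation and sensitivity/specificity are re-implemented here
rather than delegated: tp/fn/fp/tn follow the epidemiological convention
(reference in columns), sensitivity = tp/(tp+fn), specificity =
tn/(fp+tn). Confidence intervals are exact Clopper–Pearson bounds from
beta quantiles — the family that matches published small-denominator
intervals such as 6/9 → (29.9, 92.5) and 174/175 → (96.9, 100.0) — with
degenerate bounds pinned at 0 and 1. An independent bisection oracle on
binomial tail probabilities verifies the beta-quantile implementation for
every (s, n) with n ≤ 30, and a seeded simulation checks conservative
coverage. The interval family is named in the configuration
(`ci_method`) so the choice is explicit.

The retention grid correlates, across drinkers with at least four
in-window occasions, the per-person estimate using `k_quantity` occasions
for intensity and `k_frequency` for timing against the full (4, 4)
estimate, and squares the correlation. The correlated variable is the
average-drinks-per-day estimate by default, since it is the quantity that
combines both axes; a switch correlates drinks-per-occasion instead (in
which case the frequency axis is inert). The (4, 4) entry is set to
exactly 1. Drinkers with fewer than four occasions are excluded from this
analysis only, and counted in the run log. A companion analysis drops
drinkers whose four quantities are all equal (tolerance 1e-9) to check
that retention does not rest on respondents copying their most recent
occasion forward.

`pearson_r` is computed from mean-centred dot products and cross-checked
against `scipy.stats.pearsonr`; r² values are reported as percentages at
one decimal in file outputs and at full precision in the API.

## Synthetic cohort generator

The generator emulates the survey population the instruments target:

- **Strata.** 20% non-drinkers; half of drinkers labelled dependent
  (emulating stratified recruitment of ~20/40/40 per site). The label is
  metadata only. Sex is assigned 50/50 independent of drinking.
- **Timing.** Each drinker has a latent rate (occasions/day) drawn
  log-uniformly within the band of a frequency class sampled with
  probabilities (0.304, 0.424, 0.261, 0.011) over the four drinker
  classes; class boundaries sit at 1/month, 1/week and 3.5/week.
  Occasions follow a homogeneous exponential renewal process accumulated
  backwards from a uniform first offset, truncated at the 366-day window.
  Real drinking is burstier than a homogeneous process; a two-state
  on/off modulation is available behind `bursty` (default off) because
  the homogeneous base model is analysable and sufficient for the
  marginals below.
- **Quantity.** Per-occasion standard drinks are a two-component
  log-normal mixture: a heavy majority centred at 18 drinks and a 7%
  light-drinking minority centred at 2.5, each with between-person spread
  σ_b = 0.65 and within-person spread σ_w = 0.25 on the log scale. The
  mixture is structural, not cosmetic: the share of drinkers at
  short-term risk is governed by people whose *every* recorded occasion
  stays at or below four drinks, while the share in the top AUDIT-2m
  category is governed by the heavy majority's centre — a single
  log-normal cannot set both at once. These defaults were calibrated once
  by Monte Carlo (40 000 simulated drinkers) against the published
  population marginals — ~95% of drinkers at short-term risk, ~78% in the
  10+ quantity category, ~44% at long-term risk, median 16–18 drinks per
  occasion — and then frozen; the calibration-recovery checks in the test
  suite recompute them at n = 5000 from a fixed seed.
- **Self-report.** True AUDIT-1m bins the latent rate; true AUDIT-3mV
  bins the latent rate of > 4-drink occasions (rate × observed heavy
  fraction), "never" when no recorded occasion was heavy. With
  probability `report_noise` (default 0) a reported category moves one
  level, clamped so drinkers never report "never" on AUDIT-1m. A
  `copy_last_quantity_prob` parameter (default 0) lets earlier occasions
  copy the most recent occasion's quantity, emulating a
  default-answer survey affordance of unknown prevalence.

One `numpy` Generator seeded from a single integer drives everything;
regeneration is bit-identical.

What the generator does **not** emulate: community-level dry spells and
seasonal events, sex-specific consumption patterns, correlation between
dependence stratum and consumption, and systematic (non-adjacent)
misreporting. Passing calibration tests therefore show the pipeline is
internally consistent under a realistic marginal structure, not that it
would reproduce any particular field dataset.

## Numerical and interface choices

- Day spans clamp to ≥ 1; frequency is undefined (an error, not 0) with
  no occasions, so callers must handle non-drinkers explicitly.
- Zero-variance inputs to the correlation raise rather than return NaN.
- CSV schemas are strict (exact headers, lower-case tokens, '.'
  decimals); validation errors carry `file:line`. Referential-integrity
  problems (occasions for an unknown person) are collected per record and
  reported; only file-level errors abort a run.
- The pipeline writes floats at full precision alongside rounded
  percent-style strings in `concordance.json` for human comparison.
- Problem sizes used by the test suite — a 200-person cohort for the
  retention brute-force comparison and 5000 drinkers for calibration
  recovery — keep the whole suite to a few seconds while leaving Monte
  Carlo error well inside the stated tolerances.

## Known limitations

- The frequency estimator is upward-biased for a renewal process
  (E[k/span] > rate); the long-term risk share inherits this. The bias is
  shared by full and shortened variants, so retention comparisons are
  unaffected.
- With at most four recorded occasions, the "any single drinking day"
  maximum is a lower bound on the true annual maximum.
- AUDIT-2m is derived from the same records as the reference method, so
  concordance between them is partly circular — a property of the design
  being modelled, not removable here.
- The default calibration targets a single studied population;
  applications elsewhere should re-parametrise `CohortParams`.
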