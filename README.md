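# grogscreen

Screening for risky drinking is hard in populations whose drinking is
intermittent — long gaps punctuated by very heavy occasions. Standard
quantity–frequency questions assume a "usual" pattern that may not exist,
and drinks are often poured into non-standard containers and shared.
`grogscreen` implements, as a reusable and tested Python library, the
analysis pipeline used to validate short alcohol-screening tools under
exactly these conditions:

- **Consumption conversion** — beverage-level records (product, container
  volume, fullness, count, share) → grams of ethanol
  (`V·abv·fullness·share·count·0.789 g/mL`) → Australian standard drinks
  (10 g ethanol each).
- **Finnish method** — from the timing and quantity of the last *k* ≤ 4
  drinking occasions in the past year: frequency
  `f = k/span · 30.4375` occasions/month (span = days back to the *k*-th
  occasion), intensity `q̄` (mean drinks/occasion), average daily
  consumption `q̄·f/30.4375`, and the single-occasion maximum.
- **Modified AUDIT-C** — AUDIT-1m (frequency) and AUDIT-3mV (frequency of
  5+-drink occasions) scored 0–4 ordinally; AUDIT-2m derived by recoding
  the Finnish usual quantity into the AUDIT-2 bands (0: 1–2, 1: 3–4,
  2: 5–6, 3: 7–9, 4: 10+ drinks); total at risk at ≥ 3 (women) / ≥ 4 (men).
- **NHMRC risk rules** — long-term risk: average > 2 standard drinks/day;
  short-term risk: > 4 standard drinks on any recorded drinking day.
  Item subsets estimate the same risks via category midpoints (weekly
  drinking = 0.14 occasions/day; top quantity category = 10 drinks).
- **Evaluation** — 2×2 cross-tabulation of an index tool against the
  Finnish reference; sensitivity/specificity with exact (Clopper–Pearson)
  95% CIs; and a 4×4 grid of r² values measuring how much variance
  shortened Finnish variants (fewer occasions for quantity and/or
  frequency) retain against the full four-occasion estimate.
- **Synthetic cohorts** — a seeded generator reproducing the intermittent
  heavy-drinking structure (stratified drinker types, renewal-process
  occasion timing, log-normal mixture quantities with a median of 16–18
  drinks/occasion, ordinal self-report with optional noise), so the whole
  pipeline is testable without access to restricted survey data.

It is aimed at biostatisticians and epidemiologists validating or adapting
short screening instruments for intermittent-drinking populations.

## Worked example

```python
from grogscreen import DrinkingOccasion, nhmrc_risk_from_summary, summarize

occasions = [
    DrinkingOccasion(days_before_survey=5,  standard_drinks=16),
    DrinkingOccasion(days_before_survey=12, standard_drinks=12),
    DrinkingOccasion(days_before_survey=21, standard_drinks=14),
    DrinkingOccasion(days_before_survey=26, standard_drinks=12),
]
summary = summarize(occasions)
risk = nhmrc_risk_from_summary(summary)
```

prints (see `examples/02_finnish_method_and_risk.py`):

```
frequency:        4.68 occasions/month
intensity:        13.50 drinks/occasion
average:          2.08 drinks/day
heaviest day:     16.0 drinks
short-term risk:  True  (heaviest day > 4 drinks)
long-term risk:   True  (average > 2 drinks/day)
```

Four occasions in 26 days is 4/26 × 30.4375 ≈ 4.68 occasions a month;
13.5 drinks a time at that frequency averages 2.08 drinks/day — just over
the long-term guideline — and every occasion far exceeds the 4-drink
single-day threshold.

The `examples/` directory has one short script per capability
(consumption conversion, Finnish method + risk, AUDIT scoring +
concordance, full synthetic-cohort pipeline). A thin CLI wraps the same
library:

```bash
grogscreen simulate --out data/ --seed 42 --n 230
grogscreen run --in data/ --out results/
```

which writes `summary.csv` (per-drinker estimates, scores and flags),
`concordance.json` (each index method vs the Finnish reference for
any/short/long-term risk), `retention.csv` (the 16-cell r² grid, plus a
variant excluding drinkers with zero quantity variation) and a run log of
exclusion counts.

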