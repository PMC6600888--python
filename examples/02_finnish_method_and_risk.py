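"""Estimate consumption from the last four drinking occasions and classify
NHMRC drinking risk.

One drinker reports four occasions, roughly weekly, of 12-16 standard
drinks.  The Finnish method turns timing into frequency (occasions/month),
quantity into intensity (drinks/occasion), and both into an average daily
consumption; the guideline rules then flag long-term risk (average > 2
drinks/day) and short-term risk (> 4 drinks on any recorded day).
"""

from grogscreen import DrinkingOccasion, nhmrc_risk_from_summary, summarize

occasions = [
    DrinkingOccasion(days_before_survey=5, standard_drinks=16),
    DrinkingOccasion(days_before_survey=12, standard_drinks=12),
    DrinkingOccasion(days_before_survey=21, standard_drinks=14),
    DrinkingOccasion(days_before_survey=26, standard_drinks=12),
]

summary = summarize(occasions)
risk = nhmrc_risk_from_summary(summary)

print(f"frequency:        {summary.frequency_per_month:.2f} occasions/month")
print(f"intensity:        {summary.drinks_per_occasion:.2f} drinks/occasion")
print(f"average:          {summary.average_drinks_per_day:.2f} drinks/day")
print(f"heaviest day:     {summary.max_single_occasion:.1f} drinks")
print(f"short-term risk:  {risk.short_term}  (heaviest day > 4 drinks)")
print(f"long-term risk:   {risk.long_term}  (average > 2 drinks/day)")
# Drinking ~4.7 times a month at ~13.5 drinks a time averages ~2.08
# drinks/day: this intermittent but heavy pattern exceeds both guidelines.
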