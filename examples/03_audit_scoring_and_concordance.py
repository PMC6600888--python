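"""Score the modified AUDIT-C and reproduce the screening-concordance
statistics for a screening tool against a reference method.

First scores one participant's AUDIT-Cm (the quantity item AUDIT-2m is
derived from their Finnish-method usual quantity).  Then reconstructs a
2x2 concordance table from published marginals — 184 drinkers, 175 at risk
by the reference, 177 by the index test, 4 disagreements — and computes
sensitivity/specificity with exact 95% confidence intervals.
"""

from grogscreen import (
    FrequencyCategory,
    TwoByTwo,
    derive_audit2m,
    score_audit1m,
    score_audit3mv,
    sensitivity_specificity,
    total_audit_cm,
)

# --- scoring one woman who drinks ~weekly, usually 12 drinks ---------------
audit1m = score_audit1m(FrequencyCategory.WEEKLY_1_3)
audit2m = derive_audit2m(12.0)
audit3mv = score_audit3mv(FrequencyCategory.MONTHLY_1_3)
scored = total_audit_cm(audit1m, audit2m, audit3mv, sex="female")
print(f"item scores: {scored.audit1m_score}, {scored.audit2m_score}, "
      f"{scored.audit3mv_score}; total {scored.total}; at risk: {scored.at_risk}")

# --- concordance from marginals --------------------------------------------
# fn + fp = 4 disagreements, fp - fn = 177 - 175, so fp = 3, fn = 1
table = TwoByTwo(tp=174, fn=1, fp=3, tn=6)
result = sensitivity_specificity(table)
print(f"sensitivity: {result.sensitivity * 100:.0f}% "
      f"[95% CI {result.ci_sensitivity[0] * 100:.1f}, {result.ci_sensitivity[1] * 100:.1f}]")
print(f"specificity: {result.specificity * 100:.0f}% "
      f"[95% CI {result.ci_specificity[0] * 100:.1f}, {result.ci_specificity[1] * 100:.1f}]")
# High sensitivity, modest specificity: the total score rarely misses an
# at-risk drinker but the small reference-negative group makes the
# specificity interval wide.
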