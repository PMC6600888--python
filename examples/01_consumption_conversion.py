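"""Convert shared, non-standard containers into standard drinks.

A respondent describes a drinking day as beverages: a full 375 mL can of
4.8% beer, and half a shared 1.25 L soft-drink bottle of 40% spirits.  The
entries convert to grams of ethanol (volume x abv x fullness x share x
count x 0.789 g/mL) and then to Australian standard drinks (10 g each).
"""

from grogscreen import (
    BeverageEntry,
    BeverageProduct,
    DrinkingOccasion,
    occasion_total_drinks,
)

catalog = {
    "beer_can": BeverageProduct("beer_can", "full-strength beer can", 0.048),
    "spirits": BeverageProduct("spirits", "spirits in a soft-drink bottle", 0.40),
}

occasion = DrinkingOccasion(
    days_before_survey=3,
    entries=(
        BeverageEntry("beer_can", 375.0),
        BeverageEntry("spirits", 1250.0, fullness=0.8, share=0.5),
    ),
)

total = occasion_total_drinks(occasion, catalog)
print(f"total on this occasion: {total:.2f} standard drinks")
# The beer can alone is 1.42 standard drinks; the shared spirits dominate.
# Totals above 4 standard drinks put the day over the short-term risk
# guideline threshold.
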