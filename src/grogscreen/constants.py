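"""Time-unit conventions used throughout the package.

All drinking frequencies are carried internally as occasions per day;
monthly and weekly rates are converted with the constants below so every
module agrees on what "per month" means.
"""

#: Mean calendar month length, 365.25 / 12 days.
DAYS_PER_MONTH: float = 365.25 / 12

DAYS_PER_WEEK: float = 7.0

#: Survey recall window: "in the last 12 months", inclusive of a leap day.
PAST_YEAR_WINDOW_DAYS: int = 366


def occasions_per_week_to_per_day(per_week: float) -> float:
    """Convert a weekly drinking rate to occasions per day.

    A once-per-week rate maps to 1/7 = 0.142857... occasions/day
    (0.14 at two decimals).
    """
    return per_week / DAYS_PER_WEEK


def occasions_per_month_to_per_day(per_month: float) -> float:
    """Convert a monthly drinking rate to occasions per day."""
    return per_month / DAYS_PER_MONTH
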