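"""Shared constants: age groups, drink-quantification tables, standard population.

The quantification tables map AUDIT-C style categorical survey items onto
continuous consumption (grams of pure alcohol per day).  Category midpoints
follow the standard AUDIT item coding; an average month is taken as
365.25/12 days.
"""

from __future__ import annotations

import numpy as np

# --- demographic frame -----------------------------------------------------

SEXES = ("male", "female")

#: Analysis age groups; the last group is open-ended.
AGE_GROUPS = ("15-29", "30-44", "45-59", "60+")

#: (lower, upper) bounds in years; upper bound is exclusive, None = open.
AGE_GROUP_BOUNDS = {
    "15-29": (15, 30),
    "30-44": (30, 45),
    "45-59": (45, 60),
    "60+": (60, None),
}

#: Upper age captured by the survey sampling frame (inclusive).
SURVEY_MAX_AGE = 64

#: Deaths below this age are excluded from attribution (exposure frame).
MIN_ATTRIBUTION_AGE = 15


def age_to_group(age: float) -> str | None:
    """Map an age in years to its analysis age group (None below 15)."""
    for group, (lo, hi) in AGE_GROUP_BOUNDS.items():
        if age >= lo and (hi is None or age < hi):
            return group
    return None


# --- consumption quantification --------------------------------------------

DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25

#: Grams of pure alcohol in one standard drink (configurable downstream).
GRAMS_PER_DRINK = 14.0

#: Density of pure ethanol, grams per millilitre.
ETHANOL_DENSITY_G_PER_ML = 0.789

#: Drinking-frequency item -> occasions per day (category midpoints).
FREQUENCY_OCCASIONS_PER_DAY = {
    "never": 0.0,
    "monthly_or_less": 0.5 / DAYS_PER_MONTH,        # midpoint of (0, 1] per month
    "2-4_per_month": 3.0 / DAYS_PER_MONTH,
    "2-3_per_week": 2.5 / 7.0,
    "4+_per_week": 5.5 / 7.0,                        # midpoint of 4..7 per week
}

#: Typical-quantity item -> drinks per occasion (category midpoints).
QUANTITY_DRINKS_PER_OCCASION = {
    "1-2": 1.5,
    "3-4": 3.5,
    "5-6": 5.5,
    "7-9": 8.0,
    "10+": 12.0,
}

#: Heavy-episodic-drinking frequency item -> implies at least one episode
#: in the past month.
HED_FREQUENCY_PAST_MONTH = {
    "never": False,
    "less_than_monthly": False,
    "monthly": True,
    "weekly": True,
    "daily_or_almost_daily": True,
}

#: Sex-specific drinks-per-occasion threshold for heavy episodic drinking.
HED_DRINK_THRESHOLD = {"male": 5.0, "female": 4.0}

#: Consumption cap, grams of pure alcohol per day.
CONSUMPTION_CAP_G_PER_DAY = 150.0

#: Grams-per-day threshold separating the HED-specific risk range.
HED_INTEGRATION_THRESHOLD_G = 60.0


def grams_per_day_to_litres_per_year(g_per_day: float) -> float:
    """Convert grams of pure alcohol/day to litres of pure alcohol/year."""
    return g_per_day * DAYS_PER_YEAR / (ETHANOL_DENSITY_G_PER_ML * 1000.0)


def litres_per_year_to_grams_per_day(litres_per_year: float) -> float:
    """Convert litres of pure alcohol/year to grams of pure alcohol/day."""
    return litres_per_year * ETHANOL_DENSITY_G_PER_ML * 1000.0 / DAYS_PER_YEAR


# --- standard population ----------------------------------------------------

#: WHO World Standard population (Ahmad et al. 2001), percent by 5-year band.
_WHO_WORLD_STANDARD = {
    (0, 5): 8.86, (5, 10): 8.69, (10, 15): 8.60, (15, 20): 8.47,
    (20, 25): 8.22, (25, 30): 7.93, (30, 35): 7.61, (35, 40): 7.15,
    (40, 45): 6.59, (45, 50): 6.04, (50, 55): 5.37, (55, 60): 4.55,
    (60, 65): 3.72, (65, 70): 2.96, (70, 75): 2.21, (75, 80): 1.52,
    (80, 85): 0.91, (85, None): 0.635,
}


def who_standard_weights(age_groups=AGE_GROUPS) -> dict[str, float]:
    """WHO World Standard weights collapsed to the analysis age groups.

    The 5-year bands at or above 15 years are pooled into each analysis
    group and renormalized to sum to one.
    """
    raw = {}
    for group in age_groups:
        lo, hi = AGE_GROUP_BOUNDS[group]
        total = 0.0
        for (blo, bhi), pct in _WHO_WORLD_STANDARD.items():
            if blo < 15:
                continue
            if blo >= lo and (hi is None or (bhi is not None and bhi <= hi)):
                total += pct
        raw[group] = total
    norm = sum(raw.values())
    return {g: v / norm for g, v in raw.items()}


def validate_weights(weights: dict[str, float], age_groups=AGE_GROUPS) -> None:
    missing = [g for g in age_groups if g not in weights]
    if missing:
        raise ValueError(f"standard weights missing age groups: {missing}")
    total = float(np.sum([weights[g] for g in age_groups]))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"standard weights sum to {total!r}, expected 1")
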