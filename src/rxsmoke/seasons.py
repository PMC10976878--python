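"""Calendar helpers for a non-leap 365-day study year.

Days are 1-based day-of-year integers. Seasons follow the standard
meteorological definition: spring = Mar-May, summer = Jun-Aug,
fall = Sep-Nov, winter = Dec-Feb. Prescribed burning is restricted to
spring and fall.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365
MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
# first day-of-year of each month (1-based)
MONTH_STARTS = tuple(int(x) for x in np.cumsum((1,) + MONTH_LENGTHS[:-1]))

SPRING_MONTHS = (3, 4, 5)
SUMMER_MONTHS = (6, 7, 8)
FALL_MONTHS = (9, 10, 11)
WINTER_MONTHS = (12, 1, 2)


def doy(month: int, day: int) -> int:
    """Day-of-year for a calendar date in a 365-day year."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    if not 1 <= day <= MONTH_LENGTHS[month - 1]:
        raise ValueError(f"day out of range for month {month}: {day}")
    return MONTH_STARTS[month - 1] + day - 1


def month_of(day_of_year: int | np.ndarray) -> np.ndarray:
    """Month number(s) for day(s)-of-year, vectorized."""
    d = np.asarray(day_of_year)
    if np.any((d < 1) | (d > DAYS_PER_YEAR)):
        raise ValueError("day of year out of range")
    return np.searchsorted(MONTH_STARTS, d, side="right")


def season_of(day_of_year: int | np.ndarray) -> np.ndarray:
    """Season label array ('winter'|'spring'|'summer'|'fall')."""
    m = month_of(day_of_year)
    out = np.full(np.shape(m), "winter", dtype="U6")
    out[np.isin(m, SPRING_MONTHS)] = "spring"
    out[np.isin(m, SUMMER_MONTHS)] = "summer"
    out[np.isin(m, FALL_MONTHS)] = "fall"
    return out


def burn_season_days() -> np.ndarray:
    """All spring (Mar 1-May 31) and fall (Sep 1-Nov 30) days-of-year."""
    spring = np.arange(doy(3, 1), doy(5, 31) + 1)
    fall = np.arange(doy(9, 1), doy(11, 30) + 1)
    return np.concatenate([spring, fall])


def days_in_months(months) -> np.ndarray:
    """All days-of-year falling in the given month numbers."""
    all_days = np.arange(1, DAYS_PER_YEAR + 1)
    return all_days[np.isin(month_of(all_days), list(months))]
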