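"""Age and cohort-calendar arithmetic shared across the pipeline.

All follow-up times are integer days since birth; ages in years are
``floor(days / 365.25)`` so the mapping is reproducible integer arithmetic.
Two cohort calendars are used: academic years (1 September - 31 August, the
closed-cohort definition) and UK financial years (1 April - 31 March, the
open-cohort definition).
"""

from __future__ import annotations

import datetime as dt

import numpy as np

#: days per year of age used throughout (includes leap days)
YEAR_DAYS = 365.25

#: first day (in days since birth) of each year of age 0..17
YEAR_START_DAYS = np.floor(np.arange(18) * YEAR_DAYS).astype(int)

#: days to the 16th birthday — the follow-up horizon of the closed design
AGE16_DAYS = int(YEAR_START_DAYS[16])  # 5844


def years_to_days(years: float) -> int:
    """First day of age ``years`` (e.g. 5 -> 1826)."""
    return int(np.floor(years * YEAR_DAYS))


def days_to_years(days):
    """Completed years of age at ``days`` since birth (vectorized)."""
    return np.floor(np.asarray(days) / YEAR_DAYS).astype(int)


def year_label(start_year: int) -> str:
    """Cohort label in the ``2002/3`` / ``2011/12`` style."""
    return f"{start_year}/{(start_year + 1) % 100}"


def label_start_year(label: str) -> int:
    return int(label.split("/")[0])


def academic_year(date: dt.date) -> int:
    """Start year of the academic year (Sep-Aug) containing ``date``."""
    return date.year if date.month >= 9 else date.year - 1


def financial_year(date: dt.date) -> int:
    """Start year of the UK financial year (Apr-Mar) containing ``date``."""
    return date.year if date.month >= 4 else date.year - 1


def academic_year_window(start_year: int) -> tuple[dt.date, dt.date]:
    """Inclusive (first, last) calendar day of academic year ``start_year``."""
    return dt.date(start_year, 9, 1), dt.date(start_year + 1, 8, 31)
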