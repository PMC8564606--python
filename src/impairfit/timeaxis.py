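"""Study time axis: (year, week) pairs, whole-week durations, seasons.

Study time is (year, week) with weeks 1..52; durations are whole weeks
computed on an absolute axis of 52 weeks per year.  Day-within-session
(1..3) disambiguates repeat captures only and never enters a duration.
"""

from __future__ import annotations

import datetime

import numpy as np

WEEKS_PER_YEAR = 52

#: calendar-month season map for the May-November trapping window
SEASON_BY_MONTH = {
    5: "spring", 6: "spring",
    7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}

#: default session start weeks: every 3-4 weeks, May through November
DEFAULT_SESSION_WEEKS = (18, 21, 25, 28, 32, 35, 39, 42, 46)


def abs_week(year, week):
    """Absolute week index (vectorised) for whole-week arithmetic."""
    return np.asarray(year, dtype=np.int64) * WEEKS_PER_YEAR + np.asarray(
        week, dtype=np.int64
    )


def month_of_week(year: int, week: int) -> int:
    """Calendar month containing the midpoint (Thursday) of an ISO-style week."""
    week = min(int(week), 52)
    return datetime.date.fromisocalendar(int(year), week, 4).month


def season_of_week(year: int, week: int) -> str:
    """Season label for a week; months outside May-November map to the
    nearest window edge (spring before May, fall after November)."""
    m = month_of_week(year, week)
    if m in SEASON_BY_MONTH:
        return SEASON_BY_MONTH[m]
    return "spring" if m < 5 else "fall"


def weeks_between(start: tuple[int, int], end: tuple[int, int]) -> int:
    """Whole-week difference end - start across year boundaries."""
    return int(abs_week(end[0], end[1]) - abs_week(start[0], start[1]))
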