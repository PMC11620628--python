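"""Fishing-closure schedules and the open-area fraction O experienced by a cohort.

Cohorts are anchored at a 1 March birth date, so calendar dates map onto
half-month age bins: 15 April is age 1.5 months, 1 July age 4 months,
1 August age 5 months, 1 October age 7 months. The spring gillnet closure
(15 April - 30 June by default) therefore covers bins 3-7 in a cohort's
first spring and, through the following year's closure, bins 27-29 in its
second spring.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import N_BINS
from .errors import ConfigurationError

SCENARIOS = ("actual", "start_aug1", "start_oct1", "year_round_ban")


def _date_to_age_months(month: int, day: int, *, end: bool) -> float:
    """Age (months since 1 March) of a month-day under the 2-bins-per-month rule.

    Window starts snap to the half-month containing the date; window ends are
    inclusive of the half-month containing the date.
    """
    months_since_march = (month - 3) % 12
    if end:
        return months_since_march + (0.5 if day <= 15 else 1.0)
    return months_since_march + (0.5 if day >= 15 else 0.0)


@dataclasses.dataclass
class ClosureSchedule:
    """Per-year spatial closure coverage plus the seasonal closure window.

    ``coverage[year]`` is the fraction of the juvenile distribution (birth
    lair sites) inside gillnet restriction areas in that year's spring
    closure. ``season_start``/``season_end`` are (month, day) pairs bounding
    the closed season inside the calendar year.
    """

    coverage: Mapping[int, float]
    season_start: tuple[int, int] = (4, 15)
    season_end: tuple[int, int] = (6, 30)
    scenario: str = "actual"

    def __post_init__(self) -> None:
        self.coverage = dict(self.coverage)
        for year, c in self.coverage.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigurationError(f"coverage {c} for {year} outside [0, 1]")
        start_age = _date_to_age_months(*self.season_start, end=False)
        end_age = _date_to_age_months(*self.season_end, end=True)
        if end_age < start_age:
            raise ConfigurationError("season_start must not fall after season_end")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")

    # -- derived geometry ---------------------------------------------------

    @property
    def years(self) -> list[int]:
        return sorted(self.coverage)

    def closed_bins_first_spring(self) -> np.ndarray:
        """Bins whose age interval lies inside the first-spring closed window."""
        start = _date_to_age_months(*self.season_start, end=False)
        end = _date_to_age_months(*self.season_end, end=True)
        ages = np.arange(N_BINS) * 0.5
        return np.flatnonzero((ages >= start) & (ages + 0.5 <= end))

    def closed_bins_second_spring(self) -> np.ndarray:
        """Bins covered by the *following* year's closure (ages 12+ months)."""
        start = 12.0 + _date_to_age_months(*self.season_start, end=False)
        end = min(15.0, 12.0 + _date_to_age_months(*self.season_end, end=True))
        ages = np.arange(N_BINS) * 0.5
        return np.flatnonzero((ages >= start) & (ages + 0.5 <= end))

    def _coverage_for(self, year: int) -> float:
        if year in self.coverage:
            return self.coverage[year]
        # second-spring lookups one past the study period clamp to the last year
        last = max(self.coverage)
        if year == last + 1:
            return self.coverage[last]
        raise KeyError(f"no closure coverage for year {year}")

    # -- the open fraction --------------------------------------------------

    def open_fraction(self, year: int, bin_index: int) -> float:
        """Open gillnet-area fraction O for the given cohort year and age bin."""
        if not 0 <= bin_index < N_BINS:
            raise ValueError(f"bin_index {bin_index} outside 0..{N_BINS - 1}")
        if self.scenario == "year_round_ban":
            return 0.0
        if bin_index in self.closed_bins_first_spring():
            return 1.0 - self._coverage_for(year)
        if bin_index in self.closed_bins_second_spring():
            return 1.0 - self._coverage_for(year + 1)
        return 1.0

    def open_vector(self, year: int) -> np.ndarray:
        """O over all 30 bins for one cohort year."""
        if self.scenario == "year_round_ban":
            return np.zeros(N_BINS)
        out = np.ones(N_BINS)
        out[self.closed_bins_first_spring()] = 1.0 - self._coverage_for(year)
        out[self.closed_bins_second_spring()] = 1.0 - self._coverage_for(year + 1)
        return out

    # -- I/O ------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "year": year,
                "coverage": self.coverage[year],
                "season_start": f"{self.season_start[0]:02d}-{self.season_start[1]:02d}",
                "season_end": f"{self.season_end[0]:02d}-{self.season_end[1]:02d}",
                "scenario": self.scenario,
            }
            for year in self.years
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClosureSchedule":
        coverage = dict(zip(frame["year"].astype(int), frame["coverage"].astype(float)))
        first = frame.iloc[0]
        start = tuple(int(x) for x in str(first["season_start"]).split("-"))
        end = tuple(int(x) for x in str(first["season_end"]).split("-"))
        scenario = str(first.get("scenario", "actual"))
        return cls(coverage=coverage, season_start=start, season_end=end, scenario=scenario)


def open_fraction(schedule: ClosureSchedule, year: int, bin_index: int) -> float:
    """Functional alias for :meth:`ClosureSchedule.open_fraction`."""
    return schedule.open_fraction(year, bin_index)


def interpolated_coverage(
    years: Iterable[int], start: float, end: float
) -> dict[int, float]:
    """Linear coverage ramp between the first and last year."""
    years = list(years)
    if len(years) == 1:
        return {years[0]: float(start)}
    lo, hi = years[0], years[-1]
    return {
        y: float(start + (end - start) * (y - lo) / (hi - lo)) for y in years
    }
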