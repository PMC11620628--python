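"""Counterfactual closure scenarios: delayed gillnet-season starts and a ban.

The spring closure normally lapses at the end of June (cohort age four
months). The counterfactuals keep each year's spatial coverage but extend
the closed window so gillnetting starts on 1 August (age five months) or
1 October (age seven months), or ban gillnets outright year-round. The
reported effect is the change in 15-month survivors relative to the actual
schedule — an instantaneous estimate that ignores multi-year cumulative
recruitment effects.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .closures import SCENARIOS, ClosureSchedule
from .config import N_BINS

#: season_end replacement per scenario (gillnetting starts the following day)
_SEASON_END = {
    "start_aug1": (7, 31),
    "start_oct1": (9, 30),
}


@dataclasses.dataclass
class ScenarioResult:
    """Per-year survival gain and per-bin bycatch under one counterfactual."""

    scenario: str
    years: list[int]
    delta_survivors: pd.Series
    bycatch_by_bin: pd.DataFrame  # years x 30 bins, under the scenario
    survivors: pd.Series


def apply_scenario(schedule: ClosureSchedule, scenario: str) -> ClosureSchedule:
    """Derive the counterfactual closure schedule for a scenario tag."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario == "actual":
        return dataclasses.replace(schedule, scenario="actual")
    if scenario == "year_round_ban":
        return dataclasses.replace(schedule, scenario="year_round_ban")
    return dataclasses.replace(
        schedule, season_end=_SEASON_END[scenario], scenario=scenario
    )


def scenario_delta(actual, counterfactual, scenario: str = "") -> ScenarioResult:
    """Per-year survivor gain of a counterfactual over the actual schedule.

    Both arguments are lists of :class:`~saimaa_bycatch.population.CohortTrajectory`
    covering the same years.
    """
    actual_by_year = {c.year: c for c in actual}
    cf_by_year = {c.year: c for c in counterfactual}
    if set(actual_by_year) != set(cf_by_year):
        raise ValueError(
            "actual and counterfactual trajectories cover different years"
        )
    years = sorted(actual_by_year)
    delta = pd.Series(
        {
            y: cf_by_year[y].survivors_15m - actual_by_year[y].survivors_15m
            for y in years
        },
        name="delta_survivors",
    )
    bycatch = pd.DataFrame(
        np.vstack([cf_by_year[y].bycatch for y in years]),
        index=years,
        columns=[f"bin_{i}" for i in range(N_BINS)],
    )
    survivors = pd.Series(
        {y: cf_by_year[y].survivors_15m for y in years}, name="survivors_15m"
    )
    return ScenarioResult(
        scenario=scenario,
        years=years,
        delta_survivors=delta,
        bycatch_by_bin=bycatch,
        survivors=survivors,
    )


def evaluate_scenarios(
    pups: pd.DataFrame,
    fit,
    pr,
    cause_model,
    schedule: ClosureSchedule,
    scenarios: tuple[str, ...] = ("start_aug1", "start_oct1", "year_round_ban"),
) -> dict[str, ScenarioResult]:
    """Run every counterfactual against the actual schedule.

    The fitted mortality and cause components are held fixed; only the
    open-area fractions change, so the deltas isolate the closure policy.
    """
    from .population import run_cohorts  # local import to avoid a cycle

    actual = run_cohorts(pups, fit, pr, cause_model, schedule)
    results = {}
    for tag in scenarios:
        cf_schedule = apply_scenario(schedule, tag)
        cf = run_cohorts(pups, fit, pr, cause_model, cf_schedule)
        results[tag] = scenario_delta(actual, cf, scenario=tag)
    return results
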