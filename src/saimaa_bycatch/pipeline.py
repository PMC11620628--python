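"""End-to-end reconstruction: carcasses + pups + closures -> annual results.

The pipeline fits the juvenile catch curve, the k-NN death proportions,
the cause-confidence forest, and the pooled adult survival, then runs the
cohort model for every birth year and projects the adult population.

Two estimation refinements are applied by default (both can be switched
off):

* closure-censoring weights — fishing carcasses are censored by the
  closures in proportion to the closed fraction of their (bin, year)
  stratum, so they are weighted by 1/O when fitting the cause model and
  the death proportions; the cohort model then re-multiplies by O.
* survivor calibration — the cohort model applies Pr to the survivors
  entering each bin, while raw carcass proportions estimate shares of
  deaths (tilted by cumulative survival). A second pass reweights each
  record by the reciprocal of the first pass's cumulative survival at its
  (bin, year).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .causes import (
    CauseConfidenceModel,
    closure_censoring_weights,
    fit_cause_model,
    group_cause_column,
)
from .closures import ClosureSchedule
from .config import N_BINS
from .mortality import (
    CatchCurveFit,
    DeathProportionModel,
    bin_carcass_ages,
    fit_catch_curve,
    fit_death_proportions,
)
from .population import (
    DEFAULT_START_TOTAL,
    AdultSurvival,
    CohortTrajectory,
    PopulationTrajectory,
    estimate_adult_survival,
    project_population,
    run_cohorts,
)

DEFAULT_K_GRID = [1, 2, 3, 5, 8, 13, 21, 30]

RESULT_COLUMNS = [
    "year",
    "est_bycatch",
    "obs_bycatch",
    "est_pups_born",
    "est_all_deaths",
    "est_other_deaths",
    "est_averted_bycatch",
    "est_survivors_15m",
    "est_population",
    "bycatch_rate",
]


@dataclasses.dataclass
class ReconstructionResult:
    """Fitted components and the annual results table of one reconstruction."""

    table: pd.DataFrame
    catch_curve: CatchCurveFit
    death_proportions: DeathProportionModel
    cause_model: CauseConfidenceModel
    adult_survival: AdultSurvival
    cohorts: list[CohortTrajectory]
    population: PopulationTrajectory


def _survivor_weights(
    carcasses: pd.DataFrame, cohorts: Sequence[CohortTrajectory]
) -> np.ndarray:
    """1 / (cumulative survival entering the record's bin) per juvenile row."""
    nu_by_year = {
        c.year: np.maximum(c.n[:N_BINS] / max(c.n_age0, 1e-12), 1e-6) for c in cohorts
    }
    juv = carcasses["stage"].to_numpy() == "juvenile"
    years = carcasses["year"].to_numpy()
    bins = carcasses["bin"].to_numpy()
    out = np.ones(len(carcasses))
    for pos in np.flatnonzero(juv):
        nu = nu_by_year.get(int(years[pos]))
        if nu is not None:
            out[pos] = 1.0 / nu[int(bins[pos])]
    return out


def reconstruct(
    carcasses: pd.DataFrame,
    pups: pd.DataFrame,
    schedule: ClosureSchedule,
    *,
    k_grid: Sequence[int] | None = None,
    rf_grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    start_total: float = DEFAULT_START_TOTAL,
    censoring_weights: bool = True,
    survivor_calibration: bool = True,
) -> ReconstructionResult:
    """Run the full estimation pipeline and assemble the annual table."""
    carcasses = group_cause_column(carcasses)
    k_grid = list(DEFAULT_K_GRID if k_grid is None else k_grid)

    juv_freqs = bin_carcass_ages(carcasses, "juvenile")
    catch_curve = fit_catch_curve(juv_freqs)

    is_juv = carcasses["stage"] == "juvenile"
    juv_df = carcasses.loc[is_juv]
    base_w = (
        closure_censoring_weights(carcasses, schedule)
        if censoring_weights
        else np.ones(len(carcasses))
    )

    def fit_components(weights: np.ndarray):
        pr_model = fit_death_proportions(
            carcasses, k_grid, weights=weights[is_juv.to_numpy()], seed=seed
        )
        cause_model = fit_cause_model(
            juv_df, rf_grid, seed=seed, sample_weight=weights[is_juv.to_numpy()]
        )
        return pr_model, cause_model

    pr_model, cause_model = fit_components(base_w)
    cohorts = run_cohorts(pups, catch_curve, pr_model, cause_model, schedule)

    if survivor_calibration:
        weights = base_w * _survivor_weights(carcasses, cohorts)
        pr_model = fit_death_proportions(
            carcasses, k_grid, weights=weights[is_juv.to_numpy()], seed=seed
        )
        cohorts = run_cohorts(pups, catch_curve, pr_model, cause_model, schedule)

    adult_survival = estimate_adult_survival(carcasses)
    population = project_population(cohorts, adult_survival, start_total=start_total)

    obs_bycatch = (
        juv_df.loc[juv_df["cause_group"] == "fishing"]
        .groupby("year")
        .size()
        .astype(int)
    )
    pup_idx = pups.set_index(pups["year"].astype(int))
    pop_totals = population.totals

    rows = []
    for c in cohorts:
        est_bycatch = c.total_bycatch
        other = float(c.deaths_other.sum())
        n_half_month = float(c.n[1])  # survivors at age 0.5 months
        rows.append(
            {
                "year": c.year,
                "est_bycatch": est_bycatch,
                "obs_bycatch": int(obs_bycatch.get(c.year, 0)),
                "est_pups_born": float(pup_idx.loc[c.year, "pups_born"]),
                "est_all_deaths": est_bycatch + other,
                "est_other_deaths": other,
                "est_averted_bycatch": float(c.averted.sum()),
                "est_survivors_15m": c.survivors_15m,
                "est_population": float(pop_totals.loc[c.year]),
                "bycatch_rate": est_bycatch / n_half_month if n_half_month > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return ReconstructionResult(
        table=table,
        catch_curve=catch_curve,
        death_proportions=pr_model,
        cause_model=cause_model,
        adult_survival=adult_survival,
        cohorts=cohorts,
        population=population,
    )
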