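"""Age-structured cohort model: juvenile bycatch partition and adult projection.

Each birth cohort is stepped through the 30 half-month bins from age 0 to
15 months. In bin i the potential deaths are N_i * exp(-b/2) * Pr_i; the
fishing-confidence share P(C_i) of them are would-be bycatch, of which the
open-area fraction O_i is realized and the closed fraction is averted
(those animals survive the bin). Non-fishing deaths occur in open and
closed areas alike. The 15-month survivors then recruit into a 30-class
adult projection with a pooled catch-curve annual survival, starting from
the 1990 abundance of 189 animals distributed across ages by the stable
distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .causes import CauseConfidenceModel
from .closures import ClosureSchedule
from .config import N_BINS
from .errors import EstimationError
from .mortality import (
    AgeFrequencyTable,
    CatchCurveFit,
    DeathProportionModel,
    bin_carcass_ages,
    fit_catch_curve,
)

N_ADULT_CLASSES = 30
DEFAULT_START_TOTAL = 189.0  # 1990 population size (mean of 164-210)


@dataclasses.dataclass
class CohortTrajectory:
    """One birth cohort stepped from age 0 to 15 months.

    ``n`` has 31 entries (animals alive entering each bin, plus the
    15-month survivors at the end); the per-bin vectors have 30.
    """

    year: int
    n: np.ndarray
    deaths_total: np.ndarray
    bycatch: np.ndarray
    deaths_other: np.ndarray
    averted: np.ndarray

    @property
    def n_age0(self) -> float:
        return float(self.n[0])

    @property
    def survivors_15m(self) -> float:
        return float(self.n[-1])

    @property
    def total_bycatch(self) -> float:
        return float(self.bycatch.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(N_BINS),
                "n": self.n[:-1],
                "deaths_total": self.deaths_total,
                "bycatch": self.bycatch,
                "deaths_other": self.deaths_other,
                "averted": self.averted,
            }
        ).assign(year=self.year)


@dataclasses.dataclass
class AdultSurvival:
    """Pooled adult catch-curve slope and the implied annual survival."""

    b_adult: float
    fit: CatchCurveFit | None = None

    @property
    def annual_survival(self) -> float:
        return float(np.exp(-self.b_adult))


@dataclasses.dataclass
class PopulationTrajectory:
    """Adult abundance by year across the 30 annual age classes."""

    years: list[int]
    ages: np.ndarray  # (n_years, 30)
    start_total: float

    @property
    def totals(self) -> pd.Series:
        return pd.Series(self.ages.sum(axis=1), index=self.years, name="population")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.ages, index=self.years, columns=[f"age_{a}" for a in range(1, 31)]
        )
        frame.insert(0, "total", self.ages.sum(axis=1))
        frame.index.name = "year"
        return frame


# ---------------------------------------------------------------------------
# Juvenile cohort stepping
# ---------------------------------------------------------------------------


def init_cohort(pups: pd.DataFrame, year: int) -> float:
    """N_age0 = pups born minus observed age-0 deaths for one cohort year."""
    rows = pups.loc[pups["year"] == year]
    if rows.empty:
        raise KeyError(f"year {year} not present in the pup table")
    row = rows.iloc[0]
    born = float(row["pups_born"])
    observed0 = float(row["observed_age0_deaths"])
    if observed0 > born:
        raise ValueError(
            f"observed age-0 deaths ({observed0}) exceed pups born ({born}) in {year}"
        )
    return born - observed0


def _as_factor(fit: CatchCurveFit | float) -> float:
    if isinstance(fit, CatchCurveFit):
        return fit.half_month_factor
    return float(np.exp(-float(fit) / 2.0))


def _as_pr(pr: DeathProportionModel | np.ndarray) -> np.ndarray:
    vec = pr.pr if isinstance(pr, DeathProportionModel) else np.asarray(pr, dtype=float)
    if vec.shape != (N_BINS,):
        raise ValueError(f"Pr must have {N_BINS} entries")
    return vec


def step_cohort(
    n_age0: float,
    fit: CatchCurveFit | float,
    pr: DeathProportionModel | np.ndarray,
    conf: np.ndarray,
    open_frac: np.ndarray,
    *,
    year: int = 0,
) -> CohortTrajectory:
    """Step one cohort through the 30 half-month bins.

    ``conf`` is the per-bin fishing confidence P(C) (its first entry must
    be 0: no bycatch is possible in the first half-month) and ``open_frac``
    the per-bin open-area fraction O. Potential deaths that are fishing
    deaths in a closed fraction are averted and survive.
    """
    m = _as_factor(fit)
    pr_vec = _as_pr(pr)
    conf = np.asarray(conf, dtype=float)
    open_frac = np.asarray(open_frac, dtype=float)
    if conf.shape != (N_BINS,) or open_frac.shape != (N_BINS,):
        raise ValueError(f"conf and open_frac must have {N_BINS} entries")
    if conf[0] != 0.0:
        raise ValueError("fishing confidence of bin 0 must be 0")
    if ((conf < 0) | (conf > 1)).any() or ((open_frac < 0) | (open_frac > 1)).any():
        raise ValueError("conf and open_frac entries must lie in [0, 1]")
    if (m * pr_vec > 1.0).any():
        raise EstimationError(
            "per-bin death fraction exp(-b/2)*Pr exceeds 1: implausible inputs"
        )

    n = np.empty(N_BINS + 1)
    n[0] = float(n_age0)
    deaths_total = np.empty(N_BINS)
    bycatch = np.empty(N_BINS)
    deaths_other = np.empty(N_BINS)
    averted = np.empty(N_BINS)
    for i in range(N_BINS):
        potential = n[i] * m * pr_vec[i]
        bycatch[i] = potential * conf[i] * open_frac[i]
        averted[i] = potential * conf[i] * (1.0 - open_frac[i])
        deaths_other[i] = potential * (1.0 - conf[i])
        deaths_total[i] = bycatch[i] + deaths_other[i]
        n[i + 1] = n[i] - deaths_total[i]
    return CohortTrajectory(
        year=year,
        n=n,
        deaths_total=deaths_total,
        bycatch=bycatch,
        deaths_other=deaths_other,
        averted=averted,
    )


def run_cohorts(
    pups: pd.DataFrame,
    fit: CatchCurveFit | float,
    pr: DeathProportionModel | np.ndarray,
    cause_model: CauseConfidenceModel | np.ndarray,
    schedule: ClosureSchedule,
) -> list[CohortTrajectory]:
    """One trajectory per cohort year, with year-specific P(C) and O.

    ``cause_model`` may be a fitted confidence model (queried per year,
    averaged over its zones) or a fixed 30-vector of fishing confidences.
    """
    trajectories = []
    for year in sorted(pups["year"].astype(int)):
        if isinstance(cause_model, CauseConfidenceModel):
            conf = cause_model.fishing_confidence_profile(year)
        else:
            conf = np.asarray(cause_model, dtype=float)
        open_vec = schedule.open_vector(year)
        n0 = init_cohort(pups, year)
        trajectories.append(
            step_cohort(n0, fit, pr, conf, open_vec, year=year)
        )
    return trajectories


# ---------------------------------------------------------------------------
# Adults
# ---------------------------------------------------------------------------


def estimate_adult_survival(carcasses: pd.DataFrame) -> AdultSurvival:
    """Pooled adult survival exp(-b) from the 1-year-bin catch curve."""
    freqs = bin_carcass_ages(carcasses, "adult")
    fit = fit_catch_curve(freqs)
    return AdultSurvival(b_adult=fit.b, fit=fit)


def stable_age_distribution(annual_survival: float) -> np.ndarray:
    """Stable distribution over adult classes 1..30, proportional to s^(a-1)."""
    weights = annual_survival ** np.arange(N_ADULT_CLASSES, dtype=float)
    return weights / weights.sum()


def project_population(
    cohorts: list[CohortTrajectory],
    surv: AdultSurvival | float,
    start_total: float = DEFAULT_START_TOTAL,
) -> PopulationTrajectory:
    """Project the 30-class adult population over the cohort years.

    The year before the first cohort is seeded with ``start_total`` animals
    in the stable age distribution. Each subsequent year ages every class
    by the annual survival (class 30 exits) and recruits the 15-month
    survivors of the cohort born the previous year into class 1; for the
    first projected year, where no earlier cohort exists, the first
    cohort's survivors stand in.
    """
    if not cohorts:
        raise ValueError("no cohort trajectories supplied")
    s = surv.annual_survival if isinstance(surv, AdultSurvival) else float(surv)
    by_year = {c.year: c for c in cohorts}
    years = sorted(by_year)
    if years != list(range(years[0], years[-1] + 1)):
        missing = sorted(set(range(years[0], years[-1] + 1)) - set(years))
        raise KeyError(f"missing cohort trajectories for projection years {missing}")

    state = stable_age_distribution(s) * float(start_total)
    rows = [state]
    out_years = [years[0] - 1]
    for year in years:
        prev = by_year.get(year - 1, by_year[year])  # stand-in for the first year
        new = np.empty(N_ADULT_CLASSES)
        new[1:] = state[:-1] * s  # class 30 exits the population
        new[0] = prev.survivors_15m
        state = new
        rows.append(state)
        out_years.append(year)
    return PopulationTrajectory(
        years=out_years, ages=np.vstack(rows), start_total=float(start_total)
    )
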