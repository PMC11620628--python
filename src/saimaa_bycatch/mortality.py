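"""Catch-curve total mortality and k-NN-smoothed age-specific death proportions.

The catch curve reads total mortality off the log-linear decline of carcass
age frequencies (ln(count+1) against age), assuming a closed population in
which mortality alone thins the cohort. Because real mortality is not
age-constant, a k-nearest-neighbour smoother over the half-month age bins
supplies the nonlinear proportion-of-deaths profile Pr that the cohort
model combines with the catch-curve factor exp(-b/2).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .config import N_BINS
from .errors import EstimationError

logger = logging.getLogger(__name__)

ADULT_MAX_AGE = 30  # annual age classes 1..30


@dataclasses.dataclass
class AgeFrequencyTable:
    """Carcass counts per age bin, with the ln(count+1) transform attached.

    Juvenile tables use the 30 half-month bins (ages in months); adult
    tables use 1-year bins 1..30 (ages in years).
    """

    stage: str
    bins: np.ndarray
    ages: np.ndarray
    counts: np.ndarray

    @property
    def log_counts(self) -> np.ndarray:
        return np.log(self.counts + 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bins,
                "age": self.ages,
                "count": self.counts,
                "log_count": self.log_counts,
            }
        )


@dataclasses.dataclass
class CatchCurveFit:
    """Fitted catch-curve slope, stored as a non-negative magnitude.

    ``b`` is per month for juvenile fits and per year for adult fits;
    ``half_month_factor`` is exp(-b/2), the allocation factor applied per
    half-month bin by the cohort model.
    """

    b: float
    intercept: float
    r_squared: float
    stage: str
    n_bins_used: int

    @property
    def half_month_factor(self) -> float:
        return math.exp(-self.b / 2.0)


@dataclasses.dataclass
class DeathProportionModel:
    """k-NN-smoothed proportions of juvenile deaths per half-month bin."""

    k: int
    pr: np.ndarray
    cv_error_by_k: dict[int, float]

    def __post_init__(self) -> None:
        self.pr = np.asarray(self.pr, dtype=float)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def _stage_mask(carcasses: pd.DataFrame, stage: str) -> pd.DataFrame:
    if "stage" in carcasses.columns:
        return carcasses[carcasses["stage"] == stage]
    return carcasses


def bin_carcass_ages(carcasses: pd.DataFrame, stage: str) -> AgeFrequencyTable:
    """Tally carcass ages into half-month (juvenile) or 1-year (adult) bins.

    Zero-count bins are retained. Records with negative ages, juveniles of
    15 months or older, and adults outside 1-30 years are rejected with a
    logged warning.
    """
    if stage not in ("juvenile", "adult"):
        raise ValueError(f"stage must be 'juvenile' or 'adult', got {stage!r}")
    df = _stage_mask(carcasses, stage)
    if stage == "juvenile":
        edges_bins = np.arange(N_BINS)
        ages_months = df["age_months"].to_numpy(dtype=float) if len(df) else np.array([])
        bad = ages_months < 0
        if bad.any():
            logger.warning("rejecting %d records with negative ages", bad.sum())
        ages_months = ages_months[~bad]
        out_of_range = ages_months >= N_BINS * 0.5
        if out_of_range.any():
            logger.warning(
                "rejecting %d juvenile records aged 15 months or older",
                out_of_range.sum(),
            )
        ages_months = ages_months[~out_of_range]
        bins = np.floor(ages_months / 0.5).astype(int)
        counts = np.bincount(bins, minlength=N_BINS)[:N_BINS]
        return AgeFrequencyTable(
            stage="juvenile",
            bins=edges_bins,
            ages=edges_bins * 0.5,
            counts=counts.astype(int),
        )
    edges_bins = np.arange(1, ADULT_MAX_AGE + 1)
    ages_years = df["age_years"].to_numpy(dtype=float) if len(df) else np.array([])
    bad = ages_years < 0
    if bad.any():
        logger.warning("rejecting %d records with negative ages", bad.sum())
    ages_years = ages_years[~bad]
    keep = (ages_years >= 1.0) & (ages_years < ADULT_MAX_AGE + 1)
    if (~keep).any():
        logger.warning(
            "rejecting %d adult records outside ages 1-30 years", (~keep).sum()
        )
    bins = np.floor(ages_years[keep]).astype(int)
    counts = np.bincount(bins, minlength=ADULT_MAX_AGE + 1)[1 : ADULT_MAX_AGE + 1]
    return AgeFrequencyTable(
        stage="adult",
        bins=edges_bins,
        ages=edges_bins.astype(float),
        counts=counts.astype(int),
    )


# ---------------------------------------------------------------------------
# Catch curve
# ---------------------------------------------------------------------------


def fit_catch_curve(freqs: AgeFrequencyTable) -> CatchCurveFit:
    """Ordinary least squares of ln(count+1) on age, over the descending limb.

    The fit starts at the modal bin (standard catch-curve practice, to
    avoid bias from under-recruited early bins) and ``b`` is stored as the
    magnitude of the negative slope. A non-negative slope is clamped to
    zero with a warning.
    """
    counts = np.asarray(freqs.counts, dtype=float)
    if (counts > 0).sum() < 3:
        raise EstimationError(
            "catch-curve fit needs at least 3 age bins with positive counts"
        )
    modal = int(np.argmax(counts))
    ages = np.asarray(freqs.ages, dtype=float)[modal:]
    y = np.log(counts[modal:] + 1.0)
    if np.allclose(y, y[0]):
        return CatchCurveFit(
            b=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            stage=freqs.stage,
            n_bins_used=len(y),
        )
    res = stats.linregress(ages, y)
    slope = float(res.slope)
    if slope >= 0:
        warnings.warn(
            f"catch-curve slope {slope:.4f} is non-negative; clamping b to 0",
            stacklevel=2,
        )
        b = 0.0
    else:
        b = -slope
    return CatchCurveFit(
        b=b,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        stage=freqs.stage,
        n_bins_used=len(y),
    )


# ---------------------------------------------------------------------------
# k-NN death proportions
# ---------------------------------------------------------------------------

# neighbour order per bin: ascending |i-j|, ties broken toward the smaller bin
_NEIGHBOUR_ORDER = np.array(
    [sorted(range(N_BINS), key=lambda j, i=i: (abs(i - j), j)) for i in range(N_BINS)]
)


def empirical_bin_proportions(
    bins: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """(Weighted) share of deaths per half-month bin; sums to 1."""
    w = np.ones(len(bins)) if weights is None else np.asarray(weights, dtype=float)
    totals = np.bincount(np.asarray(bins, dtype=int), weights=w, minlength=N_BINS)[
        :N_BINS
    ]
    s = totals.sum()
    if s <= 0:
        return np.full(N_BINS, 1.0 / N_BINS)
    return totals / s


def knn_smooth_proportions(props: np.ndarray, k: int) -> np.ndarray:
    """Average each bin's proportion over its k nearest bins, then renormalize.

    The neighbourhood is over the bin index with absolute-difference
    distance (the bin itself included); k of 30 or more therefore returns
    the global mean proportion in every bin.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    k_eff = min(int(k), N_BINS)
    smoothed = props[_NEIGHBOUR_ORDER[:, :k_eff]].mean(axis=1)
    s = smoothed.sum()
    if s <= 0:
        return np.full(N_BINS, 1.0 / N_BINS)
    return smoothed / s


def _juvenile_bins(carcasses: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Half-month bin per juvenile record, plus the kept row positions."""
    df = _stage_mask(carcasses, "juvenile")
    ages = df["age_months"].to_numpy(dtype=float)
    keep = (ages >= 0) & (ages < N_BINS * 0.5)
    return np.floor(ages[keep] / 0.5).astype(int), np.flatnonzero(keep)


def fit_death_proportions(
    carcasses: pd.DataFrame,
    k_grid: list[int],
    *,
    weights: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> DeathProportionModel:
    """Select k by 10-fold cross-validation and smooth the death proportions.

    For each candidate k the per-fold loss is the squared error between the
    k-NN-smoothed training proportions and the held-out fold's empirical
    bin proportions; the k with minimal mean loss wins, ties going to the
    smallest k. Candidates exceeding the training sample size are skipped
    with a warning. Optional per-record ``weights`` (aligned with the
    juvenile rows of the table) enter both the smoothing and the loss.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    df = _stage_mask(carcasses, "juvenile")
    bins_all, kept_pos = _juvenile_bins(carcasses)
    if weights is not None:
        w_all = np.asarray(weights, dtype=float)
        if len(w_all) != len(df):
            raise ValueError("weights must align with the table's juvenile rows")
        w_all = w_all[kept_pos]
    else:
        w_all = np.ones(len(bins_all))
    n = len(bins_all)
    if n < 10:
        raise EstimationError(
            f"need at least 10 juvenile records to fit death proportions, got {n}"
        )

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(bins_all))
    n_train_min = min(len(train) for train, _ in folds)

    cv_error: dict[int, float] = {}
    for k in sorted(set(int(k) for k in k_grid)):
        if k < 1:
            raise ValueError("k candidates must be positive integers")
        if k > n_train_min:
            warnings.warn(
                f"skipping k={k}: larger than the training sample ({n_train_min})",
                stacklevel=2,
            )
            continue
        losses = []
        for train, test in folds:
            p_train = empirical_bin_proportions(bins_all[train], w_all[train])
            p_test = empirical_bin_proportions(bins_all[test], w_all[test])
            smoothed = knn_smooth_proportions(p_train, k)
            losses.append(float(np.sum((smoothed - p_test) ** 2)))
        cv_error[k] = float(np.mean(losses))
    if not cv_error:
        raise EstimationError("every k candidate was skipped; nothing to select")

    best_k = min(cv_error, key=lambda k: (cv_error[k], k))
    pr = knn_smooth_proportions(empirical_bin_proportions(bins_all, w_all), best_k)
    return DeathProportionModel(k=best_k, pr=pr, cv_error_by_k=cv_error)
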