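"""Cause-of-death grouping and the random-forest cause-confidence model.

Twelve raw necropsy causes collapse into four analysis groups (stillborn,
lair death, fishing, other). A random forest fitted on (age bin, year,
zone) yields, for any stratum, a confidence distribution over the four
groups; its fishing component is the P(C_age) consumed by the cohort
model. Because no bycatch has ever been recorded in the first half-month
of life, the fishing confidence of bin 0 is pinned to zero.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from .closures import ClosureSchedule
from .config import CAUSE_GROUPS, N_BINS
from .errors import EstimationError

logger = logging.getLogger(__name__)

#: Raw necropsy labels -> analysis group (total and deterministic).
RAW_TO_GROUP: dict[str, str] = {
    "stillborn": "stillborn",
    "predated lair deaths": "lair_death",
    "other lair deaths": "lair_death",
    "unweaned other deaths": "lair_death",
    "fishing (self-reported)": "fishing",
    "suffocation": "fishing",
    "natural": "other",
    "unknown": "other",
    "accidental": "other",
    "cancer": "other",
    "boat collision": "other",
    "violence": "other",
}

#: Conditional frequencies of raw labels within each group, matching the
#: pooled 1991-2021 carcass record; used by the synthetic generator.
RAW_WITHIN_GROUP: dict[str, dict[str, float]] = {
    "stillborn": {"Stillborn": 1.0},
    "lair_death": {
        "Predated lair deaths": 5 / 108,
        "Other lair deaths": 97 / 108,
        "Unweaned other deaths": 6 / 108,
    },
    "fishing": {"Fishing (self-reported)": 142 / 163, "Suffocation": 21 / 163},
    "other": {
        "Natural": 26 / 220,
        "Unknown": 186 / 220,
        "Accidental": 1 / 220,
        "Cancer": 2 / 220,
        "Boat collision": 4 / 220,
        "Violence": 1 / 220,
    },
}

#: Split-criterion vocabulary -> scikit-learn criterion. ``accuracy`` and
#: ``gain_ratio`` are aliased to the nearest available impurity measure;
#: the alias actually used is recorded in the fitted model's metadata.
CRITERION_ALIASES = {
    "gini": "gini",
    "accuracy": "gini",
    "information_gain": "entropy",
    "entropy": "entropy",
    "gain_ratio": "log_loss",
}

DEFAULT_GRID: dict[str, list] = {
    "trees": [100],
    "depth": [None, 8],
    "criterion": ["gini"],
    "pruning_confidence": [0.0],
}


def map_cause_groups(raw_cause: str) -> str:
    """Map one raw cause-of-death label to its analysis group."""
    key = str(raw_cause).strip().lower()
    if key not in RAW_TO_GROUP:
        raise KeyError(f"unknown cause of death label {raw_cause!r}")
    return RAW_TO_GROUP[key]


def group_cause_column(carcasses: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``cause_group`` column; unmappable rows dropped.

    Rows whose ``cause_raw`` is not one of the twelve known labels are
    rejected with a logged warning.
    """
    df = carcasses.copy()
    keys = df["cause_raw"].astype(str).str.strip().str.lower()
    known = keys.isin(RAW_TO_GROUP)
    if not known.all():
        bad = sorted(df.loc[~known, "cause_raw"].unique())
        logger.warning("dropping %d records with unknown causes %s", (~known).sum(), bad)
    df = df.loc[known].copy()
    df["cause_group"] = keys[known].map(RAW_TO_GROUP)
    return df


def grouped_frequencies(carcasses: pd.DataFrame) -> pd.Series:
    """Tally of carcasses per analysis group (index ordered as CAUSE_GROUPS)."""
    df = group_cause_column(carcasses)
    counts = df["cause_group"].value_counts()
    return counts.reindex(CAUSE_GROUPS, fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# Random-forest confidence model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CauseConfidenceModel:
    """A fitted cause-group confidence model.

    ``hyperparameters`` keeps the selected configuration in the original
    vocabulary (trees, depth, criterion, pruning confidence); ``cv_score``
    is the mean 10-fold multiclass log-loss of that configuration.
    """

    estimator: object
    classes_: tuple[str, ...]
    hyperparameters: dict
    cv_score: float
    zones: tuple
    feature_spec: tuple[str, ...] = ("bin", "year", "zone")

    @property
    def degenerate(self) -> bool:
        return len(self.classes_) == 1

    def _proba_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """(n, 4) confidence matrix in CAUSE_GROUPS order, bin-0 rule applied."""
        out = np.zeros((len(frame), len(CAUSE_GROUPS)))
        if self.degenerate:
            out[:, CAUSE_GROUPS.index(self.classes_[0])] = 1.0
        else:
            proba = self.estimator.predict_proba(frame[list(self.feature_spec)])
            for j, label in enumerate(self.estimator.classes_):
                out[:, CAUSE_GROUPS.index(label)] = proba[:, j]
        # no bycatch is possible during the first half-month of life
        fishing = CAUSE_GROUPS.index("fishing")
        bin0 = frame["bin"].to_numpy() == 0
        out[bin0, fishing] = 0.0
        row_sums = out.sum(axis=1)
        empty = row_sums <= 0
        out[empty, CAUSE_GROUPS.index("other")] = 1.0
        row_sums = out.sum(axis=1)
        return out / row_sums[:, None]

    def predict_confidences(self, age_bin: int, year: int, zone) -> np.ndarray:
        """Length-4 confidence simplex for one (age bin, year, zone) stratum."""
        if not 0 <= age_bin < N_BINS:
            raise ValueError(f"age_bin {age_bin} outside 0..{N_BINS - 1}")
        frame = pd.DataFrame({"bin": [age_bin], "year": [year], "zone": [zone]})
        return self._proba_frame(frame)[0]

    def fishing_confidence_profile(self, year: int, zones: Sequence | None = None) -> np.ndarray:
        """P(C_age) over all 30 bins for one year, averaged across zones."""
        zones = list(zones) if zones is not None else list(self.zones)
        frame = pd.DataFrame(
            [
                {"bin": b, "year": year, "zone": z}
                for b in range(N_BINS)
                for z in zones
            ]
        )
        conf = self._proba_frame(frame)[:, CAUSE_GROUPS.index("fishing")]
        return conf.reshape(N_BINS, len(zones)).mean(axis=1)


def _build_pipeline(seed: int) -> Pipeline:
    pre = ColumnTransformer(
        [("cat", OneHotEncoder(handle_unknown="ignore"), ["year", "zone"])],
        remainder="passthrough",
    )
    rf = RandomForestClassifier(random_state=seed, n_jobs=1)
    return Pipeline([("prep", pre), ("rf", rf)])


def _rf_params(trees: int, depth, criterion: str, pruning: float) -> dict:
    crit = str(criterion).strip().lower()
    if crit not in CRITERION_ALIASES:
        raise ValueError(f"unknown split criterion {criterion!r}")
    params = {
        "rf__n_estimators": int(trees),
        "rf__criterion": CRITERION_ALIASES[crit],
        "rf__ccp_alpha": float(pruning),
        "rf__min_impurity_decrease": 0.0,
        "rf__max_depth": None if depth in (None, "none") else int(depth),
    }
    if depth == 0:
        # a depth-0 tree is a single root leaf: forbid any split
        params["rf__max_depth"] = 1
        params["rf__min_impurity_decrease"] = 1e18
    return params


def fit_cause_model(
    carcasses: pd.DataFrame,
    grid: Mapping[str, Sequence] | None = None,
    *,
    seed: int = 0,
    sample_weight: np.ndarray | None = None,
    n_folds: int = 10,
    bootstrap: bool = True,
) -> CauseConfidenceModel:
    """Grid-search a random forest over (trees, depth, criterion, pruning).

    Configurations are scored by stratified ``n_folds``-fold cross-validated
    multiclass log-loss; the best one (ties broken by grid order) is refit
    on all data. With a single-configuration grid the cross-validation is
    skipped. Single-class data yield a degenerate model with a warning.
    """
    df = carcasses
    if "cause_group" not in df.columns:
        df = group_cause_column(df)
    X = df[["bin", "year", "zone"]].reset_index(drop=True)
    y = df["cause_group"].reset_index(drop=True)
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if w is not None and len(w) != len(y):
        raise ValueError("sample_weight length does not match the carcass table")

    classes = tuple(sorted(y.unique()))
    if len(classes) == 1:
        warnings.warn(
            f"single cause group {classes[0]!r}: returning a degenerate model",
            stacklevel=2,
        )
        return CauseConfidenceModel(
            estimator=None,
            classes_=classes,
            hyperparameters={},
            cv_score=0.0,
            zones=tuple(sorted(X["zone"].unique())),
        )
    if len(df) < 40:
        raise EstimationError(
            f"need at least 40 grouped records to fit the cause model, got {len(df)}"
        )

    grid = dict(DEFAULT_GRID if grid is None else grid)
    combos = list(
        itertools.product(
            grid["trees"], grid["depth"], grid["criterion"], grid["pruning_confidence"]
        )
    )
    base = _build_pipeline(seed)
    base.set_params(rf__bootstrap=bootstrap)

    best = None
    if len(combos) > 1:
        min_class = y.value_counts().min()
        folds = min(n_folds, int(min_class))
        if folds < n_folds:
            warnings.warn(
                f"reducing CV folds from {n_folds} to {folds}: smallest class has "
                f"{min_class} records",
                stacklevel=2,
            )
        if folds < 2:
            raise EstimationError("cannot cross-validate with a singleton class")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = []
        for combo in combos:
            params = _rf_params(*combo)
            losses = []
            for train, test in cv.split(X, y):
                model = clone(base).set_params(**params)
                fit_kw = {}
                if w is not None:
                    fit_kw["rf__sample_weight"] = w[train]
                model.fit(X.iloc[train], y.iloc[train], **fit_kw)
                proba = model.predict_proba(X.iloc[test])
                losses.append(
                    log_loss(
                        y.iloc[test],
                        proba,
                        labels=list(model.classes_),
                        sample_weight=None if w is None else w[test],
                    )
                )
            scores.append(float(np.mean(losses)))
        best_idx = int(np.argmin(scores))
        best, best_score = combos[best_idx], scores[best_idx]
    else:
        best, best_score = combos[0], float("nan")

    final = clone(base).set_params(**_rf_params(*best))
    fit_kw = {} if w is None else {"rf__sample_weight": w}
    final.fit(X, y, **fit_kw)
    trees, depth, criterion, pruning = best
    return CauseConfidenceModel(
        estimator=final,
        classes_=tuple(final.classes_),
        hyperparameters={
            "trees": trees,
            "depth": depth,
            "criterion": criterion,
            "criterion_used": CRITERION_ALIASES[str(criterion).strip().lower()],
            "pruning_confidence": pruning,
        },
        cv_score=best_score,
        zones=tuple(sorted(X["zone"].unique())),
    )


def predict_confidences(
    model: CauseConfidenceModel, age_bin: int, year: int, zone
) -> np.ndarray:
    """Functional alias for :meth:`CauseConfidenceModel.predict_confidences`."""
    if model is None:
        raise EstimationError("cause model has not been fitted")
    return model.predict_confidences(age_bin, year, zone)


def closure_censoring_weights(
    carcasses: pd.DataFrame,
    schedule: ClosureSchedule,
    *,
    cap: float = 100.0,
) -> np.ndarray:
    """Inverse-probability weights undoing closure censoring of fishing deaths.

    A fishing death in a stratum with open fraction O is observed with
    relative inclusion probability O, so each observed fishing carcass
    represents 1/O potential fishing deaths. Weighting by 1/O lets the
    cause model and the death-proportion smoother estimate closure-free
    quantities, which the cohort model then re-multiplies by O. Weights
    are capped (a fishing record in a fully closed stratum is
    contradictory and triggers a warning).
    """
    df = carcasses
    weights = np.ones(len(df))
    is_juv_fishing = (
        (df["stage"].to_numpy() == "juvenile")
        & (df["cause_group"].to_numpy() == "fishing")
    )
    for pos in np.flatnonzero(is_juv_fishing):
        row = df.iloc[pos]
        o = schedule.open_fraction(int(row["year"]), int(row["bin"]))
        if o <= 1.0 / cap:
            warnings.warn(
                f"fishing carcass in a (nearly) fully closed stratum "
                f"(year {row['year']}, bin {row['bin']}): weight capped",
                stacklevel=2,
            )
            weights[pos] = cap
        else:
            weights[pos] = 1.0 / o
    return weights
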