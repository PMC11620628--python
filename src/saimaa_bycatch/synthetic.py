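"""Seeded synthetic carcass, pup-cohort, and closure data with known truth.

The generator is the generative inverse of the cohort model: each cohort
loses, in every half-month bin, a potential-death fraction
``exp(-true_b/2) * w_bin``; potential deaths are assigned a cause group by
the age-specific mix; would-be fishing deaths inside the closed
area-season fraction are averted (those animals survive); the remaining
deaths are thinned by cause-specific detection probabilities into the
observed carcass table.

The per-bin weights ``w`` are solved per year from the configured seasonal
shape so that the *expected observed* carcass age frequencies decline
log-linearly at exactly the configured slope ``true_b`` — the assumption
the catch-curve estimator reads the data through. The seasonal shape is
log-detrended against age first, so seasonality modulates but does not
tilt the catch curve.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .causes import CAUSE_GROUPS, RAW_WITHIN_GROUP
from .closures import ClosureSchedule, interpolated_coverage
from .config import N_BINS, SimulationConfig
from .errors import ConfigurationError

_STREAM_BIN0 = 0
_STREAM_DEATHS = 1
_STREAM_DETECT = 2
_STREAM_ATTRS = 3
_STREAM_ADULTS = 4

CARCASS_COLUMNS = [
    "year",
    "stage",
    "age_months",
    "age_years",
    "bin",
    "cause_raw",
    "cause_group",
    "zone",
]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth accompanying one synthetic carcass table.

    ``deaths_by_bin`` holds realized deaths per cohort year and bin, split
    by cause group, plus the averted (closure-saved) would-be bycatch.
    Conservation holds exactly: pups born = total realized deaths +
    15-month survivors, for every cohort.
    """

    deaths_by_bin: pd.DataFrame
    bycatch_total: pd.Series
    survivors_15m: pd.Series
    potential_weights: dict[int, np.ndarray]
    potential_fractions: dict[int, np.ndarray]

    def total_deaths(self) -> pd.Series:
        cols = list(CAUSE_GROUPS)
        return self.deaths_by_bin.groupby("year")[cols].sum().sum(axis=1)


def _detrended_seasonality(config: SimulationConfig) -> np.ndarray:
    """Seasonal weights with the log-linear age trend removed (OLS on ln s)."""
    s = np.asarray(config.seasonal_bycatch_weights, dtype=float)
    s = np.where(s <= 0, 1e-12, s)
    ages = np.arange(N_BINS) * 0.5
    logs = np.log(s)
    beta = np.polyfit(ages, logs, 1)
    return np.exp(logs - np.polyval(beta, ages))


def solve_bin_weights(
    config: SimulationConfig, open_vec: np.ndarray, *, n_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin potential-death weights for one cohort year.

    Returns ``(w, nu, f)`` where ``w`` sums to 1, ``f = scale*exp(-b/2)*w``
    is the potential-death fraction applied to the survivors entering each
    bin, and ``nu`` is the expected cumulative survival entering each bin.
    ``w`` solves the fixed point making expected observed counts
    proportional to ``exp(-b*age) * seasonality``:

        w_i  ∝  exp(-b*age_i) * s_i / (nu_i * g_i)

    with ``g_i`` the detection-weighted realized share of potential deaths
    (fishing deaths occur only in the open fraction ``O_i``).
    """
    scale = getattr(config, "mortality_scale", 1.0)
    ages = np.arange(N_BINS) * 0.5
    s = _detrended_seasonality(config)
    q = config.cause_mix_by_age[:, CAUSE_GROUPS.index("fishing")]
    m = np.exp(-config.true_b / 2.0) * scale
    decline = np.exp(-config.true_b * ages)
    g = q * open_vec * config.detection_prob_bycatch + (1.0 - q) * config.detection_prob_other
    g = np.where(g <= 0, 1e-12, g)
    realized_share = 1.0 - q * (1.0 - open_vec)

    w = decline * s
    w = w / w.sum()
    nu = np.ones(N_BINS)
    for _ in range(n_iter):
        f = m * w
        realized = f * realized_share
        nu_new = np.concatenate([[1.0], np.cumprod(1.0 - realized)[:-1]])
        w_new = decline * s / (nu_new * g)
        w_new = w_new / w_new.sum()
        if np.allclose(w_new, w, atol=1e-13) and np.allclose(nu_new, nu, atol=1e-13):
            w, nu = w_new, nu_new
            break
        w, nu = w_new, nu_new
    f = m * w
    if (f > 1.0).any():
        raise ConfigurationError(
            "per-bin potential death fraction exceeds 1; lower true_b or flatten "
            "the seasonal weights"
        )
    return w, nu, f


def _rng(config: SimulationConfig, year: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, year, stream])


def generate_closure_schedule(config: SimulationConfig) -> ClosureSchedule:
    """Closure coverage ramp (linear between the configured endpoints)."""
    coverage = interpolated_coverage(
        config.year_list, config.coverage_start, config.coverage_end
    )
    return ClosureSchedule(
        coverage=coverage,
        season_start=config.season_start,
        season_end=config.season_end,
    )


def _pups_born(config: SimulationConfig) -> dict[int, int]:
    years = config.year_list
    if len(years) == 1:
        return {years[0]: int(round(config.pups_born_start))}
    lo, hi = years[0], years[-1]
    return {
        y: int(
            round(
                config.pups_born_start
                + (config.pups_born_end - config.pups_born_start)
                * (y - lo)
                / (hi - lo)
            )
        )
        for y in years
    }


def _bin0_draws(
    config: SimulationConfig, year: int, n_pups: int, f0: float, mix0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (per seed/year) bin-0 deaths by cause and detection flags.

    Shared by :func:`generate_pup_table` and :func:`generate_carcasses` so
    the pup table's observed age-0 deaths are exactly the bin-0 records of
    the carcass table.
    """
    rng = _rng(config, year, _STREAM_BIN0)
    total = rng.binomial(n_pups, min(f0, 1.0))
    by_cause = rng.multinomial(total, mix0)
    detect_u = rng.uniform(size=total)
    return by_cause, detect_u


def _detection_prob(config: SimulationConfig, group: str) -> float:
    return (
        config.detection_prob_bycatch
        if group == "fishing"
        else config.detection_prob_other
    )


def generate_pup_table(config: SimulationConfig) -> pd.DataFrame:
    """Annual pups born (linear trend) and observed age-0 deaths.

    Observed age-0 deaths are a binomial thinning (by the cause-specific
    detection probabilities) of the true bin-0 deaths.
    """
    schedule = generate_closure_schedule(config)
    pups = _pups_born(config)
    rows = []
    for year in config.year_list:
        open_vec = schedule.open_vector(year)
        _, _, f = solve_bin_weights(config, open_vec)
        mix0 = config.cause_mix_by_age[0]
        by_cause, detect_u = _bin0_draws(config, year, pups[year], f[0], mix0)
        observed = 0
        pos = 0
        for gi, group in enumerate(CAUSE_GROUPS):
            p = _detection_prob(config, group)
            observed += int((detect_u[pos : pos + by_cause[gi]] < p).sum())
            pos += by_cause[gi]
        rows.append(
            {"year": year, "pups_born": pups[year], "observed_age0_deaths": observed}
        )
    return pd.DataFrame(rows)


def _draw_raw_labels(rng: np.random.Generator, group: str, n: int) -> list[str]:
    labels = list(RAW_WITHIN_GROUP[group])
    probs = np.array(list(RAW_WITHIN_GROUP[group].values()))
    idx = rng.choice(len(labels), size=n, p=probs / probs.sum())
    return [labels[i] for i in idx]


def generate_carcasses(
    config: SimulationConfig,
    pups: pd.DataFrame,
    closures: ClosureSchedule,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate cohort deaths, closure suppression, and carcass detection.

    Returns the observed carcass table (juveniles indexed by birth-cohort
    year, adults by recovery year) together with the full ground truth.
    """
    pup_map = dict(zip(pups["year"].astype(int), pups["pups_born"].astype(int)))
    mix = config.cause_mix_by_age
    fishing_idx = CAUSE_GROUPS.index("fishing")

    records: list[dict] = []
    truth_rows: list[dict] = []
    weights: dict[int, np.ndarray] = {}
    fractions: dict[int, np.ndarray] = {}
    bycatch_total: dict[int, int] = {}
    survivors: dict[int, int] = {}

    for year in sorted(pup_map):
        open_vec = closures.open_vector(year)
        w, _, f = solve_bin_weights(config, open_vec)
        weights[year], fractions[year] = w, f
        rng_d = _rng(config, year, _STREAM_DEATHS)
        rng_det = _rng(config, year, _STREAM_DETECT)
        rng_attr = _rng(config, year, _STREAM_ATTRS)

        n_alive = pup_map[year]
        bin0_by_cause, bin0_detect_u = _bin0_draws(
            config, year, n_alive, f[0], mix[0]
        )
        year_bycatch = 0
        for i in range(N_BINS):
            if i == 0:
                by_cause = bin0_by_cause
                potential = int(by_cause.sum())
            else:
                potential = rng_d.binomial(n_alive, min(f[i], 1.0))
                by_cause = rng_d.multinomial(potential, mix[i])
            n_fishing = int(by_cause[fishing_idx])
            averted = (
                rng_d.binomial(n_fishing, 1.0 - open_vec[i]) if n_fishing else 0
            )
            realized_by_cause = by_cause.copy()
            realized_by_cause[fishing_idx] = n_fishing - averted
            realized = int(realized_by_cause.sum())
            n_alive = n_alive - realized
            year_bycatch += n_fishing - averted

            truth_rows.append(
                {
                    "year": year,
                    "bin": i,
                    **{g: int(realized_by_cause[j]) for j, g in enumerate(CAUSE_GROUPS)},
                    "averted": int(averted),
                }
            )

            # thin realized deaths into observed carcasses
            pos = 0
            for j, group in enumerate(CAUSE_GROUPS):
                n_g = int(realized_by_cause[j])
                if n_g == 0:
                    pos += int(by_cause[j])
                    continue
                if i == 0:
                    u = bin0_detect_u[pos : pos + n_g]
                    pos += int(by_cause[j])
                else:
                    u = rng_det.uniform(size=n_g)
                detected = u < _detection_prob(config, group)
                n_det = int(detected.sum())
                if n_det == 0:
                    continue
                ages = (i + rng_attr.uniform(size=n_det)) * 0.5
                zones = rng_attr.integers(1, config.n_zones + 1, size=n_det)
                raws = _draw_raw_labels(rng_attr, group, n_det)
                for a, z, raw in zip(ages, zones, raws):
                    records.append(
                        {
                            "year": year,
                            "stage": "juvenile",
                            "age_months": float(a),
                            "age_years": float(a) / 12.0,
                            "bin": i,
                            "cause_raw": raw,
                            "cause_group": group,
                            "zone": int(z),
                        }
                    )
        bycatch_total[year] = year_bycatch
        survivors[year] = n_alive

    # adult carcass stream: a stationary exp(-b_adult * age) age distribution
    adult_ages = np.arange(1, 31, dtype=float)
    adult_p = np.exp(-config.true_b_adult * adult_ages)
    adult_p /= adult_p.sum()
    for year in sorted(pup_map):
        rng_a = _rng(config, year, _STREAM_ADULTS)
        n_adults = rng_a.poisson(config.adult_carcasses_per_year)
        if n_adults == 0:
            continue
        age_classes = rng_a.choice(adult_ages, size=n_adults, p=adult_p)
        for a in age_classes:
            group = (
                "fishing"
                if rng_a.uniform() < config.adult_fishing_share
                else "other"
            )
            age_years = float(a) + float(rng_a.uniform(0.0, 0.999))
            records.append(
                {
                    "year": year,
                    "stage": "adult",
                    "age_months": age_years * 12.0,
                    "age_years": age_years,
                    "bin": int(a),
                    "cause_raw": _draw_raw_labels(rng_a, group, 1)[0],
                    "cause_group": group,
                    "zone": int(rng_a.integers(1, config.n_zones + 1)),
                }
            )

    carcasses = pd.DataFrame(records, columns=CARCASS_COLUMNS)
    truth = SyntheticTruth(
        deaths_by_bin=pd.DataFrame(truth_rows),
        bycatch_total=pd.Series(bycatch_total, name="true_bycatch").sort_index(),
        survivors_15m=pd.Series(survivors, name="true_survivors_15m").sort_index(),
        potential_weights=weights,
        potential_fractions=fractions,
    )
    return carcasses, truth


def generate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ClosureSchedule, SyntheticTruth]:
    """Convenience wrapper: (carcasses, pups, closures, truth) for one config."""
    pups = generate_pup_table(config)
    closures = generate_closure_schedule(config)
    carcasses, truth = generate_carcasses(config, pups, closures)
    return carcasses, pups, closures, truth
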