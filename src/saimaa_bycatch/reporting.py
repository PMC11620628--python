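"""Derived summary statistics of an annual results table.

Operates on a Table-2-shaped frame (one row per year, columns
``est_bycatch``, ``obs_bycatch``, ``est_pups_born``, ``est_all_deaths``,
``est_other_deaths``, ``est_survivors_15m``, ``est_population``,
``bycatch_rate``), whether produced by the pipeline or transcribed from a
published table. Transcriptions of the published mortality and results
tables ship with the package as reference data.

Decade windows follow the source convention: "the 1990s" is 1991-1999
(nine years, the first study decade), "the 2000s" 2000-2009, and the final
window 2010-2021.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .causes import group_cause_column

DECADES = ((1991, 1999), (2000, 2009), (2010, 2021))

#: Published count of gillnet entanglements among the 142 self-reported
#: bycatch deaths (reported alongside the mortality table, not within it).
GILLNET_OF_SELF_REPORTED_BYCATCH = 128


def _data_path(name: str):
    return resources.files("saimaa_bycatch").joinpath("data", name)


def load_cause_table() -> pd.DataFrame:
    """Transcription of the published 12-cause mortality frequency table."""
    with resources.as_file(_data_path("table1.csv")) as path:
        return pd.read_csv(path)


def load_annual_results_table() -> pd.DataFrame:
    """Transcription of the published 1991-2021 annual results table."""
    with resources.as_file(_data_path("table2.csv")) as path:
        return pd.read_csv(path)


def _require_years(table: pd.DataFrame, first: int, last: int) -> None:
    years = set(table["year"].astype(int))
    missing = sorted(set(range(first, last + 1)) - years)
    if missing:
        raise ValueError(f"annual table is missing years {missing}")


def decadal_summary(
    table: pd.DataFrame, column: str, decades=DECADES
) -> dict[tuple[int, int], float]:
    """Arithmetic means of one column over the three study decades."""
    _require_years(table, decades[0][0], decades[-1][1])
    out = {}
    for lo, hi in decades:
        mask = table["year"].astype(int).between(lo, hi)
        out[(lo, hi)] = float(table.loc[mask, column].mean())
    return out


def unobserved_ratio(table: pd.DataFrame) -> float:
    """Unobserved bycatch deaths per observed one, over the whole period.

    (mean estimated - mean observed) / mean observed.
    """
    est = float(table["est_bycatch"].mean())
    obs = float(table["obs_bycatch"].mean())
    if obs == 0:
        raise ValueError("mean observed bycatch is zero: ratio undefined")
    return (est - obs) / obs


def growth_rate(table: pd.DataFrame, start_year: int, end_year: int) -> float:
    """Geometric-mean annual population growth between two years, in percent."""
    idx = table.set_index(table["year"].astype(int))
    for y in (start_year, end_year):
        if y not in idx.index:
            raise ValueError(f"year {y} not in the annual table")
    n0 = float(idx.loc[start_year, "est_population"])
    n1 = float(idx.loc[end_year, "est_population"])
    if n0 <= 0 or n1 <= 0:
        raise ValueError("population sizes must be positive")
    if end_year == start_year:
        raise ValueError("start and end years must differ")
    return ((n1 / n0) ** (1.0 / (end_year - start_year)) - 1.0) * 100.0


def cause_fraction_report(
    cause_counts: pd.DataFrame | Mapping[str, int],
    gillnet_count: int | None = None,
) -> dict[str, float]:
    """Self-reported fishing share of all carcasses, and gillnet share of it.

    ``cause_counts`` is a raw-cause frequency table (columns ``cause_raw``
    and ``frequency``) or a mapping of raw cause to count. The gillnet
    count is reported separately from the cause table in the source record;
    it defaults to the published value when the self-reported count matches
    the published table.
    """
    if isinstance(cause_counts, Mapping):
        counts = pd.Series(cause_counts, dtype=float)
    else:
        counts = cause_counts.set_index("cause_raw")["frequency"].astype(float)
    total = float(counts.sum())
    if total == 0:
        raise ValueError("no carcasses: shares undefined")
    key = [k for k in counts.index if str(k).strip().lower() == "fishing (self-reported)"]
    self_reported = float(counts[key[0]]) if key else 0.0
    out = {"self_reported_fishing_pct": 100.0 * self_reported / total}
    if gillnet_count is None and self_reported == 142:
        gillnet_count = GILLNET_OF_SELF_REPORTED_BYCATCH
    if gillnet_count is not None:
        if self_reported == 0:
            raise ValueError("no self-reported fishing deaths: gillnet share undefined")
        out["gillnet_share_pct"] = 100.0 * float(gillnet_count) / self_reported
    return out


def grouped_frequency_table(carcasses: pd.DataFrame) -> pd.Series:
    """Four-group frequency tally recomputed from a carcass table."""
    df = group_cause_column(carcasses)
    return df["cause_group"].value_counts().sort_index()


def summary_report(
    table: pd.DataFrame,
    *,
    pbr: float | None = None,
    growth_years: tuple[int, int] = (2016, 2021),
) -> dict:
    """All derived statistics of an annual results table in one mapping."""
    report: dict = {"decade_definition": "1991-1999, 2000-2009, 2010-2021"}
    report["obs_bycatch_decadal_means"] = decadal_summary(table, "obs_bycatch")
    report["est_bycatch_decadal_means"] = decadal_summary(table, "est_bycatch")
    report["bycatch_rate_decadal_means"] = decadal_summary(table, "bycatch_rate")
    report["mean_est_bycatch"] = float(table["est_bycatch"].mean())
    report["mean_obs_bycatch"] = float(table["obs_bycatch"].mean())
    report["unobserved_to_observed_ratio"] = unobserved_ratio(table)
    report["total_est_pups_born"] = float(table["est_pups_born"].sum())
    try:
        report["growth_rate_pct"] = growth_rate(table, *growth_years)
    except ValueError:
        report["growth_rate_pct"] = float("nan")
    if pbr is not None:
        obs = pd.Series(
            table["obs_bycatch"].to_numpy(), index=table["year"].astype(int)
        )
        est = pd.Series(
            table["est_bycatch"].to_numpy(), index=table["year"].astype(int)
        )
        obs_cmp = obs > pbr
        est_cmp = est > pbr
        report["pbr"] = float(pbr)
        report["obs_exceedance_years"] = int(obs_cmp.sum())
        report["est_exceedance_years"] = int(est_cmp.sum())
        report["n_years"] = int(len(table))
        report["exceedance_ratio"] = float(np.mean(est) / pbr)
    return report
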