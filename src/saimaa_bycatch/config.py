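"""Simulation configuration for the synthetic carcass/pup/closure generator.

The configuration encodes the study conditions the generator emulates: a
pup production trend, a juvenile total-mortality level expressed as the
monthly catch-curve slope, a two-peaked seasonal bycatch hazard, an
age-structured cause-of-death mix, a spatial closure coverage ramp, and
partial carcass detection.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import yaml

from .errors import ConfigurationError

N_BINS = 30  # half-month age bins covering 0-15 months
CAUSE_GROUPS = ("stillborn", "lair_death", "fishing", "other")


def default_seasonal_weights() -> np.ndarray:
    """Two-peaked seasonal bycatch-hazard weights over the 30 half-month bins.

    The first peak sits at bins 6-8 (June-July, open-water gillnetting after
    the spring closure lapses) and the second at bins 24-26 (March, gillnets
    set under ice). Amplitudes are kept moderate so the age-frequency curve
    of recovered carcasses stays unimodal at age zero.
    """
    i = np.arange(N_BINS, dtype=float)
    return (
        0.8
        + 0.9 * np.exp(-(((i - 7.0) / 2.0) ** 2))
        + 0.55 * np.exp(-(((i - 25.0) / 2.0) ** 2))
    )


def default_cause_mix() -> np.ndarray:
    """Cause-group propensities by half-month age bin.

    Rows are bins 0..29, columns (stillborn, lair_death, fishing, other).
    Stillbirth is confined to the first bin and lair deaths to the nursing
    period (ages 0-2 months); no fishing death can occur in bin 0. From
    weaning onward the fishing share settles near the ratio seen in the
    pooled carcass record (163 fishing of 383 post-weaning deaths).
    """
    mix = np.zeros((N_BINS, 4))
    mix[0] = (0.55, 0.40, 0.00, 0.05)
    mix[1] = (0.10, 0.70, 0.04, 0.16)
    mix[2] = (0.00, 0.55, 0.10, 0.35)
    mix[3] = (0.00, 0.30, 0.20, 0.50)
    mix[4] = (0.00, 0.00, 0.35, 0.65)
    mix[5:] = (0.00, 0.00, 0.42, 0.58)
    return mix


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic study period.

    Attributes
    ----------
    years:
        Inclusive (first, last) cohort birth years.
    pups_born_start, pups_born_end:
        Endpoints of the linear pup-production trend (rounded to integers).
    true_b:
        Monthly catch-curve slope magnitude of the juvenile age-frequency
        distribution; ``exp(-true_b/2)`` is the per-cohort potential-death
        allocation factor of the population model.
    seasonal_bycatch_weights:
        Non-negative weights over the 30 half-month bins modulating the
        within-year timing of deaths (log-detrended against age before use).
    cause_mix_by_age:
        (30, 4) row-stochastic matrix of cause-group propensities.
    coverage_start, coverage_end:
        Fraction of the juvenile distribution inside gillnet restriction
        areas in the first and last year (linearly interpolated between).
    detection_prob_bycatch, detection_prob_other:
        Probability that a fishing / non-fishing death is recovered as a
        carcass. The default 1/3 yields roughly two unobserved bycatch
        deaths per observed one.
    n_zones:
        Number of water zones carcasses are attributed to (uniformly).
    true_b_adult:
        Annual catch-curve slope of the adult (1-30 y) age frequencies.
    adult_carcasses_per_year:
        Expected number of adult carcasses recovered per year.
    adult_fishing_share:
        Fishing propensity among adult deaths.
    seed:
        Master seed; all generator randomness derives from it.
    """

    years: tuple[int, int] = (1991, 2021)
    pups_born_start: int = 31
    pups_born_end: int = 90
    true_b: float = 0.25
    seasonal_bycatch_weights: np.ndarray = dataclasses.field(
        default_factory=default_seasonal_weights
    )
    cause_mix_by_age: np.ndarray = dataclasses.field(default_factory=default_cause_mix)
    coverage_start: float = 0.08
    coverage_end: float = 0.95
    detection_prob_bycatch: float = 1.0 / 3.0
    detection_prob_other: float = 1.0 / 3.0
    n_zones: int = 5
    true_b_adult: float = 0.095
    adult_carcasses_per_year: float = 5.4
    adult_fishing_share: float = 0.3
    season_start: tuple[int, int] = (4, 15)
    season_end: tuple[int, int] = (6, 30)
    mortality_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.seasonal_bycatch_weights = np.asarray(
            self.seasonal_bycatch_weights, dtype=float
        )
        self.cause_mix_by_age = np.asarray(self.cause_mix_by_age, dtype=float)
        self.validate()

    def validate(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError(f"empty year range {self.years}")
        if self.pups_born_start < 0 or self.pups_born_end < 0:
            raise ConfigurationError("pup trend endpoints must be non-negative")
        if self.true_b <= 0 or self.true_b_adult <= 0:
            raise ConfigurationError("catch-curve slopes must be positive")
        w = self.seasonal_bycatch_weights
        if w.shape != (N_BINS,) or (w < 0).any() or not w.any():
            raise ConfigurationError(
                "seasonal_bycatch_weights must be 30 non-negative values, not all zero"
            )
        mix = self.cause_mix_by_age
        if mix.shape != (N_BINS, len(CAUSE_GROUPS)):
            raise ConfigurationError("cause_mix_by_age must have shape (30, 4)")
        if (mix < 0).any() or (mix > 1).any():
            raise ConfigurationError("cause_mix_by_age entries must lie in [0, 1]")
        if not np.allclose(mix.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("cause_mix_by_age rows must sum to 1")
        for name in (
            "coverage_start",
            "coverage_end",
            "detection_prob_bycatch",
            "detection_prob_other",
            "adult_fishing_share",
            "mortality_scale",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_zones < 1:
            raise ConfigurationError("n_zones must be >= 1")
        if self.adult_carcasses_per_year < 0:
            raise ConfigurationError("adult_carcasses_per_year must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a configuration from a YAML or JSON file.

        Only keys present in the file override the defaults; list-valued
        fields are converted to arrays/tuples as needed.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path} does not contain a mapping")
        kwargs = {}
        field_names = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in field_names:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            if key in ("years", "season_start", "season_end"):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)
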