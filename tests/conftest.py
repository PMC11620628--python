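"""Shared fixtures: scaled-down synthetic datasets and one large pipeline run."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import saimaa_bycatch as sb

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_RF_GRID = {
    "trees": [50],
    "depth": [None],
    "criterion": ["gini"],
    "pruning_confidence": [0.0],
}


@pytest.fixture(scope="session")
def small_config() -> sb.SimulationConfig:
    """A short, moderately sized study period for fast unit tests."""
    return sb.SimulationConfig(
        years=(1991, 2000),
        pups_born_start=300,
        pups_born_end=600,
        adult_carcasses_per_year=20,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    carcasses, pups, closures, truth = sb.generate_dataset(small_config)
    return {
        "config": small_config,
        "carcasses": carcasses,
        "pups": pups,
        "closures": closures,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def large_run():
    """Full-pipeline run on a large synthetic study (shared by recovery tests).

    Cohort sizes are scaled up two-hundred-fold from the realistic trend to
    suppress sampling noise; the structural study conditions (slope,
    seasonality, cause mix, coverage ramp, detection) are the defaults.
    """
    config = sb.SimulationConfig(
        seed=11,
        pups_born_start=31 * 200,
        pups_born_end=90 * 200,
        adult_carcasses_per_year=1080,
    )
    carcasses, pups, closures, truth = sb.generate_dataset(config)
    result = sb.reconstruct(
        carcasses,
        pups,
        closures,
        seed=11,
        rf_grid={
            "trees": [100],
            "depth": [None],
            "criterion": ["gini"],
            "pruning_confidence": [0.0],
        },
    )
    return {
        "config": config,
        "carcasses": carcasses,
        "pups": pups,
        "closures": closures,
        "truth": truth,
        "result": result,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
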