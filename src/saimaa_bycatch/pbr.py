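"""Potential biological removal (PBR) reference point and exceedance checks.

PBR = Nmin * (Rmax/2) * Fr, where Nmin is the 20th percentile of a
log-normal abundance distribution (the lower bound of a 60% two-tailed
CI), Rmax the maximum net productivity rate, and Fr a recovery factor in
(0, 1]. The defaults Rmax = 0.12 and Fr = 0.1 are the standard values for
endangered pinniped stocks.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

#: standard-normal 80th percentile used for the lower 60% two-tailed bound
DEFAULT_Z = 0.842
DEFAULT_RMAX = 0.12
DEFAULT_FR = 0.1


@dataclasses.dataclass
class PBRInputs:
    """Inputs to the PBR computation.

    Supply either ``n_min`` directly or a best abundance estimate
    ``n_best`` with its CV, from which Nmin is derived.
    """

    n_best: float | None = None
    cv: float | None = None
    n_min_value: float | None = None
    r_max: float = DEFAULT_RMAX
    f_r: float = DEFAULT_FR
    z_percentile: float = DEFAULT_Z


@dataclasses.dataclass
class PBRResult:
    n_min: float
    r_max: float
    f_r: float
    pbr: float


def n_min(n_best: float, cv: float, z: float = DEFAULT_Z) -> float:
    """Lower 60% two-tailed CI bound of a log-normal abundance estimate.

    Nmin = N / exp(z * sqrt(ln(1 + CV^2))); with CV = 0 this is N itself.
    """
    if n_best <= 0:
        raise ValueError("n_best must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    return float(n_best / math.exp(z * math.sqrt(math.log(1.0 + cv**2))))


def compute_pbr(inputs: PBRInputs | None = None, **kwargs) -> PBRResult:
    """PBR = Nmin * (Rmax / 2) * Fr.

    Keyword arguments (``n_min_value`` or ``n_best``+``cv``, plus ``r_max``
    and ``f_r``) may be given instead of a :class:`PBRInputs`.
    """
    if inputs is None:
        inputs = PBRInputs(**kwargs)
    if not 0.0 < inputs.f_r <= 1.0:
        raise ValueError(
            f"recovery factor f_r={inputs.f_r} outside (0, 1]; Fr lies between 0.1 and 1"
        )
    if inputs.r_max <= 0:
        raise ValueError("r_max must be positive")
    if inputs.n_min_value is not None:
        nmin = float(inputs.n_min_value)
        if nmin <= 0:
            raise ValueError("n_min must be positive")
    else:
        if inputs.n_best is None or inputs.cv is None:
            raise ValueError("supply n_min_value, or n_best together with cv")
        nmin = n_min(inputs.n_best, inputs.cv, inputs.z_percentile)
    return PBRResult(
        n_min=nmin,
        r_max=inputs.r_max,
        f_r=inputs.f_r,
        pbr=nmin * (inputs.r_max / 2.0) * inputs.f_r,
    )


def compare_removals(removals: pd.Series, pbr: float) -> pd.DataFrame:
    """Flag, per year, whether removals exceed the PBR; attach the counts.

    Returns a frame with columns ``removals`` and ``exceeds`` plus attrs
    ``n_exceed`` and ``n_years``.
    """
    removals = pd.Series(removals).astype(float)
    if removals.empty:
        raise ValueError("removals series is empty")
    exceeds = removals > pbr
    out = pd.DataFrame({"removals": removals, "exceeds": exceeds})
    out.attrs["n_exceed"] = int(exceeds.sum())
    out.attrs["n_years"] = int(len(removals))
    out.attrs["pbr"] = float(pbr)
    return out


def exceedance_ratio(removals: pd.Series, pbr: float) -> float:
    """Mean removals divided by the PBR (how many times over the limit)."""
    return float(np.mean(pd.Series(removals).astype(float)) / pbr)
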