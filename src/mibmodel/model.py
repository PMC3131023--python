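"""Delayed-logistic model of succession indexed by Mean Individual Biomass.

The state of succession N (mg MIB) follows logistic growth

    dN/dt = r * N * (K - N) / K

from an initial degradation level ``N0`` toward a recovery level ``K``,
after an initial delay of ``t_delay`` years during which N stays at N0.
With t = t_start - t_delay the closed-form solution is

    N(t) = c * exp(r t) / (1 + c * exp(r t) / K),   c = N0 / (1 - N0 / K)

valid for t >= 0; for t < 0 the state remains at N0.  Internally the
algebraically equivalent, overflow-safe form

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t))

is evaluated, so the model stays finite for arbitrarily large r*t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "SuccessionParams",
    "ModelCurve",
    "logistic_c",
    "evaluate",
    "ode_rhs",
    "classify_phase",
    "curve",
    "load_presets",
    "preset_params",
    "preset_unverified",
    "PHASE_DELAY",
    "PHASE_INCREASE",
    "PHASE_STAGNATION",
    "DEFAULT_STAGNATION_THETA",
]

PHASE_DELAY = "delay"
PHASE_INCREASE = "increase"
PHASE_STAGNATION = "stagnation"

#: N(t) >= theta * K counts as the stagnation phase (the phase names are
#: qualitative; this boundary is a convention of this package).
DEFAULT_STAGNATION_THETA = 0.95


@dataclass(frozen=True)
class SuccessionParams:
    """The four parameters of the delayed-logistic succession model.

    Parameters
    ----------
    n0 : float
        Initial degradation level, mg MIB; 0 < n0 < k.
    t_delay : float
        Delay before the logistic increase starts, years; >= 0.
    r : float
        Increase rate, 1/years; >= 0.
    k : float
        Recovery level (asymptote), mg MIB; > n0.
    """

    n0: float
    t_delay: float
    r: float
    k: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.n0, self.t_delay, self.r, self.k]).all():
            raise ValueError("all parameters must be finite")
        if self.n0 <= 0:
            raise ValueError(f"initial level n0 must be > 0, got {self.n0}")
        if self.k <= self.n0:
            raise ValueError(
                f"recovery level k must exceed n0 (k={self.k}, n0={self.n0})"
            )
        if self.t_delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.t_delay}")
        if self.r < 0:
            raise ValueError(f"increase rate must be >= 0, got {self.r}")


@dataclass(frozen=True)
class ModelCurve:
    """Model trajectory N(t_start) on a grid of stand ages."""

    params: SuccessionParams
    ages: np.ndarray
    values: np.ndarray
    phases: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.ages)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age_years": self.ages,
                "mib_model_mg": self.values,
                "phase": list(self.phases) if self.phases else "",
            }
        )


def logistic_c(n0: float, k: float) -> float:
    """Integration constant c = N0 / (1 - N0/K) of the logistic solution.

    Requires 0 < n0 < k; c > n0 always holds in that domain.
    """
    if n0 <= 0:
        raise ValueError(f"n0 must be > 0, got {n0}")
    if n0 >= k:
        raise ValueError(f"c is undefined for n0 >= k (n0={n0}, k={k})")
    return n0 / (1.0 - n0 / k)


def evaluate(params: SuccessionParams, t_start):
    """Model state N (mg MIB) at stand age ``t_start`` (years).

    Accepts a scalar or array of ages; ages must be >= 0.  Inside the
    delay phase (t_start < t_delay) the value is exactly ``n0``;
    afterwards the closed-form logistic solution applies, evaluated in
    the overflow-safe decaying-exponential form.
    """
    t_start_arr = np.asarray(t_start, dtype=float)
    if np.any(t_start_arr < 0):
        raise ValueError("stand age t_start must be >= 0")
    t = t_start_arr - params.t_delay
    ratio = (params.k - params.n0) / params.n0
    with np.errstate(over="ignore"):
        logistic = params.k / (1.0 + ratio * np.exp(-params.r * np.maximum(t, 0.0)))
    # t == 0 is returned as exactly n0 (the branches agree algebraically)
    out = np.where(t <= 0, params.n0, logistic)
    if np.isscalar(t_start) or t_start_arr.ndim == 0:
        return float(out)
    return out


def ode_rhs(params: SuccessionParams, n: float) -> float:
    """Right-hand side of the logistic ODE, dN/dt = r N (K - N) / K."""
    return params.r * n * (params.k - n) / params.k


def classify_phase(
    params: SuccessionParams,
    t_start: float,
    theta: float = DEFAULT_STAGNATION_THETA,
) -> str:
    """Succession phase at stand age ``t_start``.

    ``delay`` while t_start < t_delay, ``stagnation`` once
    N(t_start) >= theta * K, ``increase`` in between.
    """
    if t_start < params.t_delay:
        return PHASE_DELAY
    if evaluate(params, t_start) >= theta * params.k:
        return PHASE_STAGNATION
    return PHASE_INCREASE


def curve(
    params: SuccessionParams,
    ages: Iterable[float],
    theta: float = DEFAULT_STAGNATION_THETA,
) -> ModelCurve:
    """Vectorized model trajectory with phase labels over an age grid."""
    ages_arr = np.asarray(list(ages) if not isinstance(ages, np.ndarray) else ages,
                          dtype=float)
    if ages_arr.size == 0:
        return ModelCurve(params, ages_arr, np.empty(0), ())
    values = evaluate(params, ages_arr)
    phases = tuple(classify_phase(params, a, theta=theta) for a in ages_arr)
    return ModelCurve(params, ages_arr, np.atleast_1d(values), phases)


# ---------------------------------------------------------------------------
# Shipped parameter presets for the five degraded-area types
# ---------------------------------------------------------------------------

def load_presets() -> dict:
    """Raw preset config: per area type the four parameter values plus the
    list of parameters that could not be verified from field data."""
    text = resources.files("mibmodel.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_params(area_type: str) -> SuccessionParams:
    """SuccessionParams for one of the five shipped area-type presets."""
    presets = load_presets()
    try:
        p = presets[area_type]
    except KeyError:
        raise KeyError(
            f"unknown preset {area_type!r}; available: {sorted(presets)}"
        ) from None
    return SuccessionParams(
        n0=p["initial_level_mg"],
        t_delay=p["delay_years"],
        r=p["increase_rate_per_year"],
        k=p["recovery_level_mg"],
    )


def preset_unverified(area_type: str) -> frozenset[str]:
    """Parameters of a preset that are marked as unverifiable by data."""
    return frozenset(load_presets()[area_type].get("unverified", []))
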