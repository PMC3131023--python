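import numpy as np
import pandas as pd
import pytest

from mibmodel import SuccessionParams, evaluate, preset_params
from mibmodel.mib import MibPoint, MibSeries

AREA_TYPES = (
    "forest_soil_planted",
    "post_agri_natural",
    "post_agri_planted",
    "ash_heap",
    "mining_heap",
)


@pytest.fixture(params=AREA_TYPES)
def area_type(request):
    return request.param


@pytest.fixture
def preset(area_type):
    return preset_params(area_type)


def series_from_model(params: SuccessionParams, ages, area_type="synthetic",
                      n_individuals=100) -> MibSeries:
    """Noiseless MibSeries sampled exactly from the model trajectory."""
    points = tuple(
        MibPoint("model", float(a), float(evaluate(params, a)),
                 n_individuals, n_individuals >= 25)
        for a in ages
    )
    return MibSeries(area_type=area_type, points=points)


def catch_frame(rows):
    """Catch table from (site, area, age, year, species, count) tuples."""
    return pd.DataFrame(
        rows,
        columns=["site_id", "area_type", "stand_age", "sampling_year",
                 "species", "count"],
    )


def rk4_logistic(params: SuccessionParams, t_end: float, h: float = 0.02):
    """Independent RK4 integration of dN/dt = r N (K-N)/K from N(0)=n0.

    Returns (t_grid, N) on the shifted time axis t = t_start - t_delay.
    """
    r, k = params.r, params.k
    f = lambda n: r * n * (k - n) / k
    n_steps = int(round(t_end / h))
    ts = np.linspace(0.0, n_steps * h, n_steps + 1)
    out = np.empty(n_steps + 1)
    out[0] = params.n0
    n = params.n0
    for i in range(n_steps):
        k1 = f(n)
        k2 = f(n + 0.5 * h * k1)
        k3 = f(n + 0.5 * h * k2)
        k4 = f(n + h * k3)
        n = n + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        out[i + 1] = n
    return ts, out
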