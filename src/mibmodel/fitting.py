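"""Least-squares estimation of the delayed-logistic succession parameters.

The model is non-smooth in the delay, so the delay is profiled on a grid:
for each candidate delay the remaining free parameters are estimated by
bounded nonlinear least squares, the candidate with minimal residual sum
of squares wins, and the winning delay is then polished continuously
within one grid step.  The recovery level is parameterized as
``k = n0 + dk`` with dk > 0, which keeps n0 < k throughout.

Identifiability mirrors the limits of chronosequence data: a series with
no young stands cannot pin down the initial level or the delay, and a
series that never approaches the asymptote cannot pin down the recovery
level; such parameters are flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .model import SuccessionParams, curve, evaluate

__all__ = ["FitOptions", "FitResult", "fit_succession", "predict"]

_DK_MIN = 1e-6


@dataclass(frozen=True)
class FitOptions:
    """Settings for fit_succession.

    fix_n0 / fix_delay pin parameters that the data cannot identify
    (e.g. an initial level of 40 mg when no very young stands exist).
    Unreliable points (catch < 25 individuals) can be excluded or
    down-weighted proportionally to their catch size.
    """

    fix_n0: Optional[float] = None
    fix_delay: Optional[float] = None
    fix_r: Optional[float] = None
    fix_k: Optional[float] = None
    delay_grid: tuple[float, ...] = tuple(np.arange(0.0, 30.0 + 1e-9, 0.5))
    exclude_unreliable: bool = False
    weight_by_n: bool = False
    r_bounds: tuple[float, float] = (1e-6, 5.0)
    k_max: float = 5000.0
    refine_delay: bool = True

    def __post_init__(self) -> None:
        if len(self.delay_grid) == 0:
            raise ValueError("delay_grid must be non-empty")
        if any(d < 0 for d in self.delay_grid):
            raise ValueError("delays must be >= 0")
        if self.r_bounds[0] >= self.r_bounds[1] or self.r_bounds[0] < 0:
            raise ValueError("inconsistent r bounds")


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with residual diagnostics."""

    params: SuccessionParams
    rss: float
    n_used: int
    flags: tuple[str, ...]
    options: FitOptions
    age_range: tuple[float, float]

    def report(self) -> str:
        p = self.params
        lines = [
            "delayed-logistic succession fit",
            f"  n points used : {self.n_used} (ages {self.age_range[0]:g}-{self.age_range[1]:g} y)",
            f"  initial level : {p.n0:.4g} mg"
            + ("  [fixed]" if self.options.fix_n0 is not None else ""),
            f"  delay         : {p.t_delay:.4g} y"
            + ("  [fixed]" if self.options.fix_delay is not None else ""),
            f"  increase rate : {p.r:.4g} 1/y",
            f"  recovery level: {p.k:.4g} mg",
            f"  rss           : {self.rss:.6g} mg^2",
        ]
        if self.flags:
            lines.append(f"  flags         : {', '.join(self.flags)}")
        return "\n".join(lines)


def _extract_data(series, options: FitOptions):
    points = [p for p in series.points if p.mib is not None]
    if options.exclude_unreliable:
        points = [p for p in points if p.reliable]
    ages = np.array([p.stand_age for p in points], dtype=float)
    mib = np.array([p.mib for p in points], dtype=float)
    if options.weight_by_n:
        n_ind = np.array([p.n_individuals for p in points], dtype=float)
        w = np.sqrt(n_ind / n_ind.mean())
    else:
        w = np.ones_like(mib)
    return ages, mib, w


def _profile_fit(delay, ages, mib, w, options: FitOptions):
    """Best (params, rss) for a fixed delay; inner bounded least squares."""
    mib_max = float(mib.max())
    n0_start = max(float(mib.min()), 1e-3)
    dk_start = max(mib_max - n0_start, 1.0)
    r_start = 0.2

    free: list[str] = []
    x0, lo, hi = [], [], []
    if options.fix_n0 is None:
        free.append("n0")
        x0.append(n0_start)
        lo.append(1e-3)
        hi.append(2.0 * mib_max)
    if options.fix_k is None:
        free.append("dk")
        x0.append(dk_start)
        lo.append(_DK_MIN)
        hi.append(options.k_max)
    if options.fix_r is None:
        free.append("r")
        x0.append(float(np.clip(r_start, *options.r_bounds)))
        lo.append(options.r_bounds[0])
        hi.append(options.r_bounds[1])

    def unpack(x):
        vals = dict(zip(free, x))
        n0 = options.fix_n0 if options.fix_n0 is not None else vals["n0"]
        k = options.fix_k if options.fix_k is not None else n0 + vals["dk"]
        r = options.fix_r if options.fix_r is not None else vals["r"]
        return SuccessionParams(n0=n0, t_delay=delay, r=r, k=k)

    def residuals(x):
        return w * (evaluate(unpack(x), ages) - mib)

    if free:
        sol = least_squares(residuals, x0=x0, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        x_best = sol.x
    else:
        x_best = np.empty(0)
    params = unpack(x_best)
    rss = float(np.sum(residuals(x_best) ** 2))
    return params, rss


def fit_succession(series, options: FitOptions | None = None) -> FitResult:
    """Estimate SuccessionParams from a chronosequence of MIB values.

    Raises on series too short for the number of free parameters or with
    a constant MIB (no information about the trajectory).
    """
    options = options or FitOptions()
    ages, mib, w = _extract_data(series, options)
    n_free = sum(v is None for v in (options.fix_n0, options.fix_delay,
                                     options.fix_r, options.fix_k))
    if n_free and len(ages) < n_free + 1:
        raise ValueError(
            f"{n_free} free parameters need at least {n_free + 1} points, "
            f"got {len(ages)}"
        )
    if np.ptp(mib) == 0:
        raise ValueError("constant MIB series carries no information about "
                         "the succession trajectory")

    delays = ([float(options.fix_delay)] if options.fix_delay is not None
              else list(options.delay_grid))
    results = [(_profile_fit(d, ages, mib, w, options), d) for d in delays]
    (best_params, best_rss), best_delay = min(results, key=lambda t: t[0][1])

    if options.fix_delay is None and options.refine_delay and len(delays) > 1:
        step = max(np.diff(sorted(delays)).min(), 1e-3)
        lo = max(best_delay - step, min(delays))
        hi = min(best_delay + step, max(delays))
        if hi > lo:
            res = minimize_scalar(
                lambda d: _profile_fit(d, ages, mib, w, options)[1],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            params_ref, rss_ref = _profile_fit(float(res.x), ages, mib, w, options)
            if rss_ref < best_rss:
                best_params, best_rss = params_ref, rss_ref

    flags = []
    if not np.any(ages < best_params.t_delay + 2.0):
        if options.fix_n0 is None:
            flags.append("n0_unidentified")
        if options.fix_delay is None:
            flags.append("t_delay_unidentified")
    model_at_obs = np.atleast_1d(evaluate(best_params, ages))
    if not np.any(model_at_obs >= 0.8 * best_params.k):
        flags.append("k_unidentified")

    return FitResult(
        params=best_params,
        rss=best_rss,
        n_used=len(ages),
        flags=tuple(flags),
        options=options,
        age_range=(float(ages.min()), float(ages.max())),
    )


def predict(fit: FitResult, ages: Sequence[float]) -> pd.DataFrame:
    """Model curve at the fitted parameters with phase and extrapolation flags.

    Ages beyond the fitted data's oldest stand are marked ``extrapolated``.
    """
    c = curve(fit.params, ages)
    frame = c.to_frame()
    frame["extrapolated"] = frame["age_years"] > fit.age_range[1]
    return frame
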