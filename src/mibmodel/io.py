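"""CSV readers and writers for the tabular interchange formats.

All tables are plain UTF-8 CSV with "." as the decimal separator:

* catch table:  site_id,area_type,stand_age,sampling_year,species,count
* mass table:   species,mass_mg
* MIB series:   site_id,stand_age,mib_mg,n_individuals,reliable
* model curve:  age_years,mib_model_mg,phase
* fit params:   area_type,N0,delay,r,K,rss,n_used,flags
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fitting import FitResult
from .mib import CATCH_COLUMNS, MibSeries, validate_catch_table

__all__ = [
    "read_catch_table",
    "write_catch_table",
    "read_mass_table",
    "write_mass_table",
    "read_mib_series",
    "write_mib_series",
    "write_fit_result",
    "read_fit_params",
]


def read_catch_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    validate_catch_table(frame)
    return frame


def write_catch_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=list(CATCH_COLUMNS))


def read_mass_table(path) -> dict[str, float]:
    frame = pd.read_csv(path)
    missing = {"species", "mass_mg"} - set(frame.columns)
    if missing:
        raise ValueError(f"mass table missing columns: {sorted(missing)}")
    if (frame["mass_mg"] <= 0).any():
        raise ValueError("all species masses must be > 0")
    if frame["species"].duplicated().any():
        dups = frame["species"][frame["species"].duplicated()].tolist()
        raise ValueError(f"duplicate species in mass table: {dups}")
    return dict(zip(frame["species"].astype(str), frame["mass_mg"].astype(float)))


def write_mass_table(masses: dict[str, float], path) -> None:
    pd.DataFrame(
        {"species": list(masses), "mass_mg": list(masses.values())}
    ).to_csv(path, index=False)


def write_mib_series(series: MibSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_mib_series(path, area_type: str = "") -> MibSeries:
    frame = pd.read_csv(path)
    return MibSeries.from_frame(frame, area_type=area_type or str(Path(path).stem))


def write_fit_result(fit: FitResult, area_type: str, path) -> None:
    p = fit.params
    pd.DataFrame(
        [{
            "area_type": area_type,
            "N0": p.n0,
            "delay": p.t_delay,
            "r": p.r,
            "K": p.k,
            "rss": fit.rss,
            "n_used": fit.n_used,
            "flags": ";".join(fit.flags),
        }]
    ).to_csv(path, index=False, float_format="%.10g")


def read_fit_params(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    needed = {"area_type", "N0", "delay", "r", "K"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"fit params file missing columns: {sorted(missing)}")
    return frame
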