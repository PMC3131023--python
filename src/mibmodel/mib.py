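"""Mean Individual Biomass (MIB) of carabid catches and its age trend.

MIB is the total biomass of all carabids in a sample divided by the number
of individuals caught.  Because large-bodied species become dominant in
advanced successional stages, MIB rises with stand age; a pooled site-year
sample of fewer than 25 individuals is kept but flagged as unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATCH_COLUMNS",
    "RELIABILITY_THRESHOLD",
    "MibPoint",
    "MibSeries",
    "validate_catch_table",
    "compute_mib",
    "build_series",
    "spearman_mib_age",
]

CATCH_COLUMNS = ("site_id", "area_type", "stand_age", "sampling_year",
                 "species", "count")

#: minimum pooled catch for a MIB value to count as reliable
RELIABILITY_THRESHOLD = 25

#: permutation-exact Spearman p for samples up to this size
EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class MibPoint:
    """MIB of one pooled site-year sample, placed at a stand age."""

    site_id: str
    stand_age: float
    mib: Optional[float]  # mg; None when the sample is empty
    n_individuals: int
    reliable: bool

    def __post_init__(self) -> None:
        if self.stand_age < 0:
            raise ValueError("stand_age must be >= 0")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if (self.mib is None) != (self.n_individuals == 0):
            raise ValueError("mib must be absent exactly when the sample is empty")


@dataclass(frozen=True)
class MibSeries:
    """Chronosequence of MibPoints for one area type, ordered by age."""

    area_type: str
    points: tuple[MibPoint, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a MibSeries needs at least one point")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [p.site_id for p in self.points],
                "stand_age": [p.stand_age for p in self.points],
                "mib_mg": [p.mib for p in self.points],
                "n_individuals": [p.n_individuals for p in self.points],
                "reliable": [p.reliable for p in self.points],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, area_type: str) -> "MibSeries":
        points = tuple(
            MibPoint(
                site_id=str(row.site_id),
                stand_age=float(row.stand_age),
                mib=None if pd.isna(row.mib_mg) else float(row.mib_mg),
                n_individuals=int(row.n_individuals),
                reliable=bool(row.reliable),
            )
            for row in frame.itertuples()
        )
        return cls(area_type=area_type,
                   points=tuple(sorted(points, key=lambda p: p.stand_age)))


def validate_catch_table(catches: pd.DataFrame) -> None:
    """Check column presence and the record-level invariants of a catch table."""
    missing = [c for c in CATCH_COLUMNS if c not in catches.columns]
    if missing:
        raise ValueError(f"catch table missing columns: {missing}")
    if len(catches) == 0:
        raise ValueError("catch table is empty")
    if (catches["count"] < 0).any():
        bad = catches.index[catches["count"] < 0].tolist()
        raise ValueError(f"negative counts at rows {bad}")
    if (catches["stand_age"] < 0).any():
        raise ValueError("stand_age must be >= 0")
    if catches["species"].isna().any() or (catches["species"].astype(str) == "").any():
        raise ValueError("species identifiers must be non-empty")


def compute_mib(
    catches: pd.DataFrame,
    masses: Mapping[str, float],
    *,
    threshold: int = RELIABILITY_THRESHOLD,
) -> MibPoint:
    """MIB of one pooled site-year sample.

    Parameters
    ----------
    catches : DataFrame
        Catch records for a single site and sampling year.
    masses : mapping
        Species -> mean individual body mass in mg.

    Returns a MibPoint with ``mib = sum(count_s * mass_s) / sum(count_s)``;
    an empty sample yields ``mib=None`` (MIB is undefined, not zero) and a
    catch below ``threshold`` individuals is flagged unreliable.
    """
    validate_catch_table(catches)
    sites = catches["site_id"].unique()
    years = catches["sampling_year"].unique()
    if len(sites) != 1 or len(years) != 1:
        raise ValueError(
            "compute_mib expects records of a single site-year "
            f"(got sites={sites.tolist()}, years={years.tolist()})"
        )
    unknown = sorted(set(catches["species"]) - set(masses))
    if unknown:
        raise KeyError(f"species missing from mass table: {unknown}")
    counts = catches["count"].to_numpy(dtype=float)
    mass = catches["species"].map(masses).to_numpy(dtype=float)
    if (mass <= 0).any():
        raise ValueError("species masses must be > 0")
    n = int(counts.sum())
    stand_age = float(catches["stand_age"].iloc[0])
    if n == 0:
        return MibPoint(str(sites[0]), stand_age, None, 0, False)
    mib = float((counts * mass).sum() / n)
    return MibPoint(str(sites[0]), stand_age, mib, n, n >= threshold)


def build_series(
    catches: pd.DataFrame,
    masses: Mapping[str, float],
    area_type: str,
    *,
    threshold: int = RELIABILITY_THRESHOLD,
) -> MibSeries:
    """Pool catches into one MibPoint per (site, sampling year).

    Each site contributes one point per sampling year; the age attributed
    to a point is the site's base stand age plus the offset of the
    sampling year from that site's first sampling year, so three
    consecutive sampling years yield three points of consecutive age.
    Points are returned sorted by stand age.
    """
    validate_catch_table(catches)
    subset = catches[catches["area_type"] == area_type]
    if len(subset) == 0:
        raise ValueError(f"no records with area_type {area_type!r}")
    points = []
    for site_id, site_rows in subset.groupby("site_id", sort=False):
        base_ages = site_rows["stand_age"].unique()
        if len(base_ages) != 1:
            raise ValueError(
                f"site {site_id!r} has inconsistent base stand ages: {base_ages}"
            )
        first_year = int(site_rows["sampling_year"].min())
        for year, year_rows in site_rows.groupby("sampling_year", sort=True):
            point = compute_mib(year_rows, masses, threshold=threshold)
            age = float(base_ages[0]) + (int(year) - first_year)
            points.append(
                MibPoint(point.site_id, age, point.mib,
                         point.n_individuals, point.reliable)
            )
    points.sort(key=lambda p: p.stand_age)
    return MibSeries(area_type=area_type, points=tuple(points))


def _spearman_rho(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Pearson correlation of two rank vectors (handles tied average ranks)."""
    dx = rank_x - rank_x.mean()
    dy = rank_y - rank_y.mean()
    denom = math.sqrt(float((dx * dx).sum()) * float((dy * dy).sum()))
    return float((dx * dy).sum()) / denom


def spearman_mib_age(
    series: MibSeries,
    include_unreliable: bool = True,
) -> tuple[float, float, int]:
    """Spearman rank correlation between MIB and stand age.

    Ties receive average ranks.  The two-sided p-value is exact (full
    enumeration of rank permutations) for n <= 8 and uses the standard
    t-distribution approximation for larger samples.

    Returns ``(rho, p_value, n)``.
    """
    points = [p for p in series.points if p.mib is not None
              and (include_unreliable or p.reliable)]
    n = len(points)
    if n < 3:
        raise ValueError(f"need at least 3 points with MIB values, got {n}")
    ages = np.array([p.stand_age for p in points], dtype=float)
    mibs = np.array([p.mib for p in points], dtype=float)
    if np.ptp(ages) == 0 or np.ptp(mibs) == 0:
        raise ValueError("zero variance in age or MIB; correlation undefined")
    rank_a = stats.rankdata(ages)
    rank_m = stats.rankdata(mibs)
    rho = _spearman_rho(rank_a, rank_m)
    if n <= EXACT_SPEARMAN_MAX_N:
        hits = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(rank_m):
            total += 1
            if abs(_spearman_rho(rank_a, np.asarray(perm))) >= target:
                hits += 1
        p = hits / total
    else:
        p = float(stats.spearmanr(ages, mibs).pvalue)
    return rho, p, n
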