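"""Synthetic carabid communities whose expected MIB follows the model.

The mechanism behind a rising MIB is a dominance shift from small-bodied
early-successional species toward large-bodied late-successional ones.
The simulator realizes this minimally with two guilds: at stand age t the
fraction w of individuals drawn from the large guild solves

    w * m_L + (1 - w) * m_S = N(t)

where m_S, m_L are the guild mean masses and N(t) the model trajectory,
so the expected MIB of a catch equals the model value whenever species
masses are symmetric about their guild mean (the default pool spaces
species evenly within +/-20% of the guild mean, which guarantees this).

Catch sizes per site-year are Poisson by default; a negative-binomial
overdispersion parameter is available because real pitfall catches are
typically overdispersed.  Each site-year draws from its own deterministic
random stream derived from the master seed, so enlarging a design never
changes existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SuccessionParams, evaluate, preset_params

__all__ = [
    "SpeciesPool",
    "SimDesign",
    "default_pool",
    "solve_guild_weight",
    "simulate_chronosequence",
    "study_design_presets",
]

GUILD_SMALL = "small_early"
GUILD_LARGE = "large_late"


@dataclass(frozen=True)
class SpeciesPool:
    """Species with body masses (mg) split into small-early and large-late guilds."""

    species: tuple[str, ...]
    mass_mg: tuple[float, ...]
    guild: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.species) == len(self.mass_mg) == len(self.guild)):
            raise ValueError("species, mass_mg and guild must align")
        if any(m <= 0 for m in self.mass_mg):
            raise ValueError("all masses must be > 0")
        guilds = set(self.guild)
        if not {GUILD_SMALL, GUILD_LARGE} <= guilds:
            raise ValueError("pool needs both guilds populated")

    def guild_indices(self, guild: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.guild) if g == guild])

    def guild_mean_mass(self, guild: str) -> float:
        idx = self.guild_indices(guild)
        return float(np.mean(np.asarray(self.mass_mg)[idx]))

    def mass_table(self) -> dict[str, float]:
        """Species -> mass mapping in the MassTable format used by mib."""
        return dict(zip(self.species, self.mass_mg))

    def mass_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "mass_mg": self.mass_mg})


def default_pool(
    n_per_guild: int = 8,
    mean_small: float = 40.0,
    mean_large: float = 450.0,
    spread: float = 0.2,
) -> SpeciesPool:
    """Pool with species spaced evenly within +/-spread of each guild mean.

    The default guild means (40 and 450 mg) bracket all shipped recovery
    levels (210-290 mg) so the guild-weight equation is always solvable.
    Even spacing makes within-guild masses symmetric about the mean, which
    keeps the simulated MIB unbiased for the model trajectory.
    """
    if n_per_guild < 1:
        raise ValueError("need at least one species per guild")
    species, masses, guilds = [], [], []
    for prefix, mean, guild in (("small", mean_small, GUILD_SMALL),
                                ("large", mean_large, GUILD_LARGE)):
        if n_per_guild == 1:
            factors = np.array([1.0])
        else:
            factors = np.linspace(1.0 - spread, 1.0 + spread, n_per_guild)
        for i, f in enumerate(factors, start=1):
            species.append(f"{prefix}_{i:02d}")
            masses.append(mean * f)
            guilds.append(guild)
    return SpeciesPool(tuple(species), tuple(masses), tuple(guilds))


@dataclass(frozen=True)
class SimDesign:
    """A chronosequence sampling design for one area type."""

    area_type: str
    params: SuccessionParams
    base_ages: tuple[float, ...]
    n_years: int = 3
    first_year: int = 2004
    catch_mean: float = 200.0
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_ages:
            raise ValueError("design needs at least one site")
        if any(a < 0 for a in self.base_ages):
            raise ValueError("base ages must be >= 0")
        if self.catch_mean <= 0:
            raise ValueError("expected catch must be > 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.n_years < 1:
            raise ValueError("need at least one sampling year")


def solve_guild_weight(
    params: SuccessionParams, t_start: float, pool: SpeciesPool
) -> float:
    """Large-guild weight w such that w*m_L + (1-w)*m_S = N(t_start), in [0, 1]."""
    m_s = pool.guild_mean_mass(GUILD_SMALL)
    m_l = pool.guild_mean_mass(GUILD_LARGE)
    if m_s == m_l:
        raise ValueError("degenerate pool: guild mean masses are equal")
    n = evaluate(params, t_start)
    return float(np.clip((n - m_s) / (m_l - m_s), 0.0, 1.0))


def _draw_total(rng: np.random.Generator, mean: float, overdispersion: float) -> int:
    if overdispersion == 0:
        return int(rng.poisson(mean))
    # negative binomial with variance mean + overdispersion * mean^2
    size = 1.0 / overdispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate_chronosequence(design: SimDesign, pool: SpeciesPool) -> pd.DataFrame:
    """Draw a synthetic catch table for a full chronosequence design.

    For site i with base age a_i, sampling year j contributes a pooled
    sample at age a_i + j; the total catch is Poisson (or negative
    binomial) around the design's expected catch, individuals fall into
    guilds by the age-dependent weight and into species uniformly within
    guild.  Fully reproducible from the design seed.
    """
    rows = []
    species_arr = np.asarray(pool.species)
    idx_small = pool.guild_indices(GUILD_SMALL)
    idx_large = pool.guild_indices(GUILD_LARGE)
    for i, base_age in enumerate(design.base_ages):
        site_id = f"{design.area_type}_s{i + 1:02d}"
        for j in range(design.n_years):
            rng = np.random.default_rng([design.seed, i, j])
            age = float(base_age) + j
            w = solve_guild_weight(design.params, age, pool)
            total = _draw_total(rng, design.catch_mean, design.overdispersion)
            n_large = int(rng.binomial(total, w)) if total > 0 else 0
            n_small = total - n_large
            counts = np.zeros(len(species_arr), dtype=int)
            if n_small > 0:
                counts[idx_small] += rng.multinomial(
                    n_small, np.full(len(idx_small), 1.0 / len(idx_small)))
            if n_large > 0:
                counts[idx_large] += rng.multinomial(
                    n_large, np.full(len(idx_large), 1.0 / len(idx_large)))
            for sp, cnt in zip(species_arr, counts):
                if cnt > 0:
                    rows.append((site_id, design.area_type, float(base_age),
                                 design.first_year + j, sp, int(cnt)))
            if total == 0:
                # keep an explicit empty sample so the site-year is not lost
                rows.append((site_id, design.area_type, float(base_age),
                             design.first_year + j, str(species_arr[0]), 0))
    return pd.DataFrame(
        rows,
        columns=["site_id", "area_type", "stand_age", "sampling_year",
                 "species", "count"],
    )


#: (number of sites, youngest base age, oldest base age) per area type
_DESIGN_LAYOUT = {
    "forest_soil_planted": (14, 21.0, 119.0),
    "post_agri_natural": (13, 0.0, 64.0),
    "post_agri_planted": (69, 2.0, 119.0),
    "ash_heap": (3, 8.0, 14.0),
    "mining_heap": (4, 3.0, 23.0),
}


def study_design_presets(
    seed: int = 0,
    catch_mean: float = 200.0,
    overdispersion: float = 0.0,
) -> dict[str, SimDesign]:
    """The five chronosequence designs of the original field study.

    Site counts and stand-age ranges follow the study layout (14 forest-soil
    sites aged 21-119 y, 13 naturally regenerated and 69 planted
    post-agricultural sites, 3 ash-heap and 4 mining-heap sites), with base
    ages spread evenly across each range and three consecutive sampling
    years per site.  Model parameters are the shipped area-type presets.
    """
    designs = {}
    for area_type, (n_sites, lo, hi) in _DESIGN_LAYOUT.items():
        base_ages = tuple(np.linspace(lo, hi, n_sites).round(1))
        designs[area_type] = SimDesign(
            area_type=area_type,
            params=preset_params(area_type),
            base_ages=base_ages,
            catch_mean=catch_mean,
            overdispersion=overdispersion,
            seed=seed,
        )
    return designs
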