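"""Cod population state and non-fishing demography.

The stock is represented by super-individuals: one bucket per (cell, age,
maturity state) holding a real-valued count of identical fish. Length and
weight are deterministic functions of age (von Bertalanffy growth and a
power-law length-weight allometry), so the whole population lives in a dense
``(n_cells, max_age + 1, 2)`` count array; age 0 holds the current year's
recruits. Maturation moves fish from the immature to the mature bucket by the
incremental logistic probability, so the mature fraction at age a is exactly
the ogive value — a deterministic cohort-fraction rendering of per-individual
Bernoulli maturation.

Mortality sources handled here: larval (Beta(1000, 1.2) per cell-year; the
draw *is* the mortality fraction), adult natural (Normal(0.5938, 0.0517)
clipped to [0, 1] per cell-year), density-dependent recruitment
(Beverton-Holt, anchored to the cell's carrying capacity), and an adult
carrying-capacity cap. Fishing mortality lives in :mod:`mpabioecon.harvest`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import GridDomain
from .params import LifeHistoryParams, MortalityParams

__all__ = [
    "Population",
    "vb_length",
    "length_to_weight",
    "maturity_prob",
    "spawn",
    "draw_larval_mortality",
    "draw_adult_mortality",
    "bh_max_recruits",
    "beverton_holt_recruits",
    "enforce_carrying_capacity",
    "age_and_grow",
    "initialize_population",
]

IMM, MAT = 0, 1


def vb_length(age, p: LifeHistoryParams):
    """Von Bertalanffy length at age (cm), floored at 0."""
    age = np.asarray(age, dtype=float)
    L = p.L_inf * (1.0 - np.exp(-p.k_mean * (age - p.t0)))
    return np.maximum(L, 0.0)


def length_to_weight(length, p: LifeHistoryParams):
    """Allometric weight at length, in kg (lw_a is in g cm^-b)."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("length must be non-negative")
    return p.lw_a * length ** p.lw_b / 1000.0


def maturity_prob(age, p: LifeHistoryParams):
    """Logistic maturity ogive: P(mature | age)."""
    age = np.asarray(age, dtype=float)
    return 1.0 / (1.0 + np.exp(-p.age_mat_steepness * (age - p.age_mat_mid)))


@dataclass
class Population:
    """Super-individual counts indexed (cell, age, immature/mature)."""

    counts: np.ndarray          # (n_cells, max_age + 1, 2)
    length: np.ndarray          # per-age length, cm
    weight: np.ndarray          # per-age weight, kg

    @classmethod
    def empty(cls, n_cells: int, p: LifeHistoryParams) -> "Population":
        ages = np.arange(p.max_age + 1)
        length = vb_length(ages, p)
        return cls(
            counts=np.zeros((n_cells, p.max_age + 1, 2)),
            length=length,
            weight=length_to_weight(length, p),
        )

    def copy(self) -> "Population":
        return Population(self.counts.copy(), self.length.copy(), self.weight.copy())

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def total_count(self) -> float:
        return float(self.counts.sum())

    def biomass_per_cell(self) -> np.ndarray:
        """Total biomass per cell, tonnes."""
        return (self.counts.sum(axis=2) @ self.weight) / 1000.0

    def total_biomass(self) -> float:
        return float(self.biomass_per_cell().sum())

    def mature_biomass_per_cell(self) -> np.ndarray:
        """Mature (spawner) biomass per cell, kg."""
        return self.counts[:, :, MAT] @ self.weight

    def to_frame(self) -> pd.DataFrame:
        """Long-format snapshot: one row per non-empty super-individual."""
        cell, age, mat = np.nonzero(self.counts)
        return pd.DataFrame({
            "cell_id": cell,
            "age": age,
            "count": self.counts[cell, age, mat],
            "length": self.length[age],
            "weight": self.weight[age],
            "mature": mat.astype(bool),
        })


def spawn(pop: Population, p: LifeHistoryParams) -> np.ndarray:
    """Egg production per cell: fecundity x female spawner biomass (kg)."""
    return p.fecundity * p.female_fraction * pop.mature_biomass_per_cell()


def draw_larval_mortality(
    n_draws: int, mp: MortalityParams, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Per-cell-year larval mortality fractions ~ Beta(alpha, beta)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.beta(mp.larval_alpha, mp.larval_beta, size=n_draws)


def draw_adult_mortality(
    n_draws: int, mp: MortalityParams, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Per-cell-year adult mortality ~ Normal(mu, sd) clipped to [0, 1]."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.clip(rng.normal(mp.adult_mu, mp.adult_sd, size=n_draws), 0.0, 1.0)


def per_recruit_standing_biomass(p: LifeHistoryParams, mp: MortalityParams) -> float:
    """Equilibrium standing biomass (kg) sustained by one recruit per year.

    With a constant annual recruitment R and mean adult survival
    s = 1 - adult_mu, the steady-state cohort sizes are R*s^(a-1) for ages
    a = 1..max_age, so standing biomass per unit recruitment is
    sum_a s^(a-1) * w(a). This anchors the Beverton-Holt asymptote to the
    carrying capacity: R_max recruits per year eventually hold the cell at K.
    """
    ages = np.arange(1, p.max_age + 1)
    s = 1.0 - mp.adult_mu
    w = length_to_weight(vb_length(ages, p), p)
    return float(np.sum(s ** (ages - 1) * w))


def bh_max_recruits(K_cell: float, p: LifeHistoryParams, mp: MortalityParams) -> float:
    """Beverton-Holt asymptote R_max for a cell of carrying capacity K_cell (t)."""
    if K_cell <= 0:
        return 0.0
    return K_cell * 1000.0 / per_recruit_standing_biomass(p, mp)


def beverton_holt_recruits(settlers, K_cell, p: LifeHistoryParams,
                           mp: MortalityParams):
    """Recruits from settlers: R = a*S / (1 + a*S/R_max), a = bh_slope."""
    settlers = np.asarray(settlers, dtype=float)
    K_cell = np.asarray(K_cell, dtype=float)
    if np.any(settlers < 0):
        raise ValueError("settlers must be non-negative")
    phi = per_recruit_standing_biomass(p, mp)
    r_max = K_cell * 1000.0 / phi
    a_s = mp.bh_slope * settlers
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(r_max > 0, a_s / (1.0 + np.divide(
            a_s, r_max, out=np.zeros_like(a_s), where=r_max > 0)), 0.0)
    return r


def enforce_carrying_capacity(pop: Population, domain: GridDomain) -> Population:
    """Scale down cells whose adult biomass exceeds K x area.

    The cap applies uniformly across a cell's super-individuals, so the age
    structure is preserved; cells at or below capacity are untouched.
    """
    cap_kg = domain.K * domain.cell_area * 1000.0
    biomass_kg = pop.counts.sum(axis=2) @ pop.weight
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(biomass_kg > cap_kg,
                         np.divide(cap_kg, biomass_kg,
                                   out=np.ones_like(cap_kg), where=biomass_kg > 0),
                         1.0)
    out = pop.copy()
    out.counts *= scale[:, None, None]
    return out


def age_and_grow(pop: Population, p: LifeHistoryParams) -> Population:
    """Advance every cohort one year and apply incremental maturation.

    Counts are conserved: the oldest tracked cohort is a plus-group (cohorts
    reaching ``max_age`` merge into it). Immature fish of new age a mature
    with probability (P(a) - P(a-1)) / (1 - P(a-1)), so the cohort's mature
    fraction tracks the ogive exactly; fish never revert to immature.
    """
    out = pop.copy()
    new = np.zeros_like(out.counts)
    new[:, 1:, :] = out.counts[:, :-1, :]
    new[:, -1, :] += out.counts[:, -1, :]       # plus-group
    ages = np.arange(p.max_age + 1, dtype=float)
    p_now = maturity_prob(ages, p)
    p_prev = maturity_prob(ages - 1.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.clip((p_now - p_prev) / np.maximum(1.0 - p_prev, 1e-300), 0.0, 1.0)
    inc[p_prev > 1.0 - 1e-9] = 1.0    # ogive saturated in float: mature now
    maturing = new[:, :, IMM] * inc[None, :]
    new[:, :, IMM] -= maturing
    new[:, :, MAT] += maturing
    out.counts = new
    return out


def initialize_population(
    domain: GridDomain,
    p: LifeHistoryParams,
    mp: MortalityParams,
    seed: int = 0,
) -> Population:
    """Seed ``initial_abun`` fish across water cells proportional to K.

    The age composition is the stable-age approximation from mean adult
    survival (proportions ~ s^(a-1), ages 1..max_age) and each age's mature
    fraction follows the ogive. Deterministic given the domain.
    """
    pop = Population.empty(domain.n_cells, p)
    water = domain.water_eez_ids
    weights_K = domain.K[water] * domain.cell_area
    if weights_K.sum() <= 0:
        weights_K = np.ones_like(weights_K)
    cell_share = weights_K / weights_K.sum()

    ages = np.arange(1, p.max_age + 1)
    s = 1.0 - mp.adult_mu
    age_share = s ** (ages - 1)
    age_share /= age_share.sum()
    mature_frac = maturity_prob(ages, p)

    n = p.initial_abun * cell_share[:, None] * age_share[None, :]
    pop.counts[water[:, None], ages[None, :], MAT] = n * mature_frac[None, :]
    pop.counts[water[:, None], ages[None, :], IMM] = n * (1.0 - mature_frac[None, :])
    return pop
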