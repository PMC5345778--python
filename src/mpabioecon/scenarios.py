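"""Management-scenario generation: four ways of closing 10% of the EEZ.

* ``status_quo`` — only the supplied pre-existing MPAs (those at least one
  model cell, 400 km², in size); with none supplied, nothing is protected.
* ``max_distance`` — MPAs placed greedily to maximize the distance between
  them (a worst case for connectivity).
* ``fixed_distance`` — MPAs placed so nearest-neighbour spacing tracks a
  target (~75 km, of the order of mean adult dispersal).
* ``targeted`` — breeding sites protected by default, the remaining budget
  filled with fixed-distance placement restricted to suitable habitat.

New-MPA sizes are drawn from a configurable distribution (default log-normal,
median ~2 cells, a stand-in for the WDPA coastal/marine size distribution),
with a floor of one model cell. Placement is greedy and sequential: each MPA
is seeded at a chosen center cell and grown by accreting the nearest
unprotected water cells. All tie-breaks are by ascending cell id, so a fixed
seed reproduces a scenario exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .domain import GridDomain

__all__ = [
    "MPAScenario",
    "MPASizeDistribution",
    "sample_mpa_sizes",
    "scenario_status_quo",
    "place_max_distance",
    "place_fixed_distance",
    "place_targeted",
    "build_scenario",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("status_quo", "max_distance", "fixed_distance", "targeted")


@dataclass
class MPASizeDistribution:
    """Log-normal MPA size distribution with a hard minimum size.

    Defaults give a median of ~800 km² (two model cells).
    """

    log_mean: float = float(np.log(800.0))   # log km^2
    log_sd: float = 0.7
    min_size: float = 400.0                  # km^2

    def sample(self, rng: np.random.Generator) -> float:
        return max(float(rng.lognormal(self.log_mean, self.log_sd)), self.min_size)


@dataclass
class MPAScenario:
    """A named set of protected cells covering ``coverage`` of the EEZ."""

    name: str
    protected_cells: frozenset[int]
    coverage: float
    mpas: list[list[int]] = field(default_factory=list)  # cells per MPA
    warning: str | None = None

    def protected_mask(self, n_cells: int) -> np.ndarray:
        mask = np.zeros(n_cells, dtype=bool)
        mask[list(self.protected_cells)] = True
        return mask

    def centroids(self, domain: GridDomain) -> np.ndarray:
        """Area-weighted (= unweighted, cells are equal) centroid per MPA."""
        return np.array(
            [[domain.x[m].mean(), domain.y[m].mean()] for m in self.mpas]
        ).reshape(-1, 2)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mpa,cell_id\n")
            for k, cells in enumerate(self.mpas):
                for c in sorted(cells):
                    fh.write(f"{k},{c}\n")

    def to_geojson(self, path, domain: GridDomain) -> None:
        half = domain.spacing / 2.0
        feats = []
        for k, cells in enumerate(self.mpas):
            polys = []
            for c in sorted(cells):
                cx, cy = float(domain.x[c]), float(domain.y[c])
                polys.append([[
                    [cx - half, cy - half], [cx + half, cy - half],
                    [cx + half, cy + half], [cx - half, cy + half],
                    [cx - half, cy - half],
                ]])
            feats.append({
                "type": "Feature",
                "geometry": {"type": "MultiPolygon", "coordinates": polys},
                "properties": {"mpa": k, "n_cells": len(cells)},
            })
        with open(path, "w") as fh:
            json.dump({
                "type": "FeatureCollection", "features": feats,
                "properties": {"name": self.name, "coverage": self.coverage},
            }, fh)


def sample_mpa_sizes(
    target_total: float,
    dist: MPASizeDistribution | None = None,
    seed: int = 0,
    cell_area: float = 400.0,
) -> list[float]:
    """Draw MPA sizes (km²) until their total first reaches ``target_total``.

    Each size is rounded to a whole number of cells (>= the distribution's
    minimum); the last draw is clipped so the total lands within one cell
    area of the target.
    """
    dist = dist or MPASizeDistribution(min_size=cell_area)
    if target_total < cell_area:
        raise ValueError("target_total must be at least one cell area")
    rng = np.random.default_rng(seed)
    min_cells = max(1, round(dist.min_size / cell_area))
    sizes: list[float] = []
    total = 0.0
    while total < target_total:
        n_cells = max(min_cells, round(dist.sample(rng) / cell_area))
        if total + n_cells * cell_area >= target_total:
            needed = int(np.ceil((target_total - total) / cell_area))
            n_cells = max(min_cells, needed)
        sizes.append(n_cells * cell_area)
        total += n_cells * cell_area
    return sizes


def scenario_status_quo(domain: GridDomain, existing_mpas=None) -> MPAScenario:
    """Protect the cells covered by existing MPAs of at least one cell (400 km²).

    ``existing_mpas`` may be an iterable of shapely geometries, an iterable of
    cell-id collections (one per MPA), or a single flat cell-id set treated as
    one MPA. Smaller MPAs are dropped.
    """
    mpas: list[list[int]] = []
    items = list(existing_mpas or [])
    if items and all(isinstance(i, (int, np.integer)) for i in items):
        items = [items]
    water = set(map(int, domain.water_eez_ids))
    for mpa in items:
        if hasattr(mpa, "area"):  # shapely geometry
            if mpa.area < domain.cell_area:
                continue
            from shapely.geometry import Point
            cells = [
                int(i) for i in domain.water_eez_ids
                if mpa.contains(Point(float(domain.x[i]), float(domain.y[i])))
            ]
        else:
            cells = sorted(set(map(int, mpa)) & water)
            if len(cells) * domain.cell_area < domain.cell_area:
                cells = []
        if cells:
            mpas.append(sorted(cells))
    protected = frozenset(c for m in mpas for c in m)
    coverage = len(protected) * domain.cell_area / domain.eez_area
    return MPAScenario("status_quo", protected, coverage, mpas)


def _grow_mpa(domain: GridDomain, seed_cell: int, n_cells: int,
              protected: np.ndarray, allowed: np.ndarray) -> list[int]:
    """Accrete the ``n_cells`` nearest allowed, unprotected water cells."""
    candidates = np.flatnonzero(allowed & ~protected)
    d = np.hypot(domain.x[candidates] - domain.x[seed_cell],
                 domain.y[candidates] - domain.y[seed_cell])
    order = np.lexsort((candidates, d))
    return [int(c) for c in candidates[order[:n_cells]]]


def _components(domain: GridDomain, cells: set[int]) -> list[list[int]]:
    """4-neighbour connected components of a cell set (for MPA centroids)."""
    remaining = set(cells)
    comps = []
    while remaining:
        seed_cell = min(remaining)
        stack, comp = [seed_cell], []
        remaining.discard(seed_cell)
        while stack:
            c = stack.pop()
            comp.append(c)
            i, j = c % domain.n_x, c // domain.n_x
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < domain.n_x and 0 <= nj < domain.n_y:
                    nb = nj * domain.n_x + ni
                    if nb in remaining:
                        remaining.discard(nb)
                        stack.append(nb)
        comps.append(sorted(comp))
    return comps


def _place_sequential(
    domain: GridDomain,
    name: str,
    fraction: float,
    dist: MPASizeDistribution | None,
    seed: int,
    objective: str,
    spacing: float = 75.0,
    allowed: np.ndarray | None = None,
    initial_mpas: list[list[int]] | None = None,
    target_cells: int | None = None,
) -> MPAScenario:
    """Greedy sequential placement engine shared by the treatment scenarios.

    ``objective`` is ``"max"`` (maximize the minimum distance to previously
    placed MPA centroids) or ``"spacing"`` (minimize |nearest-centroid
    distance - spacing|). The first MPA is seeded at a random allowed water
    cell. Ties are broken by ascending cell id.
    """
    rng = np.random.default_rng(seed)
    water_mask = np.zeros(domain.n_cells, dtype=bool)
    water_mask[domain.water_eez_ids] = True
    if allowed is None:
        allowed = water_mask
    else:
        allowed = allowed & water_mask

    protected = np.zeros(domain.n_cells, dtype=bool)
    mpas: list[list[int]] = [list(m) for m in (initial_mpas or [])]
    for m in mpas:
        protected[m] = True

    if target_cells is None:
        target_cells = round(fraction * int(domain.in_eez.sum()))
    budget = target_cells - int(protected.sum())
    warning = None
    if budget > 0:
        if not (allowed & ~protected).any():
            raise ValueError("insufficient water area to place MPAs")
        sizes = sample_mpa_sizes(budget * domain.cell_area, dist, seed=int(rng.integers(2**31)),
                                 cell_area=domain.cell_area)
        for size in sizes:
            n_cells = min(round(size / domain.cell_area), budget)
            if n_cells <= 0:
                break
            candidates = np.flatnonzero(allowed & ~protected)
            if candidates.size == 0:
                warning = ("allowed cells exhausted before reaching the "
                           "coverage target; protected all allowed cells")
                warnings.warn(warning)
                break
            if not mpas:
                center = int(rng.choice(candidates))
            else:
                # distance from each candidate to its nearest existing centroid
                cents = np.array([[domain.x[m].mean(), domain.y[m].mean()] for m in mpas])
                d = np.hypot(
                    domain.x[candidates][:, None] - cents[None, :, 0],
                    domain.y[candidates][:, None] - cents[None, :, 1],
                ).min(axis=1)
                if objective == "max":
                    best = np.lexsort((candidates, -d))[0]
                else:
                    best = np.lexsort((candidates, np.abs(d - spacing)))[0]
                center = int(candidates[best])
            cells = _grow_mpa(domain, center, n_cells, protected, allowed)
            if not cells:
                break
            protected[cells] = True
            mpas.append(sorted(cells))
            budget = target_cells - int(protected.sum())
            if budget <= 0:
                break
        if budget > 0 and not (allowed & ~protected).any():
            warning = warning or ("allowed cells exhausted before reaching the "
                                  "coverage target; protected all allowed cells")
            warnings.warn(warning)

    cells = frozenset(int(i) for i in np.flatnonzero(protected))
    coverage = len(cells) * domain.cell_area / domain.eez_area
    return MPAScenario(name, cells, coverage, mpas, warning=warning)


def place_max_distance(
    domain: GridDomain,
    fraction: float = 0.10,
    dist: MPASizeDistribution | None = None,
    seed: int = 0,
) -> MPAScenario:
    """Greedy farthest-point MPA placement covering ``fraction`` of the EEZ."""
    return _place_sequential(domain, "max_distance", fraction, dist, seed, "max")


def place_fixed_distance(
    domain: GridDomain,
    spacing: float = 75.0,
    fraction: float = 0.10,
    dist: MPASizeDistribution | None = None,
    seed: int = 0,
) -> MPAScenario:
    """Sequential placement targeting ~``spacing`` km between MPA centroids."""
    return _place_sequential(
        domain, "fixed_distance", fraction, dist, seed, "spacing", spacing=spacing
    )


def place_targeted(
    domain: GridDomain,
    spacing: float = 75.0,
    fraction: float = 0.10,
    suitability_threshold: float = 0.5,
    dist: MPASizeDistribution | None = None,
    seed: int = 0,
) -> MPAScenario:
    """Protect all breeding sites, then add spaced MPAs in suitable habitat."""
    breeding = set(map(int, np.flatnonzero(
        domain.is_breeding & ~domain.is_land & domain.in_eez)))
    initial = _components(domain, breeding)
    allowed = (domain.suitability >= suitability_threshold)
    scenario = _place_sequential(
        domain, "targeted", fraction, dist, seed, "spacing", spacing=spacing,
        allowed=allowed, initial_mpas=initial,
    )
    return scenario


def build_scenario(
    name: str,
    domain: GridDomain,
    seed: int = 0,
    fraction: float = 0.10,
    spacing: float = 75.0,
    suitability_threshold: float = 0.5,
    dist: MPASizeDistribution | None = None,
    existing_mpas=None,
) -> MPAScenario:
    """Dispatch on scenario name (see ``SCENARIO_NAMES``)."""
    if name == "status_quo":
        return scenario_status_quo(domain, existing_mpas)
    if name == "max_distance":
        return place_max_distance(domain, fraction, dist, seed)
    if name == "fixed_distance":
        return place_fixed_distance(domain, spacing, fraction, dist, seed)
    if name == "targeted":
        return place_targeted(domain, spacing, fraction, suitability_threshold, dist, seed)
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
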