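"""Gridded seascape construction and annotation.

The simulation domain is a regular lattice of square cells (default 400 km²,
i.e. 20 km x 20 km) classified as land, EEZ water, or outside-EEZ water. Water
cells carry a habitat-suitability field, breeding-site flags, distance to
shore, and a stochastic carrying-capacity field (Normal, mean 0.43 t/km², SD
0.38, clipped below at 0 — clipping rather than redrawing, which biases the
field mean slightly upward; see docs/methods.md).

Domains are either generated synthetically (a contiguous, optionally
irregular land margin along the western edge standing in for a coastline) or
overlaid on user-supplied shapely polygons for land and the EEZ.

Conventions
-----------
* Cell ids are row-major, x fastest, starting at 0 at the lower-left cell.
* Coordinates are cell-center km; the lower-left cell center is the origin.
* Distances are Euclidean between cell centers, ignoring land obstruction.
* dist_to_shore is the distance to the nearest land-cell center (0 on land).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridCell",
    "GridDomain",
    "build_synthetic_domain",
    "load_domain_from_polygons",
    "assign_habitat_and_breeding",
    "assign_carrying_capacity",
    "draw_carrying_capacity",
]

CSV_COLUMNS = [
    "id", "x", "y", "area", "is_land", "in_eez", "suitability",
    "is_breeding", "dist_to_shore", "K",
]


@dataclass
class GridCell:
    """One grid cell; a convenience view over the domain's arrays."""

    id: int
    center: tuple[float, float]
    area: float
    is_land: bool
    in_eez: bool
    habitat_suitability: float
    is_breeding_site: bool
    dist_to_shore: float
    carrying_capacity: float


@dataclass
class GridDomain:
    """Discretized seascape held as flat per-cell arrays (row-major)."""

    n_x: int
    n_y: int
    cell_area: float                      # km^2
    x: np.ndarray                         # cell-center x, km
    y: np.ndarray                         # cell-center y, km
    is_land: np.ndarray                   # bool
    in_eez: np.ndarray                    # bool
    suitability: np.ndarray               # [0, 1]
    is_breeding: np.ndarray               # bool
    dist_to_shore: np.ndarray             # km
    K: np.ndarray                         # carrying capacity, t km^-2
    rng_seed: int | None = None
    _pairwise: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def spacing(self) -> float:
        """Center-to-center spacing, km."""
        return float(np.sqrt(self.cell_area))

    @property
    def water_eez_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_land & self.in_eez)

    @property
    def eez_area(self) -> float:
        """Total EEZ area, km² (= number of in_eez cells x cell area)."""
        return float(self.in_eez.sum() * self.cell_area)

    def pairwise_distances(self) -> np.ndarray:
        """All-pairs Euclidean center distances (cached), km."""
        if self._pairwise is None:
            dx = self.x[:, None] - self.x[None, :]
            dy = self.y[:, None] - self.y[None, :]
            self._pairwise = np.hypot(dx, dy)
        return self._pairwise

    def cells(self) -> list[GridCell]:
        return [
            GridCell(
                id=i,
                center=(float(self.x[i]), float(self.y[i])),
                area=self.cell_area,
                is_land=bool(self.is_land[i]),
                in_eez=bool(self.in_eez[i]),
                habitat_suitability=float(self.suitability[i]),
                is_breeding_site=bool(self.is_breeding[i]),
                dist_to_shore=float(self.dist_to_shore[i]),
                carrying_capacity=float(self.K[i]),
            )
            for i in range(self.n_cells)
        ]

    # -- serialization --------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for i in range(self.n_cells):
                writer.writerow([
                    i, repr(float(self.x[i])), repr(float(self.y[i])),
                    repr(float(self.cell_area)), int(self.is_land[i]),
                    int(self.in_eez[i]), repr(float(self.suitability[i])),
                    int(self.is_breeding[i]), repr(float(self.dist_to_shore[i])),
                    repr(float(self.K[i])),
                ])

    @classmethod
    def from_csv(cls, path) -> "GridDomain":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != CSV_COLUMNS:
                raise ValueError(f"expected columns {CSV_COLUMNS}, got {reader.fieldnames}")
            rows = sorted(reader, key=lambda r: int(r["id"]))
        x = np.array([float(r["x"]) for r in rows])
        y = np.array([float(r["y"]) for r in rows])
        cell_area = float(rows[0]["area"])
        spacing = float(np.sqrt(cell_area))
        n_x = len(np.unique(np.round(x / spacing).astype(int)))
        n_y = len(rows) // n_x
        return cls(
            n_x=n_x, n_y=n_y, cell_area=cell_area, x=x, y=y,
            is_land=np.array([bool(int(r["is_land"])) for r in rows]),
            in_eez=np.array([bool(int(r["in_eez"])) for r in rows]),
            suitability=np.array([float(r["suitability"]) for r in rows]),
            is_breeding=np.array([bool(int(r["is_breeding"])) for r in rows]),
            dist_to_shore=np.array([float(r["dist_to_shore"]) for r in rows]),
            K=np.array([float(r["K"]) for r in rows]),
        )

    def to_geojson(self, path) -> None:
        """Write cells as square polygons with per-cell properties."""
        half = self.spacing / 2.0
        features = []
        for i in range(self.n_cells):
            cx, cy = float(self.x[i]), float(self.y[i])
            ring = [
                [cx - half, cy - half], [cx + half, cy - half],
                [cx + half, cy + half], [cx - half, cy + half],
                [cx - half, cy - half],
            ]
            features.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": i, "area": self.cell_area,
                    "is_land": bool(self.is_land[i]),
                    "in_eez": bool(self.in_eez[i]),
                    "suitability": float(self.suitability[i]),
                    "is_breeding": bool(self.is_breeding[i]),
                    "dist_to_shore": float(self.dist_to_shore[i]),
                    "K": float(self.K[i]),
                },
            })
        obj = {
            "type": "FeatureCollection",
            "features": features,
            "properties": {"n_x": self.n_x, "n_y": self.n_y, "cell_area": self.cell_area},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_geojson(cls, path) -> "GridDomain":
        with open(path) as fh:
            obj = json.load(fh)
        feats = sorted(obj["features"], key=lambda f: f["properties"]["id"])
        n = len(feats)
        props = [f["properties"] for f in feats]
        centers = []
        for f in feats:
            ring = np.asarray(f["geometry"]["coordinates"][0][:4])
            centers.append(ring.mean(axis=0))
        centers = np.asarray(centers)
        return cls(
            n_x=int(obj["properties"]["n_x"]), n_y=int(obj["properties"]["n_y"]),
            cell_area=float(obj["properties"]["cell_area"]),
            x=centers[:, 0], y=centers[:, 1],
            is_land=np.array([p["is_land"] for p in props], dtype=bool),
            in_eez=np.array([p["in_eez"] for p in props], dtype=bool),
            suitability=np.array([p["suitability"] for p in props]),
            is_breeding=np.array([p["is_breeding"] for p in props], dtype=bool),
            dist_to_shore=np.array([p["dist_to_shore"] for p in props]),
            K=np.array([p["K"] for p in props]),
        )


def _nearest_land_distance(x, y, is_land) -> np.ndarray:
    """Distance from each cell center to the nearest land-cell center, km."""
    land = np.flatnonzero(is_land)
    if land.size == 0:
        raise ValueError("domain has no land cells")
    dx = x[:, None] - x[land][None, :]
    dy = y[:, None] - y[land][None, :]
    d = np.hypot(dx, dy).min(axis=1)
    d[is_land] = 0.0
    return d


def build_synthetic_domain(
    n_x: int,
    n_y: int,
    cell_area: float = 400.0,
    coast_profile: dict | None = None,
    seed: int = 0,
    suitability_threshold: float = 0.5,
    breeding_fraction: float = 0.05,
    shore_bias: float = 2.0,
    k_mean: float = 0.43,
    k_sd: float = 0.38,
) -> GridDomain:
    """Build a fully annotated synthetic seascape.

    A contiguous land margin runs along the western edge; its width per row is
    ``base_width`` plus a random 0..roughness offset (``coast_profile`` keys
    ``base_width`` and ``roughness``, defaults 1 and 1). All remaining cells
    are EEZ water. Habitat, breeding sites and carrying capacity are assigned
    with seeds derived from ``seed``, so the whole construction is
    deterministic for a fixed seed.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("n_x and n_y must both be >= 2")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    profile = {"base_width": 1, "roughness": 1}
    profile.update(coast_profile or {})

    ss = np.random.SeedSequence(seed)
    coast_seed, hab_seed, k_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    rng = np.random.default_rng(coast_seed)

    spacing = float(np.sqrt(cell_area))
    xs = np.arange(n_x) * spacing
    ys = np.arange(n_y) * spacing
    X, Y = np.meshgrid(xs, ys)           # shape (n_y, n_x)
    widths = profile["base_width"] + rng.integers(0, profile["roughness"] + 1, size=n_y)
    widths = np.clip(widths, 1, n_x - 1)  # keep >=1 water cell per row
    is_land = (np.arange(n_x)[None, :] < widths[:, None]).ravel()

    x, y = X.ravel(), Y.ravel()
    in_eez = ~is_land
    dist = _nearest_land_distance(x, y, is_land)
    domain = GridDomain(
        n_x=n_x, n_y=n_y, cell_area=cell_area, x=x, y=y,
        is_land=is_land, in_eez=in_eez,
        suitability=np.zeros(n_x * n_y),
        is_breeding=np.zeros(n_x * n_y, dtype=bool),
        dist_to_shore=dist,
        K=np.zeros(n_x * n_y),
        rng_seed=seed,
    )
    domain = assign_habitat_and_breeding(
        domain, suitability_threshold=suitability_threshold,
        breeding_fraction=breeding_fraction, seed=hab_seed, shore_bias=shore_bias,
    )
    return assign_carrying_capacity(domain, k_mean=k_mean, k_sd=k_sd, seed=k_seed)


def load_domain_from_polygons(
    land_polygons,
    eez_polygon,
    cell_area: float = 400.0,
    **annotate_kwargs,
) -> GridDomain:
    """Overlay a grid on the EEZ bounding box and classify cells by center.

    A cell is ``in_eez`` if its center falls inside ``eez_polygon`` and not
    inside any land polygon; it is land if its center falls inside a land
    polygon. When land cells exist, dist_to_shore is grid-native (nearest
    land-cell center); otherwise it is the shapely distance to the nearest
    land polygon, or — with no land at all — the distance to the grid's
    western boundary, treated as the shoreline.
    """
    from shapely.geometry import Point
    from shapely.ops import unary_union

    land_polygons = list(land_polygons or [])
    if eez_polygon is None or eez_polygon.is_empty:
        raise ValueError("eez_polygon must be a non-empty geometry")
    if not eez_polygon.is_valid or any(not p.is_valid for p in land_polygons):
        raise ValueError("invalid geometry supplied")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")

    spacing = float(np.sqrt(cell_area))
    minx, miny, maxx, maxy = eez_polygon.bounds
    n_x = max(int(np.ceil((maxx - minx) / spacing)), 1)
    n_y = max(int(np.ceil((maxy - miny) / spacing)), 1)
    xs = minx + (np.arange(n_x) + 0.5) * spacing
    ys = miny + (np.arange(n_y) + 0.5) * spacing
    X, Y = np.meshgrid(xs, ys)
    x, y = X.ravel() - xs[0], Y.ravel() - ys[0]   # origin at lower-left center

    land_union = unary_union(land_polygons) if land_polygons else None
    pts = [Point(px, py) for px, py in zip(X.ravel(), Y.ravel())]
    is_land = np.array(
        [land_union is not None and land_union.contains(p) for p in pts], dtype=bool
    )
    in_eez = np.array(
        [eez_polygon.contains(p) for p in pts], dtype=bool
    ) & ~is_land
    if not in_eez.any():
        raise ValueError("no EEZ water cells: land covers the EEZ or the grid is empty")

    if is_land.any():
        dist = _nearest_land_distance(x, y, is_land)
    elif land_union is not None:
        dist = np.array([p.distance(land_union) for p in pts])
    else:
        dist = x + spacing / 2.0
    domain = GridDomain(
        n_x=n_x, n_y=n_y, cell_area=cell_area, x=x, y=y,
        is_land=is_land, in_eez=in_eez,
        suitability=np.zeros(x.size), is_breeding=np.zeros(x.size, dtype=bool),
        dist_to_shore=dist, K=np.zeros(x.size),
    )
    if annotate_kwargs:
        seed = annotate_kwargs.pop("seed", 0)
        domain = assign_habitat_and_breeding(domain, seed=seed, **annotate_kwargs)
        domain = assign_carrying_capacity(domain, seed=seed + 1)
    return domain


def assign_habitat_and_breeding(
    domain: GridDomain,
    suitability_threshold: float = 0.5,
    breeding_fraction: float = 0.05,
    seed: int = 0,
    shore_bias: float = 2.0,
    smoothing_cells: float = 2.0,
) -> GridDomain:
    """Assign a smoothed random habitat field and pick breeding sites.

    The habitat layer is uniform noise smoothed with a Gaussian kernel
    (``smoothing_cells`` sigma, in cell widths) and min-max rescaled to [0, 1]
    over water cells. Breeding sites are the ``breeding_fraction`` share of
    water cells with the highest score ``suitability x (1 - d/d_max)**shore_bias``
    among cells with suitability >= ``suitability_threshold``; ``shore_bias=0``
    reduces to pure top-suitability selection.
    """
    if not (0.0 < breeding_fraction < 1.0):
        raise ValueError("breeding_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    noise = rng.random((domain.n_y, domain.n_x))
    smooth = gaussian_filter(noise, sigma=smoothing_cells, mode="reflect").ravel()

    water = ~domain.is_land
    suit = np.zeros(domain.n_cells)
    w = smooth[water]
    lo, hi = w.min(), w.max()
    suit[water] = (w - lo) / (hi - lo) if hi > lo else 0.5

    eligible = np.flatnonzero(water & (suit >= suitability_threshold))
    if eligible.size == 0:
        raise ValueError(
            f"suitability_threshold={suitability_threshold} excludes every water cell"
        )
    n_breed = max(1, round(breeding_fraction * int(water.sum())))
    d = domain.dist_to_shore
    d_max = d[water].max()
    score = suit[eligible] * (1.0 - d[eligible] / (d_max + 1e-12)) ** shore_bias
    # stable sort: descending score, ties by ascending cell id
    order = np.lexsort((eligible, -score))
    chosen = eligible[order[:n_breed]]
    if chosen.size < n_breed:
        warnings.warn(
            "fewer eligible cells than requested breeding sites; using all eligible"
        )
    is_breeding = np.zeros(domain.n_cells, dtype=bool)
    is_breeding[chosen] = True
    domain.suitability = suit
    domain.is_breeding = is_breeding
    return domain


def draw_carrying_capacity(
    n: int,
    k_mean: float = 0.43,
    k_sd: float = 0.38,
    seed: int = 0,
    truncate: bool = True,
) -> np.ndarray:
    """Draw per-cell carrying capacities, Normal(k_mean, k_sd) in t km^-2.

    With ``truncate`` (the default) negative draws are clipped to 0, which
    raises the field mean slightly above ``k_mean``; ``truncate=False`` gives
    the raw normal draws (used to verify the distribution's mean).
    """
    if k_mean <= 0:
        raise ValueError("k_mean must be positive")
    if k_sd < 0:
        raise ValueError("k_sd must be non-negative")
    draws = np.random.default_rng(seed).normal(k_mean, k_sd, size=n)
    return np.clip(draws, 0.0, None) if truncate else draws


def assign_carrying_capacity(
    domain: GridDomain,
    k_mean: float = 0.43,
    k_sd: float = 0.38,
    seed: int = 0,
) -> GridDomain:
    """Assign water-cell carrying capacities (t km^-2); land cells get 0."""
    water = np.flatnonzero(~domain.is_land)
    K = np.zeros(domain.n_cells)
    K[water] = draw_carrying_capacity(water.size, k_mean, k_sd, seed=seed)
    domain.K = K
    return domain
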