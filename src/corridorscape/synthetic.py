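"""Synthetic landscape generator.

Emulates the statistical structure of a savanna protected-area (PA) network
undergoing cropland expansion, so that the full analysis chain — ensemble
habitat modelling, resistance surfaces, least-cost corridors, circuit theory,
change accounting and validation — can be exercised end-to-end with no
external data. The generator produces:

* smooth correlated environmental fields (elevation, vegetation index,
  rainfall, wetness) built by Gaussian-kernel smoothing of white noise;
* slope derived from elevation, plus a ruggedness layer that is slope with
  added noise (deliberately collinear, to exercise the Pearson screen);
* point/line features (houses, roads, rivers) and their distance surfaces;
* disjoint PA polygons (rectangles and ellipses);
* a time series of land-cover maps in which cropland grows outward from
  settlement nuclei on flat, river-near land outside PAs, hitting configured
  per-step cover targets;
* presence points drawn from a known ("true") logistic suitability surface
  whose dominant positive effect is distance to cropland — i.e. simulated
  elephants avoid cultivated land — so parameter-recovery tests have a
  ground truth;
* dung-transect and interview-report tables for corridor validation, with
  one corridor forced silent to create a known inactive link.

Every output is a deterministic function of (config, seed): all randomness
flows from one master seed through named substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from corridorscape.raster import CovariateStack, RasterGrid, euclidean_distance_surface

__all__ = [
    "SimulationConfig",
    "TrueSuitability",
    "LANDCOVER_CODES",
    "SDM_COVARIATES",
    "simulate_protected_areas",
    "simulate_covariates",
    "simulate_cropland_series",
    "landcover_series",
    "true_suitability",
    "sample_presences",
    "simulate_validation_data",
    "pa_geojson",
]

#: Land-cover class codes shared across the package.
LANDCOVER_CODES = {
    "dense_woodland": 1,
    "open_woodland": 2,
    "burned": 3,
    "cropland": 4,
    "water": 5,
}

#: Covariates offered to the distribution model (before collinearity
#: screening; ``dist_cropland`` is appended per time step).
SDM_COVARIATES = [
    "elevation",
    "slope",
    "ruggedness",
    "twi",
    "evi",
    "rainfall",
    "dist_houses",
    "dist_roads",
    "dist_rivers",
]

# named substreams of the master seed
_STREAMS = {
    "fields": 1,
    "features": 2,
    "pas": 3,
    "cropland": 4,
    "presences": 5,
    "transects": 6,
    "reports": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng((int(seed), _STREAMS[stream]))


def _default_weights() -> dict[str, float]:
    # Distance to cropland dominates (simulated elephants avoid cultivation),
    # distance to houses is the second anthropogenic effect; environmental
    # effects are weaker, mirroring the relative-importance pattern the
    # generator is meant to reproduce.
    return {
        "dist_cropland": 2.5,
        "dist_houses": 1.0,
        "evi": 0.6,
        "slope": -0.6,
        "elevation": -0.4,
        "dist_roads": 0.4,
        "dist_rivers": -0.4,
        "rainfall": 0.4,
        "twi": 0.3,
    }


@dataclass
class SimulationConfig:
    """Parameters of one synthetic landscape.

    Defaults are the package's study conditions: a 120x120 grid of 1 km
    cells, 9 protected areas, ~300 presence points per time step, and
    cropland expanding 6.71% -> 8.79% -> 13.14% across the three steps.
    """

    nrows: int = 120
    ncols: int = 120
    cellsize: float = 1.0
    n_pas: int = 9
    n_presence: int = 300
    time_steps: tuple[int, ...] = (2000, 2010, 2019)
    cropland_target_fraction: tuple[float, ...] = (0.0671, 0.0879, 0.1314)
    smoothness: float = 8.0  # correlation length of random fields, in cells
    n_house_clusters: int = 15
    n_roads: int = 3
    n_rivers: int = 3
    true_effect_weights: dict[str, float] = field(default_factory=_default_weights)
    #: intercept of the suitability logistic; negative so that highly suitable
    #: habitat is the rarer condition (roughly a fifth of the landscape)
    suitability_intercept: float = -2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 20 or self.ncols < 20:
            raise ValueError("grid must be at least 20x20")
        if len(self.cropland_target_fraction) != len(self.time_steps):
            raise ValueError("one cropland target per time step required")
        if any(
            b < a - 1e-12
            for a, b in zip(self.cropland_target_fraction, self.cropland_target_fraction[1:])
        ):
            raise ValueError("cropland target fractions must be non-decreasing")
        w = self.true_effect_weights
        if "dist_cropland" not in w or w["dist_cropland"] <= 0:
            raise ValueError("true_effect_weights must include a positive dist_cropland weight")
        others = [abs(v) for k, v in w.items() if k != "dist_cropland"]
        if others and w["dist_cropland"] <= max(others):
            raise ValueError("dist_cropland must carry the strictly dominant weight")


@dataclass
class TrueSuitability:
    """Known suitability surface used to place presences (parameter-recovery
    ground truth)."""

    grid: RasterGrid
    weights: dict[str, float]


# ---------------------------------------------------------------------------
# Environmental fields and features
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized Gaussian random field with correlation length ``sigma``."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _slope_of(elevation: np.ndarray, cellsize: float) -> np.ndarray:
    """Maximum central-difference gradient magnitude (rise in m per km)."""
    gy, gx = np.gradient(elevation, cellsize)
    return np.hypot(gx, gy)


def _walk_line(
    rng: np.random.Generator, shape: tuple[int, int], mask: np.ndarray
) -> None:
    """Mark a meandering walk from one grid edge across the grid into ``mask``."""
    nrows, ncols = shape
    # start on a random edge, head roughly toward the opposite side
    edge = rng.integers(4)
    if edge == 0:
        r, c, heading = 0.0, float(rng.uniform(0, ncols)), math.pi / 2
    elif edge == 1:
        r, c, heading = float(nrows - 1), float(rng.uniform(0, ncols)), -math.pi / 2
    elif edge == 2:
        r, c, heading = float(rng.uniform(0, nrows)), 0.0, 0.0
    else:
        r, c, heading = float(rng.uniform(0, nrows)), float(ncols - 1), math.pi
    for _ in range(3 * max(nrows, ncols)):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < nrows and 0 <= ci < ncols):
            break
        mask[ri, ci] = 1.0
        heading += rng.normal(0, 0.25)
        c += math.cos(heading)
        r += math.sin(heading)


def _straight_line(rng: np.random.Generator, shape: tuple[int, int], mask: np.ndarray) -> None:
    """Rasterize a straight segment between two random opposite-edge points."""
    nrows, ncols = shape
    if rng.random() < 0.5:
        p0 = (0.0, float(rng.uniform(0, ncols - 1)))
        p1 = (float(nrows - 1), float(rng.uniform(0, ncols - 1)))
    else:
        p0 = (float(rng.uniform(0, nrows - 1)), 0.0)
        p1 = (float(rng.uniform(0, nrows - 1)), float(ncols - 1))
    n = 2 * max(nrows, ncols)
    rr = np.clip(np.round(np.linspace(p0[0], p1[0], n)).astype(int), 0, nrows - 1)
    cc = np.clip(np.round(np.linspace(p0[1], p1[1], n)).astype(int), 0, ncols - 1)
    mask[rr, cc] = 1.0


def simulate_covariates(cfg: SimulationConfig) -> CovariateStack:
    """Generate the static covariate stack.

    Layers: elevation (m), slope and its noisy ruggedness twin, topographic
    wetness proxy, vegetation-index proxy, rainfall, binary masks for houses,
    roads and rivers, and the Euclidean distance surface of each mask (km).
    """
    rng = _rng(cfg.seed, "fields")
    shape = (cfg.nrows, cfg.ncols)

    def grid(values: np.ndarray) -> RasterGrid:
        return RasterGrid(values, cellsize=cfg.cellsize, origin=(0.0, cfg.nrows * cfg.cellsize))

    elevation = 1200.0 + 400.0 * _smooth_field(rng, shape, cfg.smoothness)
    slope = _slope_of(elevation, cfg.cellsize * 1000.0) * 1000.0  # m rise per km, scaled
    slope_z = (slope - slope.mean()) / max(slope.std(), 1e-12)
    ruggedness = slope + 0.35 * slope.std() * rng.standard_normal(shape)
    twi = _smooth_field(rng, shape, cfg.smoothness) - 0.3 * slope_z
    evi = _smooth_field(rng, shape, cfg.smoothness)
    # rainfall: smooth field plus a gentle north-south gradient
    lat = np.linspace(1.0, -1.0, cfg.nrows)[:, None] * np.ones(shape)
    rainfall = 900.0 + 250.0 * (0.7 * _smooth_field(rng, shape, 1.5 * cfg.smoothness) + 0.3 * lat)

    frng = _rng(cfg.seed, "features")
    rivers = np.zeros(shape)
    for _ in range(cfg.n_rivers):
        _walk_line(frng, shape, rivers)
    roads = np.zeros(shape)
    for _ in range(cfg.n_roads):
        _straight_line(frng, shape, roads)

    # houses cluster on flat land near rivers
    dist_rivers = euclidean_distance_surface(grid(rivers)).values
    desir = -slope_z - 0.4 * (dist_rivers - dist_rivers.mean()) / max(dist_rivers.std(), 1e-12)
    desir = desir + 0.5 * frng.standard_normal(shape)
    p = np.exp(desir - desir.max())
    p /= p.sum()
    # half the clusters follow desirability, half scatter uniformly: rural
    # settlement is more dispersed than the cropland that later grows from it
    n_pref = cfg.n_house_clusters // 2 + cfg.n_house_clusters % 2
    pref = frng.choice(cfg.nrows * cfg.ncols, size=n_pref, replace=False, p=p.ravel())
    unif = frng.choice(cfg.nrows * cfg.ncols, size=cfg.n_house_clusters - n_pref, replace=False)
    centers = np.concatenate([pref, unif])
    houses = np.zeros(shape)
    for flat in centers:
        r0, c0 = divmod(int(flat), cfg.ncols)
        for _ in range(10):
            r = int(np.clip(round(r0 + frng.normal(0, 1.5)), 0, cfg.nrows - 1))
            c = int(np.clip(round(c0 + frng.normal(0, 1.5)), 0, cfg.ncols - 1))
            houses[r, c] = 1.0

    layers = {
        "elevation": elevation,
        "slope": slope,
        "ruggedness": ruggedness,
        "twi": twi,
        "evi": evi,
        "rainfall": rainfall,
        "houses": houses,
        "roads": roads,
        "rivers": rivers,
    }
    stack = CovariateStack(names=list(layers), grids={k: grid(v) for k, v in layers.items()})
    for feat in ("houses", "roads", "rivers"):
        stack.add(f"dist_{feat}", euclidean_distance_surface(stack[feat]))
    return stack


# ---------------------------------------------------------------------------
# Protected areas
# ---------------------------------------------------------------------------


def simulate_protected_areas(cfg: SimulationConfig) -> list[RasterGrid]:
    """Place ``n_pas`` disjoint PA masks (alternating rectangles/ellipses).

    Centers sit on a jittered regular lattice so that polygons never touch;
    half-sizes are drawn relative to the grid so PAs cover roughly 15% of it.
    """
    rng = _rng(cfg.seed, "pas")
    shape = (cfg.nrows, cfg.ncols)
    k = math.ceil(math.sqrt(cfg.n_pas))
    row_step = cfg.nrows / k
    col_step = cfg.ncols / k
    slots = [(i, j) for i in range(k) for j in range(k)]
    order = rng.permutation(len(slots))[: cfg.n_pas]
    masks: list[RasterGrid] = []
    rr, cc = np.meshgrid(np.arange(cfg.nrows), np.arange(cfg.ncols), indexing="ij")
    for idx, slot in enumerate(order):
        i, j = slots[slot]
        max_half = 0.30 * min(row_step, col_step)
        hr = rng.uniform(0.6, 1.0) * max_half
        hc = rng.uniform(0.6, 1.0) * max_half
        r0 = (i + 0.5) * row_step + rng.uniform(-0.1, 0.1) * row_step
        c0 = (j + 0.5) * col_step + rng.uniform(-0.1, 0.1) * col_step
        if idx % 2 == 0:  # rectangle
            m = (np.abs(rr - r0) <= hr) & (np.abs(cc - c0) <= hc)
        else:  # ellipse
            m = ((rr - r0) / hr) ** 2 + ((cc - c0) / hc) ** 2 <= 1.0
        masks.append(
            RasterGrid(m.astype(float), cellsize=cfg.cellsize, origin=(0.0, cfg.nrows * cfg.cellsize))
        )
    return masks


def pa_union_mask(pa_masks: Sequence[RasterGrid]) -> np.ndarray:
    out = np.zeros(pa_masks[0].shape, dtype=bool)
    for m in pa_masks:
        out |= m.values > 0
    return out


def pa_geojson(pa_masks: Sequence[RasterGrid], names: Sequence[str] | None = None) -> dict:
    """GeoJSON FeatureCollection of PA outlines (unions of cell squares)."""
    from shapely import union_all
    from shapely.geometry import box, mapping

    features = []
    for i, mask in enumerate(pa_masks):
        rows, cols = np.nonzero(mask.values > 0)
        cells = []
        for r, c in zip(rows, cols):
            x = mask.origin[0] + c * mask.cellsize
            y = mask.origin[1] - (r + 1) * mask.cellsize
            cells.append(box(x, y, x + mask.cellsize, y + mask.cellsize))
        geom = union_all(cells)
        features.append(
            {
                "type": "Feature",
                "properties": {"name": names[i] if names else f"PA{i + 1}"},
                "geometry": mapping(geom),
            }
        )
    return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# Cropland expansion and land cover
# ---------------------------------------------------------------------------


def simulate_cropland_series(
    cfg: SimulationConfig,
    covariates: CovariateStack,
    pa_masks: Sequence[RasterGrid] | None = None,
) -> list[RasterGrid]:
    """Grow cropland masks for each time step (nested over time).

    Cropland spreads outward from settlement nuclei (house cells outside
    PAs), preferentially onto flat, river-near cells, until each step's
    target cover fraction is met exactly in cell counts (so always within
    +-0.5 percentage points of the target).
    """
    import heapq

    if pa_masks is None:
        pa_masks = simulate_protected_areas(cfg)
    pa = pa_union_mask(pa_masks)
    shape = (cfg.nrows, cfg.ncols)
    total = cfg.nrows * cfg.ncols
    targets = [int(round(f * total)) for f in cfg.cropland_target_fraction]
    eligible = ~pa
    if targets[-1] > eligible.sum():
        raise ValueError(
            f"cropland target {cfg.cropland_target_fraction[-1]:.4f} exceeds the "
            f"non-PA area share {eligible.sum() / total:.4f}"
        )

    rng = _rng(cfg.seed, "cropland")
    slope = covariates["slope"].values
    slope_z = (slope - slope.mean()) / max(slope.std(), 1e-12)
    driv = covariates["dist_rivers"].values
    driv_z = (driv - driv.mean()) / max(driv.std(), 1e-12)
    desirability = -slope_z - 0.4 * driv_z + 0.3 * rng.standard_normal(shape)

    nuclei = np.nonzero((covariates["houses"].values > 0) & eligible)
    if len(nuclei[0]) == 0:
        raise ValueError("no settlement nuclei outside protected areas to seed cropland")

    cropland = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    in_heap = np.zeros(shape, dtype=bool)

    def push(r: int, c: int) -> None:
        if 0 <= r < shape[0] and 0 <= c < shape[1] and eligible[r, c] and not in_heap[r, c]:
            heapq.heappush(heap, (-desirability[r, c], r, c))
            in_heap[r, c] = True

    for r, c in zip(*nuclei):
        push(int(r), int(c))

    grids: list[RasterGrid] = []
    count = 0
    for target in targets:
        while count < target and heap:
            _, r, c = heapq.heappop(heap)
            if cropland[r, c]:
                continue
            cropland[r, c] = True
            count += 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr or dc:
                        push(r + dr, c + dc)
        grids.append(
            RasterGrid(
                cropland.astype(float),
                cellsize=cfg.cellsize,
                origin=(0.0, cfg.nrows * cfg.cellsize),
            )
        )
    return grids


def landcover_series(
    cfg: SimulationConfig,
    covariates: CovariateStack,
    cropland_masks: Sequence[RasterGrid],
) -> list[RasterGrid]:
    """Label every cell per time step: cropland overrides a static base map of
    water (wettest cells), burned (lowest vegetation index), dense woodland
    (highest vegetation index) and open woodland (the remainder)."""
    twi = covariates["twi"].values
    evi = covariates["evi"].values
    base = np.full((cfg.nrows, cfg.ncols), LANDCOVER_CODES["open_woodland"], dtype=float)
    base[evi <= np.quantile(evi, 0.25)] = LANDCOVER_CODES["burned"]
    base[evi >= np.quantile(evi, 0.78)] = LANDCOVER_CODES["dense_woodland"]
    base[twi >= np.quantile(twi, 0.922)] = LANDCOVER_CODES["water"]
    out = []
    for crop in cropland_masks:
        values = base.copy()
        values[crop.values > 0] = LANDCOVER_CODES["cropland"]
        out.append(crop.copy_with(values))
    return out


# ---------------------------------------------------------------------------
# True suitability and presence sampling
# ---------------------------------------------------------------------------


def true_suitability(cfg: SimulationConfig, stack: CovariateStack) -> TrueSuitability:
    """Logistic suitability in [0, 1] from standardized covariates.

    ``stack`` must contain every weighted covariate (including the per-step
    ``dist_cropland`` layer). With a positive weight, suitability is
    monotonically non-decreasing in distance to cropland.
    """
    weights = cfg.true_effect_weights
    missing = [k for k in weights if k not in stack]
    if missing:
        raise ValueError(f"stack lacks weighted covariates: {missing}")
    lin = np.full((cfg.nrows, cfg.ncols), cfg.suitability_intercept)
    for name, w in weights.items():
        v = stack[name].values
        lin += w * (v - v.mean()) / max(v.std(), 1e-12)
    suit = 1.0 / (1.0 + np.exp(-lin))
    return TrueSuitability(grid=stack.template.copy_with(suit), weights=dict(weights))


def sample_presences(
    true_suit: TrueSuitability, n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` presence cells without replacement, probability proportional
    to suitability; returns cell-center coordinates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), "presences")
    grid = true_suit.grid
    valid = grid.valid_mask() & (grid.values > 0)
    rows, cols = np.nonzero(valid)
    if n > rows.size:
        raise ValueError(f"n={n} exceeds {rows.size} cells with positive suitability")
    p = grid.values[rows, cols]
    p = p / p.sum()
    idx = rng.choice(rows.size, size=n, replace=False, p=p)
    rr, cc = rows[idx], cols[idx]
    x = grid.origin[0] + (cc + 0.5) * grid.cellsize
    y = grid.origin[1] - (rr + 0.5) * grid.cellsize
    return pd.DataFrame({"x": x, "y": y, "row": rr, "col": cc})


# ---------------------------------------------------------------------------
# Validation data
# ---------------------------------------------------------------------------


def simulate_validation_data(
    true_suit: TrueSuitability,
    links,
    cfg: SimulationConfig,
    respondents_per_site: int = 5,
    transect_spacing_km: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate the two field validation datasets.

    Transects: one centroid per ``transect_spacing_km`` grid cell, Bernoulli
    presence with p = true suitability at the centroid. Reports: per corridor
    link, ``respondents_per_site`` interviewees whose sighting counts are
    Poisson with a mean that decreases with the link's mean per-km resistance
    (``cwd_lcp_ratio``); the costliest link (highest CWD:EUD ratio) is forced
    to zero reports, creating one known-inactive corridor.
    """
    grid = true_suit.grid
    stride = max(1, int(round(transect_spacing_km / grid.cellsize)))
    trng = _rng(cfg.seed, "transects")
    recs = []
    for r in range(stride // 2, grid.nrows, stride):
        for c in range(stride // 2, grid.ncols, stride):
            p = float(grid.values[r, c])
            x, y = grid.cell_center(r, c)
            recs.append(
                {
                    "transect_id": len(recs) + 1,
                    "x": x,
                    "y": y,
                    "presence": int(trng.random() < p),
                }
            )
    transects = pd.DataFrame(recs)

    rrng = _rng(cfg.seed, "reports")
    reachable = [lk for lk in links if np.isfinite(lk.lcp_cost)]
    if reachable:
        silent = max(range(len(reachable)), key=lambda i: reachable[i].cwd_eud_ratio)
    rows = []
    seasons = ["Wet", "Dry", "Wet and Dry"]
    for i, lk in enumerate(reachable):
        # per-km resistance in [1, 100] -> mean sightings roughly 20 down to ~2
        mean = 20.0 * math.exp(-(lk.cwd_lcp_ratio - 1.0) / 40.0)
        for resp in range(respondents_per_site):
            count = 0 if i == silent else int(rrng.poisson(mean))
            rows.append(
                {
                    "site": f"site_{lk.pa_from}_{lk.pa_to}",
                    "pa_from": lk.pa_from,
                    "pa_to": lk.pa_to,
                    "respondent": resp + 1,
                    "sightings": count,
                    "season": "-" if i == silent else seasons[int(rrng.integers(len(seasons)))],
                }
            )
    reports = pd.DataFrame(rows)
    return transects, reports
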