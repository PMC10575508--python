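"""Suitability-to-resistance transformation and least-cost corridor extraction.

Landscape resistance is derived from habitat suitability h in [0, 1] with the
negative-exponential transform

    R = 100 - 99 * (1 - exp(-c * h)) / (1 - exp(-c)),

so R(1) = 1 and R(0) = 100 for every shape factor c > 0; c = 0.25 gives the
approximately linear curve used by default, with {2, 1, 0.5, 0.25} the
candidate set.

Cost-weighted distance (CWD) is the multi-source shortest-path cost over the
8-connected grid with edge cost cellsize * d * (R_i + R_j) / 2 (d = 1 cardinal,
sqrt(2) diagonal), accumulated in cost-weighted km (cw-km). For a pair of
protected areas (PAs) the least-cost path (LCP) yields the corridor metrics:
CWD:EUD (cost over straight-line separation) and CWD:LCP (mean resistance per
km along the optimal route; 1 is the high-quality limit). The normalized
corridor CWD_A + CWD_B - LCP cost, truncated at a cw-km cutoff (default 200),
delimits the corridor swath.

Shortest paths use a bespoke binary-heap Dijkstra with (cost, row, col) keys,
so equal-cost ties resolve deterministically toward lower row, then lower
column.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from corridorscape.raster import RasterGrid
from corridorscape.sdm import SuitabilitySurface

__all__ = [
    "ResistanceParams",
    "ResistanceSurface",
    "CorridorLink",
    "suitability_to_resistance",
    "cost_weighted_distance",
    "least_cost_path",
    "normalized_corridor",
    "pa_euclidean_distance",
    "build_link_table",
]

_SQRT2 = math.sqrt(2.0)
_NEIGHBORS = [
    (-1, -1, _SQRT2), (-1, 0, 1.0), (-1, 1, _SQRT2),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, _SQRT2), (1, 0, 1.0), (1, 1, _SQRT2),
]


@dataclass
class ResistanceParams:
    """Shape factor of the suitability-to-resistance curve."""

    c: float = 0.25
    candidates: tuple[float, ...] = (2.0, 1.0, 0.5, 0.25)

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"shape factor c must be > 0, got {self.c}")


@dataclass
class ResistanceSurface:
    """Per-cell movement cost in [1, 100], strictly decreasing in suitability."""

    grid: RasterGrid
    params: ResistanceParams
    suitability: RasterGrid | None = None


@dataclass
class CorridorLink:
    """One PA pair: least-cost metrics, corridor swath, and (once the circuit
    stage has run) current map and centrality."""

    pa_from: str
    pa_to: str
    lcp_cost: float  # cw-km
    lcp_length: float  # km
    euclid_dist: float  # km
    cwd_eud_ratio: float
    cwd_lcp_ratio: float
    corridor_mask: RasterGrid | None = None
    path: list[tuple[int, int]] = field(default_factory=list)
    reachable: bool = True
    centrality: float = float("nan")
    current_map: RasterGrid | None = None
    current_mean: float = float("nan")
    current_max: float = float("nan")


def suitability_to_resistance(
    h: SuitabilitySurface | RasterGrid, params: ResistanceParams | None = None
) -> ResistanceSurface:
    """Apply R = 100 - 99*(1 - exp(-c*h))/(1 - exp(-c)) cellwise.

    ``h`` must lie in [0, 1] on valid cells; nodata is propagated.
    """
    if params is None:
        params = ResistanceParams()
    grid = h.grid if isinstance(h, SuitabilitySurface) else h
    valid = grid.valid_mask()
    vals = grid.values
    bad = valid & ((vals < 0) | (vals > 1))
    if bad.any():
        rows, cols = np.nonzero(bad)
        sample = list(zip(rows[:5].tolist(), cols[:5].tolist()))
        raise ValueError(
            f"suitability outside [0, 1] at {bad.sum()} cells, e.g. {sample}"
        )
    c = params.c
    out = np.full(grid.shape, grid.nodata)
    out[valid] = 100.0 - 99.0 * (1.0 - np.exp(-c * vals[valid])) / (1.0 - math.exp(-c))
    return ResistanceSurface(grid=grid.copy_with(out), params=params, suitability=grid)


# ---------------------------------------------------------------------------
# Dijkstra over the 8-connected grid
# ---------------------------------------------------------------------------


def _dijkstra(
    res: RasterGrid, source_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source Dijkstra. Returns (cost array, predecessor array).

    Predecessors are encoded as flat indices (row*ncols+col), -1 for source
    or unreached cells. Heap keys are (cost, row, col): at equal cost the
    lower-(row, col) cell is settled first, making path reconstruction
    deterministic.
    """
    nrows, ncols = res.shape
    valid = res.valid_mask()
    R = res.values
    cs = res.cellsize
    src = (source_mask > 0) & valid
    if not src.any():
        raise ValueError("no source cells on valid (non-nodata) resistance cells")
    dist = np.full((nrows, ncols), np.inf)
    pred = np.full((nrows, ncols), -1, dtype=np.int64)
    done = np.zeros((nrows, ncols), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r, c in zip(*np.nonzero(src)):
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, int(r), int(c)))
    while heap:
        d, r, c = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        base = R[r, c]
        for dr, dc, w in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and not done[nr, nc] and valid[nr, nc]:
                nd = d + cs * w * (base + R[nr, nc]) / 2.0
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    pred[nr, nc] = r * ncols + c
                    heapq.heappush(heap, (nd, nr, nc))
    return dist, pred


def cost_weighted_distance(res: ResistanceSurface, sources: RasterGrid) -> RasterGrid:
    """CWD surface (cw-km) from the source set; unreachable cells are +inf,
    nodata cells keep the nodata sentinel."""
    dist, _ = _dijkstra(res.grid, sources.values)
    out = dist.copy()
    out[~res.grid.valid_mask()] = res.grid.nodata
    return res.grid.copy_with(out)


def _touching(src: np.ndarray, dst: np.ndarray) -> bool:
    """True when the masks overlap or are 8-adjacent."""
    from scipy.ndimage import binary_dilation

    return bool((binary_dilation(src, structure=np.ones((3, 3))) & dst).any())


def least_cost_path(
    res: ResistanceSurface, src_mask: RasterGrid, dst_mask: RasterGrid
) -> tuple[list[tuple[int, int]], float, float]:
    """Minimum-cost path between two cell sets.

    Returns (cell sequence from source to destination, lcp cost in cw-km,
    geometric path length in km). Overlapping or 8-adjacent masks yield cost
    0 with an empty interior path; an unreachable destination yields an empty
    path with infinite cost.
    """
    src = src_mask.values > 0
    dst = dst_mask.values > 0
    if not src.any() or not dst.any():
        raise ValueError("both masks must be non-empty")
    if _touching(src, dst):
        return [], 0.0, 0.0
    dist, pred = _dijkstra(res.grid, src_mask.values)
    drows, dcols = np.nonzero(dst)
    costs = dist[drows, dcols]
    if not np.isfinite(costs).any():
        return [], float("inf"), float("inf")
    # destination with minimal cost; ties resolve to the lowest (row, col)
    order = np.lexsort((dcols, drows, costs))
    best = order[0]
    r, c = int(drows[best]), int(dcols[best])
    lcp_cost = float(costs[best])
    path = [(r, c)]
    ncols = res.grid.ncols
    length = 0.0
    while pred[r, c] >= 0:
        pr, pc = divmod(int(pred[r, c]), ncols)
        step = _SQRT2 if (pr != r and pc != c) else 1.0
        length += step * res.grid.cellsize
        r, c = pr, pc
        path.append((r, c))
    path.reverse()
    return path, lcp_cost, length


def normalized_corridor(
    cwd_a: RasterGrid, cwd_b: RasterGrid, lcp_cost: float, cutoff: float = 200.0
) -> tuple[RasterGrid, RasterGrid]:
    """Normalized least-cost corridor and its truncation.

    Corridor value per cell = CWD_A + CWD_B - lcp_cost (0 on the optimal
    path); the mask keeps cells with value <= cutoff. Returns (corridor
    value grid, binary mask grid).
    """
    if not cwd_a.aligned_with(cwd_b):
        raise ValueError("CWD grids are not aligned")
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if not np.isfinite(lcp_cost):
        warnings.warn("least-cost path unreachable; corridor mask is empty", stacklevel=2)
        empty = np.zeros(cwd_a.shape)
        return cwd_a.copy_with(np.full(cwd_a.shape, np.inf)), cwd_a.copy_with(empty)
    valid = cwd_a.valid_mask() & cwd_b.valid_mask()
    value = np.full(cwd_a.shape, np.inf)
    value[valid] = cwd_a.values[valid] + cwd_b.values[valid] - lcp_cost
    mask = (value <= cutoff + 1e-9).astype(float)
    return cwd_a.copy_with(value), cwd_a.copy_with(mask)


def pa_euclidean_distance(pa_a: RasterGrid, pa_b: RasterGrid) -> float:
    """Minimum center-to-center distance (km) between cells of two PA masks."""
    a = np.column_stack(np.nonzero(pa_a.values > 0)).astype(float)
    b = np.column_stack(np.nonzero(pa_b.values > 0)).astype(float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both PA masks must be non-empty")
    overlap = (pa_a.values > 0) & (pa_b.values > 0)
    if overlap.any():
        warnings.warn("PA masks overlap; Euclidean distance is 0", stacklevel=2)
        return 0.0
    tree = cKDTree(b)
    d, _ = tree.query(a)
    return float(d.min() * pa_a.cellsize)


def build_link_table(
    pas: list[RasterGrid],
    res: ResistanceSurface,
    pairs: list[tuple[int, int]] | None = None,
    cutoff: float = 200.0,
    names: list[str] | None = None,
) -> list[CorridorLink]:
    """Assemble one :class:`CorridorLink` per PA pair.

    CWD surfaces are computed once per PA and reused across pairs. The
    default pair list is all unordered pairs; unreachable pairs are flagged
    and carry no ratios. Centrality and current maps are filled by the
    circuit stage.
    """
    if len(pas) < 2:
        raise ValueError("need at least 2 PAs")
    if names is None:
        names = [f"PA{i + 1}" for i in range(len(pas))]
    if pairs is None:
        pairs = [(i, j) for i in range(len(pas)) for j in range(i + 1, len(pas))]
    needed = sorted({i for p in pairs for i in p})
    cwd: dict[int, RasterGrid] = {i: cost_weighted_distance(res, pas[i]) for i in needed}

    links: list[CorridorLink] = []
    for i, j in pairs:
        path, lcp_cost, lcp_length = least_cost_path(res, pas[i], pas[j])
        eud = pa_euclidean_distance(pas[i], pas[j])
        if not np.isfinite(lcp_cost):
            links.append(
                CorridorLink(
                    pa_from=names[i], pa_to=names[j],
                    lcp_cost=float("inf"), lcp_length=float("inf"), euclid_dist=eud,
                    cwd_eud_ratio=float("nan"), cwd_lcp_ratio=float("nan"),
                    reachable=False,
                )
            )
            continue
        _, mask = normalized_corridor(cwd[i], cwd[j], lcp_cost, cutoff)
        links.append(
            CorridorLink(
                pa_from=names[i], pa_to=names[j],
                lcp_cost=lcp_cost, lcp_length=lcp_length, euclid_dist=eud,
                cwd_eud_ratio=lcp_cost / eud if eud > 0 else float("nan"),
                cwd_lcp_ratio=lcp_cost / lcp_length if lcp_length > 0 else float("nan"),
                corridor_mask=mask, path=path,
            )
        )
    return links
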