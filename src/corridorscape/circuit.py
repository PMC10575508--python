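"""Circuit-theory connectivity: pinch points and link centrality.

The resistance raster is read as a resistor network: every valid cell is a
node, 8-neighbor cells are joined by a resistor of cellsize * d * (R_i+R_j)/2
(so conductance g = 1 / that), and each protected area is collapsed into a
single supernode by exact node contraction of its member cells (an ideal,
zero-internal-resistance region). Injecting 1 A at one PA supernode and grounding
another solves the Kirchhoff/Laplacian system; per-cell current density
(half the sum of absolute incident edge currents, in Amps/cell) highlights
pinch points — corridor constrictions where flow concentrates — and the
voltage drop gives the pair's effective resistance.

Link centrality is computed on the reduced PA network: each corridor link is
one resistor (resistance = its least-cost path cost), 1 A is injected across
every unordered PA pair in turn, and a link's centrality is the summed
absolute current it carries (Amps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from corridorscape.connectivity import CorridorLink, ResistanceSurface
from corridorscape.raster import RasterGrid

__all__ = [
    "ConductanceGraph",
    "CurrentMap",
    "build_conductance_graph",
    "solve_pair_current",
    "pinchpoint_maps",
    "link_centrality",
]

#: Relative residual tolerance for the linear solve.
RESIDUAL_TOL = 1e-8


@dataclass
class ConductanceGraph:
    """Sparse symmetric conductance matrix over domain cells + PA supernodes.

    Each PA's member cells are contracted exactly into the PA's supernode
    (ideal internal conductance), so nodes 0..n_cells-1 are the *free*
    (non-PA) domain cells in row-major order and node ``n_cells + k`` is the
    supernode of PA k. Parallel edges created by the contraction accumulate.
    """

    conductance: sp.csr_matrix
    cell_rows: np.ndarray
    cell_cols: np.ndarray
    n_cells: int
    n_pas: int
    template: RasterGrid


@dataclass
class CurrentMap:
    grid: RasterGrid  # per-cell current density (Amps/cell)
    src_pa: int
    dst_pa: int
    injection: float
    effective_resistance: float


def build_conductance_graph(
    res: ResistanceSurface,
    pas: list[RasterGrid],
    domain_mask: RasterGrid | np.ndarray | None = None,
) -> ConductanceGraph:
    """Build the resistor network over ``domain_mask`` (default: all valid
    cells). Every PA must intersect the domain."""
    grid = res.grid
    valid = grid.valid_mask()
    if domain_mask is not None:
        dm = domain_mask.values if isinstance(domain_mask, RasterGrid) else domain_mask
        valid = valid & (np.asarray(dm) > 0)
    for k, pa in enumerate(pas):
        if not ((pa.values > 0) & valid).any():
            raise ValueError(f"PA {k} has no cells inside the analysis domain")

    nrows, ncols = grid.shape
    n_pas = len(pas)
    # node assignment: PA member cells collapse onto their supernode
    pa_of = np.full((nrows, ncols), -1, dtype=np.int64)
    for k, pa in enumerate(pas):
        member = (pa.values > 0) & valid & (pa_of < 0)
        pa_of[member] = k
    free = valid & (pa_of < 0)
    cell_rows, cell_cols = np.nonzero(free)
    n_cells = cell_rows.size
    node = np.full((nrows, ncols), -1, dtype=np.int64)
    node[cell_rows, cell_cols] = np.arange(n_cells)
    node[pa_of >= 0] = n_cells + pa_of[pa_of >= 0]
    R = grid.values
    cs = grid.cellsize

    vrows, vcols = np.nonzero(valid)
    ii, jj, gg = [], [], []
    # east, southwest, south, southeast cover each undirected pair once
    for dr, dc, w in ((0, 1, 1.0), (1, -1, np.sqrt(2)), (1, 0, 1.0), (1, 1, np.sqrt(2))):
        r2 = vrows + dr
        c2 = vcols + dc
        ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
        ok[ok] = valid[r2[ok], c2[ok]]
        a = node[vrows[ok], vcols[ok]]
        b = node[r2[ok], c2[ok]]
        g = 1.0 / (cs * w * (R[vrows[ok], vcols[ok]] + R[r2[ok], c2[ok]]) / 2.0)
        internal = a == b  # both endpoints inside the same PA: no edge
        ii.append(a[~internal])
        jj.append(b[~internal])
        gg.append(g[~internal])
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    g = np.concatenate(gg)
    n = n_cells + n_pas
    G = sp.coo_matrix((np.concatenate([g, g]), (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n, n)).tocsr()
    G.sum_duplicates()
    return ConductanceGraph(
        conductance=G,
        cell_rows=cell_rows,
        cell_cols=cell_cols,
        n_cells=n_cells,
        n_pas=n_pas,
        template=grid,
    )


def solve_pair_current(
    graph: ConductanceGraph, src_pa: int, dst_pa: int, injection: float = 1.0
) -> CurrentMap:
    """Solve node potentials for ``injection`` Amps from src supernode to a
    grounded dst supernode; returns the per-cell current-density map and the
    pair's effective resistance."""
    G = graph.conductance
    n = G.shape[0]
    src = graph.n_cells + src_pa
    dst = graph.n_cells + dst_pa
    n_comp, labels = connected_components(G, directed=False)
    if labels[src] != labels[dst]:
        raise ValueError(f"PA {src_pa} and PA {dst_pa} are disconnected in the domain")

    deg = np.asarray(G.sum(axis=1)).ravel()
    L = sp.diags(deg) - G
    keep = np.ones(n, dtype=bool)
    keep[dst] = False
    # restrict to the pair's component so the reduced Laplacian is nonsingular
    keep &= labels == labels[src]
    idx = np.nonzero(keep)[0]
    L_red = L[np.ix_(idx, idx)].tocsc()
    b = np.zeros(idx.size)
    b[np.searchsorted(idx, src)] = injection
    # sparse LU with a few steps of iterative refinement; convergence judged
    # by the normwise backward error |r| / (|L||v| + |b|)
    lu = splu(L_red)
    v_red = lu.solve(b)
    scale = sp.linalg.norm(L_red, np.inf) * np.linalg.norm(v_red, np.inf) + np.linalg.norm(b)
    for _ in range(3):
        r = b - L_red @ v_red
        residual = np.linalg.norm(r) / max(scale, 1e-300)
        if residual <= RESIDUAL_TOL:
            break
        v_red = v_red + lu.solve(r)
    if residual > RESIDUAL_TOL:
        raise RuntimeError(f"linear solve residual {residual:.2e} above tolerance")
    v = np.zeros(n)
    v[idx] = v_red

    # per-cell density: half the sum of |edge currents| incident to the cell
    coo = sp.triu(G, k=1).tocoo()
    edge_cur = np.abs(coo.data * (v[coo.row] - v[coo.col]))
    density_nodes = np.zeros(n)
    np.add.at(density_nodes, coo.row, edge_cur)
    np.add.at(density_nodes, coo.col, edge_cur)
    density_nodes *= 0.5

    out = np.zeros(graph.template.shape)
    out[graph.cell_rows, graph.cell_cols] = density_nodes[: graph.n_cells]
    grid = RasterGrid(
        out,
        cellsize=graph.template.cellsize,
        origin=graph.template.origin,
        nodata=graph.template.nodata,
    )
    return CurrentMap(
        grid=grid,
        src_pa=src_pa,
        dst_pa=dst_pa,
        injection=injection,
        effective_resistance=float((v[src] - v[dst]) / injection),
    )


def pinchpoint_maps(
    links: list[CorridorLink],
    res: ResistanceSurface,
    pas: list[RasterGrid],
    names: list[str] | None = None,
    injection: float = 1.0,
) -> list[CorridorLink]:
    """Fill each reachable link's current map by solving the pair's circuit
    restricted to its truncated corridor (plus both PA masks); summary mean
    and max densities are taken over corridor cells."""
    if names is None:
        names = [f"PA{i + 1}" for i in range(len(pas))]
    name_to_idx = {n: i for i, n in enumerate(names)}
    for link in links:
        if not link.reachable or link.corridor_mask is None:
            continue
        i, j = name_to_idx[link.pa_from], name_to_idx[link.pa_to]
        domain = (link.corridor_mask.values > 0) | (pas[i].values > 0) | (pas[j].values > 0)
        try:
            graph = build_conductance_graph(res, [pas[i], pas[j]], domain_mask=domain)
            cm = solve_pair_current(graph, 0, 1, injection)
        except ValueError as exc:
            warnings.warn(
                f"link {link.pa_from}-{link.pa_to}: corridor domain unsolvable ({exc})",
                stacklevel=2,
            )
            continue
        link.current_map = cm.grid
        in_corridor = link.corridor_mask.values > 0
        dens = cm.grid.values[in_corridor]
        link.current_mean = float(dens.mean())
        link.current_max = float(dens.max())
    return links


def link_centrality(links: list[CorridorLink]) -> list[CorridorLink]:
    """Current-flow centrality of every link on the reduced PA network.

    PAs are nodes; each reachable link is a resistor of resistance
    ``lcp_cost``. For every unordered PA pair, 1 A is injected at one node
    and drained at the other; a link's centrality is the sum over all pairs
    of the absolute current it carries. On a disconnected PA graph the pairs
    of each component are solved separately (with a warning).
    """
    usable = [lk for lk in links if lk.reachable and lk.lcp_cost > 0]
    if len(usable) < 1:
        raise ValueError("centrality needs at least one reachable link with positive cost")
    pa_names = sorted({lk.pa_from for lk in usable} | {lk.pa_to for lk in usable})
    n = len(pa_names)
    idx = {name: i for i, name in enumerate(pa_names)}
    G = np.zeros((n, n))
    for lk in usable:
        g = 1.0 / lk.lcp_cost
        a, b = idx[lk.pa_from], idx[lk.pa_to]
        G[a, b] += g
        G[b, a] += g
    L = np.diag(G.sum(axis=1)) - G
    comp_of = _components(G)
    if len(set(comp_of)) > 1:
        warnings.warn("PA link graph is disconnected; centrality computed per component",
                      stacklevel=2)
    # Moore-Penrose pseudoinverse handles each component's singular Laplacian
    Linv = np.linalg.pinv(L)
    for lk in usable:
        lk.centrality = 0.0
    for a, b in combinations(range(n), 2):
        if comp_of[a] != comp_of[b]:
            continue
        e = np.zeros(n)
        e[a], e[b] = 1.0, -1.0
        v = Linv @ e
        for lk in usable:
            i, j = idx[lk.pa_from], idx[lk.pa_to]
            lk.centrality += abs((v[i] - v[j]) / lk.lcp_cost)
    return links


def _components(G: np.ndarray) -> list[int]:
    n = G.shape[0]
    comp = [-1] * n
    cur = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = cur
        while stack:
            u = stack.pop()
            for w in np.nonzero(G[u] > 0)[0]:
                if comp[w] < 0:
                    comp[w] = cur
                    stack.append(int(w))
        cur += 1
    return comp
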