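"""Surrogate data layers used in place of genetic data.

Three surrogate layers are computed:

* long-term environmental suitability per site — the harmonic mean of
  contemporary and historical suitability at the site's cell.  The harmonic
  mean penalizes sites whose suitability fluctuated through time, so stable
  refugial sites score high;
* pairwise Euclidean geographic distances in the projected (metric)
  coordinate system;
* pairwise circuit-theory resistance distances over a conductance graph
  derived from the contemporary suitability raster.  Suitability is clamped
  to 1e-5 before inversion, cells become graph nodes with conductance equal
  to clamped suitability, and the effective resistance between two focal
  cells is the voltage drop per unit current injected between them —
  computed from the graph Laplacian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu
from scipy.spatial.distance import pdist, squareform

from .containers import (
    DistanceMatrix,
    GensurrError,
    RasterStack,
    ScoreVector,
    SiteTable,
)

SUITABILITY_FLOOR = 1e-6  # inside the harmonic mean, to keep 1/s finite
RESISTANCE_CLAMP = 1e-5  # suitability clamp before inversion


def longterm_suitability(stack: RasterStack, sites: SiteTable) -> ScoreVector:
    """Harmonic mean of suitability across all periods at each site's cell.

    score(site) = P / sum_t 1/s_t over the P periods, with s_t floored at
    1e-6; a near-zero suitability in any single period pins the score near
    zero, which is exactly the penalty the harmonic mean is chosen for.
    """
    values = {}
    for site_id, x, y in zip(sites.ids, sites.coords[:, 0], sites.coords[:, 1]):
        row, col = stack.cell_of(x, y)
        series = stack.values[:, row, col]
        bad = np.isnan(series)
        if bad.any():
            periods = [stack.periods[p] for p in np.flatnonzero(bad)]
            raise GensurrError(
                f"site {site_id!r} falls on NODATA in period(s) {periods}"
            )
        floored = np.maximum(series, SUITABILITY_FLOOR)
        values[site_id] = len(floored) / np.sum(1.0 / floored)
    return ScoreVector(pd.Series(values, index=sites.ids), "longterm_suitability")


def geographic_distances(sites: SiteTable) -> DistanceMatrix:
    """Pairwise Euclidean distances between site coordinates (meters)."""
    coords = sites.coords
    if not np.isfinite(coords).all():
        raise GensurrError("NaN/inf site coordinates")
    dist = squareform(pdist(coords))
    off_diag = dist[~np.eye(len(coords), dtype=bool)]
    if len(coords) > 1 and (off_diag == 0).any():
        warnings.warn("duplicate site coordinates (zero geographic distance)",
                      stacklevel=2)
    return DistanceMatrix(tuple(sites.ids), dist, "geographic")


@dataclass(frozen=True)
class ConductanceGraph:
    """Resistor network over raster cells with site-to-node mapping.

    Nodes are the non-NODATA cells of the contemporary raster; undirected
    edges connect neighboring cells with conductance = mean of the two cell
    conductances (diagonal edges divided by sqrt(2) to correct for length).
    """

    laplacian: sparse.csr_matrix  # weighted graph Laplacian (conductances)
    focal_nodes: dict[str, int]  # site ID -> node index

    @property
    def n_nodes(self) -> int:
        return self.laplacian.shape[0]


def build_conductance_graph(
    contemporary: np.ndarray,
    sites: SiteTable,
    stack: RasterStack | None = None,
    clamp: float = RESISTANCE_CLAMP,
    connectivity: int = 8,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
) -> ConductanceGraph:
    """Build the resistor network from a contemporary suitability grid.

    Cell conductance is ``max(suitability, clamp)`` (so cell resistance is
    the clamped inverse suitability).  ``connectivity`` is 4 (rook) or 8
    (queen, the Circuitscape-style default).  When ``stack`` is given its
    georeference overrides the explicit corner/cellsize arguments.
    """
    if clamp <= 0:
        raise GensurrError("clamp must be positive")
    if connectivity not in (4, 8):
        raise GensurrError("connectivity must be 4 or 8")
    grid = np.asarray(contemporary, dtype=float)
    if stack is not None:
        xllcorner, yllcorner, cellsize = stack.xllcorner, stack.yllcorner, stack.cellsize
    nrows, ncols = grid.shape
    valid = ~np.isnan(grid)
    node_of = -np.ones((nrows, ncols), dtype=np.int64)
    node_of[valid] = np.arange(valid.sum())
    conduct = np.maximum(grid, clamp)

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    rows_idx, cols_idx, weights = [], [], []
    for dr, dc in offsets:
        # pair cell (r, c) with (r + dr, c + dc); both windows stay in-grid
        a = (slice(0, nrows - dr), slice(max(0, -dc), ncols - max(0, dc)))
        b = (slice(dr, nrows), slice(max(0, dc), ncols + min(0, dc)))
        na, nb = node_of[a], node_of[b]
        ca, cb = conduct[a], conduct[b]
        ok = (na >= 0) & (nb >= 0)
        w = (ca[ok] + cb[ok]) / 2.0
        if dr != 0 and dc != 0:
            w = w / np.sqrt(2.0)
        rows_idx.append(na[ok])
        cols_idx.append(nb[ok])
        weights.append(w)
    i = np.concatenate(rows_idx)
    j = np.concatenate(cols_idx)
    w = np.concatenate(weights)
    n = int(valid.sum())
    adj = sparse.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
    adj = adj.tocsr()
    lap = sparse.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj

    focal: dict[str, int] = {}
    for site_id, x, y in zip(sites.ids, sites.coords[:, 0], sites.coords[:, 1]):
        col = int(np.floor((x - xllcorner) / cellsize))
        row = nrows - 1 - int(np.floor((y - yllcorner) / cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols) or node_of[row, col] < 0:
            raise GensurrError(f"site {site_id!r} falls outside the valid raster")
        focal[site_id] = int(node_of[row, col])

    # all focal nodes must be mutually reachable
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    focal_labels = {s: labels[nd] for s, nd in focal.items()}
    unique = set(focal_labels.values())
    if len(unique) > 1:
        by_comp: dict[int, list[str]] = {}
        for s, lab in focal_labels.items():
            by_comp.setdefault(lab, []).append(s)
        groups = sorted(by_comp.values(), key=len, reverse=True)
        raise GensurrError(
            f"focal sites are disconnected: e.g. {groups[0][0]!r} cannot reach "
            f"{groups[1][0]!r}"
        )
    # restrict to the component holding the focal nodes so the grounded
    # Laplacian is non-singular even if the raster has other islands
    if n_comp > 1:
        comp = next(iter(unique))
        keep = np.flatnonzero(labels == comp)
        remap = -np.ones(n, dtype=np.int64)
        remap[keep] = np.arange(keep.size)
        lap = lap[keep][:, keep].tocsr()
        focal = {s: int(remap[nd]) for s, nd in focal.items()}
    return ConductanceGraph(laplacian=lap.tocsr(), focal_nodes=focal)


def resistance_distances(graph: ConductanceGraph) -> DistanceMatrix:
    """Effective resistance between every pair of focal nodes.

    With the graph Laplacian L, the effective resistance is
    R_ij = (e_i - e_j)^T L+ (e_i - e_j).  One node is grounded, the reduced
    system is factorized once, and one solve per focal node yields the
    grounded inverse entries from which all pairwise resistances follow.
    """
    site_ids = list(graph.focal_nodes)
    nodes = np.array([graph.focal_nodes[s] for s in site_ids], dtype=np.int64)
    n = graph.n_nodes
    if n < 2 or len(site_ids) < 1:
        raise GensurrError("resistance needs at least two graph nodes")
    ground = int(nodes[0])
    keep = np.concatenate([np.arange(ground), np.arange(ground + 1, n)])
    reduced = graph.laplacian[keep][:, keep].tocsc()
    try:
        solver = splu(reduced)
    except RuntimeError as exc:  # pragma: no cover - guarded by build step
        raise GensurrError(f"singular resistance system: {exc}") from exc

    def reduced_index(node: int) -> int:
        return node if node < ground else node - 1

    # potentials[s][t] = (L_grounded^-1)_{node_s, node_t}; ground row/col = 0
    m = len(site_ids)
    ginv = np.zeros((m, m))
    non_ground = [i for i, nd in enumerate(nodes) if nd != ground]
    for a in non_ground:
        rhs = np.zeros(n - 1)
        rhs[reduced_index(int(nodes[a]))] = 1.0
        x = solver.solve(rhs)
        for b in non_ground:
            ginv[a, b] = x[reduced_index(int(nodes[b]))]
    res = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            res[a, b] = ginv[a, a] + ginv[b, b] - ginv[a, b] - ginv[b, a]
    res = (res + res.T) / 2.0
    return DistanceMatrix(tuple(site_ids), res, "resistance")


def resistance_from_stack(
    stack: RasterStack,
    sites: SiteTable,
    clamp: float = RESISTANCE_CLAMP,
    connectivity: int = 8,
) -> DistanceMatrix:
    """Convenience wrapper: contemporary layer -> graph -> resistances."""
    graph = build_conductance_graph(
        stack.contemporary, sites, stack=stack, clamp=clamp, connectivity=connectivity
    )
    return resistance_distances(graph)
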