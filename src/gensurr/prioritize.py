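"""Generate prioritizations: rank-based, optimal distance-based, and random.

The distance-based ("environmental diversity") reserve-selection problem is
treated as the discrete p-median on the site-by-site distance matrix: pick
k sites minimizing the summed distance from every site to its nearest
selected site.  The exact solver uses the standard p-median integer program
(binary open/assignment variables) solved with HiGHS at a zero optimality
gap; a brute-force enumerator over all k-subsets serves as an independent
exact method for small instances.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .containers import DistanceMatrix, GensurrError, PrioritizationSeries, ScoreVector

BRUTE_FORCE_LIMIT = 500_000  # max C(n, k) for the enumeration cross-check


def rank_series(scores: ScoreVector, species: str = "species") -> PrioritizationSeries:
    """Nested top-k selections by descending score, ties to the lower site ID."""
    ser = scores.series
    if len(ser) == 0:
        raise GensurrError("empty score vector")
    order = sorted(ser.index, key=lambda s: (-ser[s], str(s)))
    selections = {k: frozenset(order[:k]) for k in range(1, len(order) + 1)}
    return PrioritizationSeries(
        species=species, method=f"{scores.metric}_rank", selections=selections
    )


def ed_objective(dist: DistanceMatrix, selected) -> float:
    """p-median objective: sum over all sites of distance to nearest selected."""
    selected = set(selected)
    if not selected:
        raise GensurrError("empty selection")
    unknown = selected - set(dist.sites)
    if unknown:
        raise GensurrError(f"selected sites not in distance matrix: {sorted(unknown)}")
    idx = [dist.sites.index(s) for s in selected]
    return float(dist.values[:, idx].min(axis=1).sum())


def solve_ed_brute(dist: DistanceMatrix, k: int) -> tuple[frozenset, float]:
    """Exhaustive enumeration over all k-subsets (exact, small n only)."""
    n = dist.n
    if not 1 <= k <= n:
        raise GensurrError(f"k={k} out of range 1..{n}")
    if comb(n, k) > BRUTE_FORCE_LIMIT:
        raise GensurrError(f"C({n},{k}) exceeds the brute-force limit")
    vals = dist.values
    best_obj = np.inf
    best: tuple[int, ...] | None = None
    for subset in combinations(range(n), k):
        obj = vals[:, subset].min(axis=1).sum()
        if obj < best_obj - 1e-12:
            best_obj = obj
            best = subset
    assert best is not None
    return frozenset(dist.sites[i] for i in best), float(best_obj)


def solve_ed_exact(dist: DistanceMatrix, k: int) -> tuple[frozenset, float]:
    """Certified-optimal k-site p-median selection via integer programming.

    Variables: y_j = 1 if site j is selected; x_ij = 1 if site i is assigned
    to selected site j.  Each site is assigned to exactly one open site,
    assignments require open sites, and exactly k sites open.  Solved with
    HiGHS at mip_rel_gap = 0, so the returned objective is a certified
    global optimum (any optimal set is valid; ties are solver-dependent).
    """
    n = dist.n
    if not 1 <= k <= n:
        raise GensurrError(f"k={k} out of range 1..{n}")
    if k == n:
        return frozenset(dist.sites), 0.0
    vals = dist.values
    cost = np.concatenate([np.zeros(n), vals.ravel()])  # y then x (row-major x_ij)
    n_var = n + n * n
    assign_once = sparse.hstack(
        [sparse.csr_matrix((n, n)), sparse.kron(sparse.eye(n), np.ones((1, n)))]
    )
    open_link = sparse.hstack(
        [-sparse.kron(np.ones((n, 1)), sparse.eye(n)), sparse.eye(n * n)]
    )
    cardinality = sparse.hstack(
        [sparse.csr_matrix(np.ones((1, n))), sparse.csr_matrix((1, n * n))]
    )
    constraints = [
        LinearConstraint(assign_once, 1, 1),
        LinearConstraint(open_link, -np.inf, 0),
        LinearConstraint(cardinality, k, k),
    ]
    res = milp(
        cost,
        constraints=constraints,
        integrality=np.ones(n_var),
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0:  # pragma: no cover - cannot occur for valid input
        raise GensurrError(f"MILP solver failed: {res.message}")
    opened = np.flatnonzero(np.round(res.x[:n]) == 1)
    selected = frozenset(dist.sites[int(i)] for i in opened)
    return selected, ed_objective(dist, selected)


def ed_series(
    dist: DistanceMatrix, species: str = "species", method: str | None = None
) -> PrioritizationSeries:
    """Optimal p-median selections for every k = 1..n."""
    method = method or f"{dist.metric}_ed"
    selections: dict[int, frozenset] = {}
    objectives: dict[int, float] = {}
    for k in range(1, dist.n + 1):
        sel, obj = solve_ed_exact(dist, k)
        selections[k] = sel
        objectives[k] = obj
    return PrioritizationSeries(
        species=species, method=method, selections=selections, objectives=objectives
    )


def random_series(
    site_ids, reps: int = 1000, seed: int = 0, species: str = "species"
) -> list[PrioritizationSeries]:
    """Seeded uniform-random k-subsets: ``reps`` independent series."""
    if reps < 1:
        raise GensurrError("reps must be >= 1")
    site_ids = [str(s) for s in site_ids]
    n = len(site_ids)
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(reps):
        selections = {
            k: frozenset(rng.choice(site_ids, size=k, replace=False))
            for k in range(1, n + 1)
        }
        out.append(
            PrioritizationSeries(
                species=species,
                method="random",
                selections=selections,
                replicate=rep,
                seed=seed,
            )
        )
    return out
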