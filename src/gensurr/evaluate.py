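"""Score prioritizations against genetic data and run association statistics.

Site-level performance is the proportion of high-diversity sites (allelic
richness at or above a percentile threshold) captured by a selection.
Broad-scale performance measures how much of the pairwise genetic-distance
space a selection spans: 1 - A/B where A is the p-median objective of the
selection on the genetic distance matrix and B is the mean single-site
objective (the expected objective of a random single-site prioritization);
negative values are clamped to 0.

Association statistics mirror standard landscape-genetics practice: a
one-sided Spearman rank test for a positive association between allelic
richness and long-term suitability, and maximum-likelihood population
effects (MLPE) regression of pairwise genetic distances on geographic or
resistance distances, with the R2_beta fixed-effect summary.
"""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

from .containers import (
    DistanceMatrix,
    GensurrError,
    MLPEFit,
    PrioritizationSeries,
    ScoreVector,
)
from .prioritize import ed_objective

# ---------------------------------------------------------------------------
# site-level performance


def high_diversity_sites(scores: ScoreVector, percentile: float = 80.0) -> frozenset:
    """Sites scoring at or above the given percentile of the score distribution.

    The percentile is computed by linear interpolation of order statistics
    (numpy's default); the comparison is ``>=`` so the top-scoring site is
    always included and the set is never empty.
    """
    ser = scores.series
    if len(ser) < 2:
        raise GensurrError("need at least two sites for a percentile threshold")
    threshold = float(np.percentile(ser.to_numpy(), percentile, method="linear"))
    return frozenset(str(s) for s in ser.index[ser >= threshold])


def site_capture_performance(selected, high) -> float:
    """Proportion of high-diversity sites contained in the selection."""
    high = set(high)
    if not high:
        raise GensurrError("empty high-diversity set")
    return len(set(selected) & high) / len(high)


# ---------------------------------------------------------------------------
# broad-scale performance


def broadscale_baseline(genetic: DistanceMatrix) -> float:
    """Mean single-site p-median objective: expected dispersion of a random
    single-site prioritization, the 0%-performance reference."""
    return float(genetic.values.sum(axis=0).mean())


def broadscale_performance(genetic: DistanceMatrix, selected) -> float:
    """Fraction of broad-scale genetic diversity secured by a selection.

    max(0, 1 - A/B) with A the selection's p-median objective on the genetic
    distances and B the mean single-site objective.  Full selections score 1;
    selections worse than the single-site average are clamped to 0 (akin to
    negative R^2 values).  Reports express this as a percentage.
    """
    baseline = broadscale_baseline(genetic)
    if baseline == 0.0:
        warnings.warn("all genetic distances are zero; performance defined as 1.0",
                      stacklevel=2)
        return 1.0
    return max(0.0, 1.0 - ed_objective(genetic, selected) / baseline)


# ---------------------------------------------------------------------------
# performance curves (tidy frames: species, method, threshold, k, replicate,
# performance; replicate -1 for deterministic methods)

CURVE_COLUMNS = ["species", "method", "threshold", "k", "replicate", "performance"]


def capture_curves(
    series_list: list[PrioritizationSeries], high, threshold_label: str = "p80"
) -> pd.DataFrame:
    rows = []
    for series in series_list:
        rep = -1 if series.replicate is None else series.replicate
        for k in series.ks:
            rows.append(
                (
                    series.species,
                    series.method,
                    threshold_label,
                    k,
                    rep,
                    site_capture_performance(series.selections[k], high),
                )
            )
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def broadscale_curves(
    series_list: list[PrioritizationSeries], genetic: DistanceMatrix
) -> pd.DataFrame:
    baseline = broadscale_baseline(genetic)
    vals = genetic.values
    index = {s: i for i, s in enumerate(genetic.sites)}
    rows = []
    for series in series_list:
        rep = -1 if series.replicate is None else series.replicate
        for k in series.ks:
            idx = [index[s] for s in series.selections[k]]
            raw = vals[:, idx].min(axis=1).sum()
            perf = 1.0 if baseline == 0 else max(0.0, 1.0 - raw / baseline)
            rows.append((series.species, series.method, "broadscale", k, rep, perf))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


# ---------------------------------------------------------------------------
# surrogate summaries


def surrogate_summary(
    curves: pd.DataFrame,
    reference_method: str,
    random_method: str = "random",
    k_window: tuple[float, float] = (0.0, 0.25),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Summarize surrogate performance against the genetic-data reference.

    For every non-random method, per species and k: (i) performance relative
    to the reference method (surrogate / reference, as a percentage) and
    (ii) improvement over the random-replicate mean at the same k (in
    percentage points).  Means and SDs are reported over all k and over the
    realistic window (k/n within ``k_window``), pooled across species, with
    seeded bootstrap 95% CIs over the pooled per-k values.
    """
    rng = np.random.default_rng(seed)
    required = set(CURVE_COLUMNS)
    if not required.issubset(curves.columns):
        raise GensurrError(f"curves frame needs columns {sorted(required)}")
    out_rows = []
    methods = [
        m for m in curves["method"].unique() if m not in (random_method,)
    ]
    per_method_vals: dict[str, pd.DataFrame] = {}
    for species, group in curves.groupby("species"):
        ref = group[group["method"] == reference_method]
        if ref.empty:
            raise GensurrError(f"no reference curve for species {species!r}")
        ref_by_k = ref.set_index("k")["performance"]
        rand = group[group["method"] == random_method]
        rand_by_k = rand.groupby("k")["performance"].mean()
        n_sites = int(group["k"].max())
        for method in methods:
            cur = group[group["method"] == method]
            if cur.empty:
                continue
            cur_by_k = cur.groupby("k")["performance"].mean()
            if set(cur_by_k.index) != set(ref_by_k.index):
                raise GensurrError(
                    f"mismatched k grids for {method!r} vs {reference_method!r}"
                )
            frame = pd.DataFrame(
                {
                    "species": species,
                    "k": cur_by_k.index,
                    "frac": cur_by_k.index / n_sites,
                    "performance": cur_by_k.to_numpy(),
                    "reference": ref_by_k.reindex(cur_by_k.index).to_numpy(),
                    "random_mean": rand_by_k.reindex(cur_by_k.index).to_numpy(),
                }
            )
            per_method_vals.setdefault(method, pd.DataFrame())
            per_method_vals[method] = pd.concat(
                [per_method_vals[method], frame], ignore_index=True
            )

    def _boot_ci(values: np.ndarray) -> tuple[float, float]:
        if len(values) == 0:
            return np.nan, np.nan
        idx = rng.integers(0, len(values), size=(n_boot, len(values)))
        means = values[idx].mean(axis=1)
        return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))

    for method, frame in per_method_vals.items():
        for window, sub in (
            ("all", frame),
            (
                "realistic",
                frame[(frame["frac"] >= k_window[0]) & (frame["frac"] <= k_window[1])],
            ),
        ):
            ok = sub["reference"] > 1e-12
            relative = 100.0 * sub.loc[ok, "performance"] / sub.loc[ok, "reference"]
            improvement = 100.0 * (sub["performance"] - sub["random_mean"])
            rel_ci = _boot_ci(relative.to_numpy())
            imp_ci = _boot_ci(improvement.to_numpy())
            out_rows.append(
                {
                    "method": method,
                    "window": window,
                    "n_k": len(sub),
                    "relative_mean_pct": float(relative.mean()) if len(relative) else np.nan,
                    "relative_sd_pct": float(relative.std(ddof=1)) if len(relative) > 1 else np.nan,
                    "relative_ci_low": rel_ci[0],
                    "relative_ci_high": rel_ci[1],
                    "improvement_mean_pct": float(improvement.mean()) if len(improvement) else np.nan,
                    "improvement_sd_pct": float(improvement.std(ddof=1)) if len(improvement) > 1 else np.nan,
                    "improvement_ci_low": imp_ci[0],
                    "improvement_ci_high": imp_ci[1],
                }
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# association statistics


def spearman_onesided(x: ScoreVector, y: ScoreVector) -> tuple[float, float]:
    """One-sided Spearman rank test for a positive association (H1: rho > 0).

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    The p-value is exact (full permutation enumeration) for n <= 9 and the
    usual t-approximation with n - 2 degrees of freedom otherwise.
    """
    if set(x.sites) != set(y.sites):
        raise GensurrError("score vectors cover different sites")
    xv = x.series.to_numpy(dtype=float)
    yv = y.series.reindex(x.series.index).to_numpy(dtype=float)
    n = len(xv)
    if n < 4:
        raise GensurrError("need at least 4 sites for a Spearman test")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise GensurrError("constant score vector: rho undefined")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if r >= rho - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(stats.t.sf(t, df=n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# MLPE regression on pairwise distances


def _pairwise_vectors(
    response: DistanceMatrix, predictor: DistanceMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if set(response.sites) != set(predictor.sites):
        raise GensurrError("response and predictor cover different sites")
    order = list(response.sites)
    pred = predictor.submatrix(order)
    n = len(order)
    iu = np.triu_indices(n, k=1)
    y = response.values[iu]
    x = pred.values[iu]
    m = len(y)
    incidence = np.zeros((m, n))
    incidence[np.arange(m), iu[0]] = 1.0
    incidence[np.arange(m), iu[1]] = 1.0
    return y, x, incidence


def mlpe_fit(
    response: DistanceMatrix,
    predictor: DistanceMatrix,
    standardize: bool = True,
) -> MLPEFit:
    """Fit the MLPE model y_ij = b0 + b1 x_ij + u_i + u_j + e_ij by ML.

    Every pairwise observation shares a random effect with each pair
    containing one of its two populations, giving the marginal covariance
    V = sigma2_e I + sigma2_u Z Z' with Z the pair-membership incidence.
    The likelihood is profiled over the variance ratio phi = s2_u / s2_e
    (bounded [0, 1e3], Brent search); R2_beta is the Edwards et al.
    fixed-effect summary computed from the Wald F statistic of the slope.
    """
    y, x, incidence = _pairwise_vectors(response, predictor)
    n_sites = incidence.shape[1]
    m = len(y)
    if n_sites < 5:
        raise GensurrError("MLPE needs at least 5 sites (10 pairs)")
    if standardize:
        sd = x.std(ddof=0)
        if sd == 0:
            raise GensurrError("constant predictor cannot be standardized")
        x = (x - x.mean()) / sd
    design = np.column_stack([np.ones(m), x])

    # ZZ' is fixed: diagonalize once so each profile step is O(m^2)
    gram = incidence @ incidence.T
    eigvals, eigvecs = linalg.eigh(gram)
    yt = eigvecs.T @ y
    designt = eigvecs.T @ design

    def profile(phi: float):
        w = 1.0 / (1.0 + phi * eigvals)
        xtwx = designt.T @ (w[:, None] * designt)
        xtwy = designt.T @ (w * yt)
        beta = linalg.solve(xtwx, xtwy, assume_a="pos")
        resid = yt - designt @ beta
        rss = float(np.sum(w * resid**2))
        sigma2 = max(rss / m, 1e-300)
        logdet = float(np.sum(np.log1p(phi * eigvals)))
        loglik = -0.5 * (m * np.log(2 * np.pi * sigma2) + logdet + m)
        return loglik, beta, sigma2, xtwx

    res = minimize_scalar(
        lambda phi: -profile(phi)[0], bounds=(0.0, 1e3), method="bounded",
        options={"xatol": 1e-10},
    )
    phi = float(res.x)
    # the bounded search never evaluates the exact boundary; snap to 0 when
    # the boundary is at least as good (pure-residual model)
    if profile(0.0)[0] >= profile(phi)[0]:
        phi = 0.0
    loglik, beta, sigma2_e, xtwx = profile(phi)
    cov_beta = sigma2_e * linalg.inv(xtwx)
    slope_se = float(np.sqrt(max(cov_beta[1, 1], 0.0)))
    nu = m - design.shape[1]
    f_stat = (beta[1] / slope_se) ** 2 if slope_se > 0 else np.inf
    ratio = f_stat / nu
    r2_beta = float(ratio / (1.0 + ratio)) if np.isfinite(ratio) else 1.0
    return MLPEFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        sigma2_u=float(phi * sigma2_e),
        sigma2_e=float(sigma2_e),
        loglik=float(loglik),
        r2_beta=min(max(r2_beta, 0.0), 1.0),
        slope_se=slope_se,
        converged=bool(res.success),
        n_sites=n_sites,
        n_pairs=m,
    )
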