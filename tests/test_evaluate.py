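"""Performance metrics, surrogate summaries, Spearman test and MLPE."""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gensurr import (
    DistanceMatrix,
    GensurrError,
    ScoreVector,
    broadscale_performance,
    capture_curves,
    high_diversity_sites,
    mlpe_fit,
    rank_series,
    site_capture_performance,
    spearman_onesided,
    surrogate_summary,
)
from gensurr.evaluate import broadscale_baseline
from gensurr.prioritize import ed_objective, random_series

from conftest import random_distance_matrix


def scores(d: dict[str, float]) -> ScoreVector:
    return ScoreVector(pd.Series(d), "allelic_richness")


class TestHighDiversitySites:
    def test_all_equal_returns_everything(self):
        high = high_diversity_sites(scores({"A": 2.0, "B": 2.0, "C": 2.0}), 80)
        assert high == {"A", "B", "C"}

    def test_linear_interpolation_convention(self):
        # scores 1..10: the 80th percentile threshold is 8.2
        vec = scores({f"S{i}": float(i) for i in range(1, 11)})
        assert high_diversity_sites(vec, 80) == {"S9", "S10"}

    def test_threshold_nesting(self, rng):
        vec = scores({f"S{i}": float(v) for i, v in enumerate(rng.random(15))})
        p90 = high_diversity_sites(vec, 90)
        p70 = high_diversity_sites(vec, 70)
        assert p90 <= p70
        assert len(p90) >= 1


class TestSiteCapture:
    @pytest.mark.parametrize(
        "selected,high,expected",
        [
            ({"A", "B", "C"}, {"A", "B"}, 1.0),
            ({"C", "D"}, {"A", "B"}, 0.0),
            ({"A", "X", "Y"}, {"A", "B", "C", "D"}, 0.25),
        ],
    )
    def test_ratio(self, selected, high, expected):
        assert site_capture_performance(selected, high) == pytest.approx(expected)

    def test_empty_high_set_errors(self):
        with pytest.raises(GensurrError, match="empty"):
            site_capture_performance({"A"}, set())

    def test_rank_series_captures_all_when_k_reaches_high_count(self, rng):
        vec = scores({f"S{i}": float(v) for i, v in enumerate(rng.random(12))})
        high = high_diversity_sites(vec, 80)
        series = rank_series(vec)
        for k in range(len(high), 13):
            assert site_capture_performance(series.selections[k], high) == 1.0


class TestBroadscale:
    def test_full_selection_scores_one(self, rng):
        d = random_distance_matrix(rng, 6)
        assert broadscale_performance(d, set(d.sites)) == pytest.approx(1.0)

    def test_worse_than_baseline_clamps_to_zero(self):
        # one remote outlier: selecting only it is worse than the average
        vals = np.array(
            [
                [0, 1, 1, 9],
                [1, 0, 1, 9],
                [1, 1, 0, 9],
                [9, 9, 9, 0.0],
            ]
        )
        d = DistanceMatrix(("A", "B", "C", "D"), vals, "hand")
        assert ed_objective(d, {"D"}) > broadscale_baseline(d)
        assert broadscale_performance(d, {"D"}) == 0.0

    def test_medoid_value_matches_bruteforce(self):
        vals = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 3, 5],
                [4, 3, 0, 1],
                [6, 5, 1, 0.0],
            ]
        )
        d = DistanceMatrix(("A", "B", "C", "D"), vals, "hand")
        col_sums = vals.sum(axis=0)
        medoid = d.sites[int(np.argmin(col_sums))]
        a = col_sums.min()
        b = col_sums.mean()
        assert broadscale_performance(d, {medoid}) == pytest.approx(
            max(0.0, 1 - a / b), abs=1e-12
        )

    def test_all_zero_distances_warn(self):
        d = DistanceMatrix(("A", "B"), np.zeros((2, 2)), "hand")
        with pytest.warns(UserWarning, match="zero"):
            assert broadscale_performance(d, {"A"}) == 1.0


class TestSurrogateSummary:
    def _curves(self, rng):
        d = random_distance_matrix(rng, 8)
        from gensurr.evaluate import broadscale_curves
        from gensurr.prioritize import ed_series

        series = [ed_series(d, method="jost_d_ed")]
        series += random_series(d.sites, reps=40, seed=1)
        return broadscale_curves(series, d)

    def test_reference_relative_is_100(self, rng):
        curves = self._curves(rng)
        summary = surrogate_summary(curves, "jost_d_ed", seed=5)
        ref = summary[summary["method"] == "jost_d_ed"]
        assert np.allclose(ref["relative_mean_pct"], 100.0)

    def test_random_vs_itself_is_centered_on_zero(self, rng):
        d = random_distance_matrix(rng, 8)
        from gensurr.evaluate import broadscale_curves

        randoms = random_series(d.sites, reps=200, seed=2)
        # treat the first replicate as if it were a "method"
        probe = randoms[0]
        object.__setattr__(probe, "method", "jost_d_ed")
        object.__setattr__(probe, "replicate", None)
        curves = broadscale_curves([probe] + randoms[1:], d)
        summary = surrogate_summary(curves, "jost_d_ed", n_boot=500, seed=7)
        row = summary[(summary["method"] == "jost_d_ed") & (summary["window"] == "all")]
        lo = float(row["improvement_ci_low"].iloc[0])
        hi = float(row["improvement_ci_high"].iloc[0])
        assert lo <= 0.0 + 5.0 and hi >= 0.0 - 5.0  # CI overlaps zero (pp scale)

    def test_mismatched_k_grid_errors(self, rng):
        d = random_distance_matrix(rng, 8)
        from gensurr.evaluate import broadscale_curves
        from gensurr.prioritize import ed_series

        series = [ed_series(d, method="jost_d_ed"), ed_series(d, method="geographic_ed")]
        series += random_series(d.sites, reps=10, seed=1)
        curves = broadscale_curves(series, d)
        broken = curves[~((curves["method"] == "geographic_ed") & (curves["k"] == 3))]
        with pytest.raises(GensurrError, match="mismatched"):
            surrogate_summary(broken, "jost_d_ed")


class TestSpearman:
    def test_perfect_concordance_small_n(self):
        x = scores({c: float(i) for i, c in enumerate("ABCDE")})
        rho, p = spearman_onesided(x, x)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / factorial(5), abs=1e-15)

    def test_perfect_discordance(self):
        x = scores({c: float(i) for i, c in enumerate("ABCDEF")})
        y = scores({c: float(-i) for i, c in enumerate("ABCDEF")})
        rho, p = spearman_onesided(x, y)
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_tied_fixture_matches_enumeration(self):
        xd = {"A": 1.0, "B": 2.0, "C": 2.0, "D": 3.0, "E": 4.0, "F": 5.0}
        yd = {"A": 2.0, "B": 1.0, "C": 4.0, "D": 4.0, "E": 3.0, "F": 6.0}
        rho, p = spearman_onesided(scores(xd), scores(yd))
        rx = stats.rankdata(list(xd.values()))
        ry = stats.rankdata(list(yd.values()))
        count = sum(
            np.corrcoef(rx, perm)[0, 1] >= rho - 1e-12
            for perm in permutations(ry)
        )
        assert p == pytest.approx(count / factorial(6), abs=1e-15)

    def test_matches_scipy_for_large_n(self, rng):
        vals_x = rng.random(20)
        vals_y = 0.5 * vals_x + rng.random(20)
        ids = [f"S{i}" for i in range(20)]
        x = scores(dict(zip(ids, vals_x)))
        y = scores(dict(zip(ids, vals_y)))
        rho, p = spearman_onesided(x, y)
        ref = stats.spearmanr(vals_x, vals_y, alternative="greater")
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_vector_errors(self):
        x = scores({c: 1.0 for c in "ABCD"})
        y = scores({c: float(i) for i, c in enumerate("ABCD")})
        with pytest.raises(GensurrError, match="constant"):
            spearman_onesided(x, y)


def simulate_mlpe(rng, n_sites, beta0, beta1, s2u, s2e):
    coords = rng.random((n_sites, 2))
    x = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    u = rng.normal(0, np.sqrt(s2u), size=n_sites)
    y = np.zeros_like(x)
    iu = np.triu_indices(n_sites, 1)
    y[iu] = beta0 + beta1 * x[iu] + u[iu[0]] + u[iu[1]] + rng.normal(
        0, np.sqrt(s2e), size=len(iu[0])
    )
    y = y + y.T
    np.fill_diagonal(y, 0.0)
    ids = tuple(f"S{i}" for i in range(n_sites))
    return (
        DistanceMatrix(ids, np.abs(y), "sim_response"),
        DistanceMatrix(ids, x, "sim_predictor"),
    )


class TestMLPE:
    def test_noiseless_recovery(self, rng):
        response, predictor = simulate_mlpe(rng, 10, 2.0, 3.0, 0.0, 1e-12)
        fit = mlpe_fit(response, predictor, standardize=False)
        assert fit.intercept == pytest.approx(2.0, abs=1e-4)
        assert fit.slope == pytest.approx(3.0, abs=1e-4)
        assert fit.r2_beta > 0.999

    def test_null_case_slope_near_zero(self, rng):
        slopes, r2s = [], []
        for _ in range(40):
            response, _ = simulate_mlpe(rng, 12, 5.0, 0.0, 0.2, 0.1)
            _, predictor = simulate_mlpe(rng, 12, 0.0, 1.0, 0.0, 0.0)
            fit = mlpe_fit(response, predictor, standardize=False)
            slopes.append(fit.slope)
            r2s.append(fit.r2_beta)
        assert abs(np.mean(slopes)) < 0.15
        assert np.mean(r2s) < 0.25

    def test_variance_partition_sane(self, rng):
        response, predictor = simulate_mlpe(rng, 25, 5.0, 0.5, 0.3, 0.05)
        fit = mlpe_fit(response, predictor, standardize=False)
        assert fit.converged
        assert fit.sigma2_u > fit.sigma2_e  # site effects dominate here

    def test_too_few_sites_errors(self, rng):
        response, predictor = simulate_mlpe(rng, 4, 5.0, 0.5, 0.1, 0.1)
        with pytest.raises(GensurrError, match="at least 5"):
            mlpe_fit(response, predictor)
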