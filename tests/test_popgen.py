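"""Rarefied allelic richness and pairwise Jost's D."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gensurr import GensurrError, allele_counts, jost_d_pairwise, rarefied_allelic_richness
from gensurr.popgen import AlleleCountTable, _rarefied_locus_richness

from conftest import build_dataset, random_dataset


def make_counts(cells: dict[tuple[str, str], dict[int, int]]) -> AlleleCountTable:
    sites = sorted({s for s, _ in cells})
    loci = sorted({l for _, l in cells})
    counts = {s: {l: dict(cells[(s, l)]) for l in loci} for s in sites}
    return AlleleCountTable(tuple(sites), tuple(loci), counts)


def enumeration_richness(locus_counts: dict[int, int], g: int) -> float:
    """Independent oracle: mean distinct alleles over all C(N, g) subsamples
    of the explicit multiset of allele copies."""
    copies = [a for a, n in locus_counts.items() for _ in range(n)]
    subsets = list(combinations(range(len(copies)), g))
    total = Fraction(0)
    for idx in subsets:
        total += len({copies[i] for i in idx})
    return float(total / len(subsets))


class TestAlleleCounts:
    def test_counts_exclude_missing(self):
        ds = build_dataset(
            {"A": [[(1, 2), (1, 0)], [(2, 2), (0, 0)]]}  # 2 inds x 2 loci
        )
        table = allele_counts(ds)
        assert table.n_copies("A", "L1") == 4
        assert table.n_copies("A", "L2") == 1
        assert table.counts["A"]["L1"] == {1: 1, 2: 3}

    def test_full_data_has_two_copies_per_individual(self, rng):
        ds = random_dataset(rng, n_sites=2, n_ind=5)
        table = allele_counts(ds)
        for site in ds.sites:
            for locus in ds.loci:
                assert table.n_copies(site, locus) == 10

    def test_empty_dataset_errors(self):
        with pytest.raises(GensurrError, match="empty"):
            allele_counts(_empty())

    def test_all_missing_site_is_flagged(self):
        ds = build_dataset({"A": [[(1, 2)]], "B": [[(0, 0)]]})
        with pytest.raises(GensurrError, match="B"):
            allele_counts(ds)


def _empty():
    from gensurr import GenotypeDataset

    return GenotypeDataset(sites=[], loci=[], calls={})


class TestRarefaction:
    def test_monomorphic_locus_gives_one(self):
        table = make_counts({("A", "L1"): {1: 8}})
        ar = rarefied_allelic_richness(table, g=4)
        assert ar.series["A"] == pytest.approx(1.0, abs=1e-15)

    def test_small_fixture_exact(self):
        # counts {A:3, B:1}: of the 6 pairs of copies, 3 are {A,A} and 3 {A,B}
        table = make_counts({("A", "L1"): {1: 3, 2: 1}})
        ar = rarefied_allelic_richness(table, g=2)
        assert ar.series["A"] == pytest.approx(1.5, abs=1e-15)

    def test_g_equals_n_returns_distinct_alleles(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 5))
            counts = {i + 1: int(rng.integers(1, 4)) for i in range(k)}
            table = make_counts({("A", "L1"): counts})
            n_total = sum(counts.values())
            ar = rarefied_allelic_richness(table, g=n_total)
            assert ar.series["A"] == pytest.approx(k, abs=1e-12)

    def test_auto_uses_global_minimum(self):
        table = make_counts(
            {("A", "L1"): {1: 2, 2: 2}, ("B", "L1"): {1: 6, 2: 2}}
        )
        auto = rarefied_allelic_richness(table, g="auto")
        explicit = rarefied_allelic_richness(table, g=4)
        assert (auto.series == explicit.series).all()

    def test_rarefying_upward_errors(self):
        table = make_counts({("A", "L1"): {1: 2, 2: 2}})
        with pytest.raises(GensurrError, match="L1"):
            rarefied_allelic_richness(table, g=6)

    def test_g_below_two_errors(self):
        table = make_counts({("A", "L1"): {1: 2, 2: 2}})
        with pytest.raises(GensurrError, match="g=1"):
            rarefied_allelic_richness(table, g=1)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_enumeration_oracle(self, data):
        k = data.draw(st.integers(1, 4))
        counts = {
            a + 1: data.draw(st.integers(1, 4), label=f"n_{a}") for a in range(k)
        }
        n_total = sum(counts.values())
        if n_total > 10 or n_total < 2:
            counts = {1: 5, 2: 5}
            n_total = 10
        g = data.draw(st.integers(2, min(6, n_total)))
        assert _rarefied_locus_richness(counts, g) == pytest.approx(
            enumeration_richness(counts, g), abs=1e-12
        )

    @given(st.dictionaries(st.integers(1, 5), st.integers(1, 4), min_size=2, max_size=4))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_in_g(self, counts):
        n_total = sum(counts.values())
        values = [_rarefied_locus_richness(counts, g) for g in range(2, n_total + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


JOST_FIXTURE = build_dataset(
    {
        # locus1 counts A:{6,4} B:{2,8}; locus2 A:{10,0} B:{5,5}; n=5 each
        "A": [
            [(1, 1), (1, 1)],
            [(1, 1), (1, 1)],
            [(1, 2), (1, 1)],
            [(2, 2), (1, 1)],
            [(1, 2), (1, 1)],
        ],
        "B": [
            [(1, 2), (1, 2)],
            [(2, 2), (1, 2)],
            [(2, 2), (1, 2)],
            [(1, 2), (1, 2)],
            [(2, 2), (1, 2)],
        ],
    }
)


def oracle_jost_d(counts_a: dict[int, int], counts_b: dict[int, int]) -> Fraction:
    """Independent exact-rational transliteration of the two-population
    Jost's D estimator (Nei/Chesser-corrected heterozygosities)."""
    alleles = set(counts_a) | set(counts_b)
    copies_a, copies_b = sum(counts_a.values()), sum(counts_b.values())
    p_a = {al: Fraction(counts_a.get(al, 0), copies_a) for al in alleles}
    p_b = {al: Fraction(counts_b.get(al, 0), copies_b) for al in alleles}
    n_a, n_b = Fraction(copies_a, 2), Fraction(copies_b, 2)
    n_tilde = 2 / (1 / n_a + 1 / n_b)
    h_s = (2 * n_tilde / (2 * n_tilde - 1)) * (
        1 - Fraction(sum(v**2 for v in p_a.values()) + sum(v**2 for v in p_b.values()), 2)
    )
    p_bar = {al: (p_a[al] + p_b[al]) / 2 for al in alleles}
    h_t = 1 - sum(v**2 for v in p_bar.values()) + h_s / (4 * n_tilde)
    return 2 * (h_t - h_s) / (1 - h_s)


class TestJostD:
    def test_identical_profiles_give_zero(self):
        block = [[(1, 2), (1, 1)], [(1, 1), (1, 2)], [(2, 2), (2, 2)]]
        ds = build_dataset({"A": block, "B": block})
        d = jost_d_pairwise(ds)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles_give_one(self):
        ds = build_dataset({"A": [[(1, 1)]] * 5, "B": [[(2, 2)]] * 5})
        d = jost_d_pairwise(ds)
        assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_two_locus_fixture_matches_independent_oracle(self):
        d = jost_d_pairwise(JOST_FIXTURE)
        per_locus = [
            oracle_jost_d({1: 6, 2: 4}, {1: 2, 2: 8}),
            oracle_jost_d({1: 10}, {1: 5, 2: 5}),
        ]
        expected = float(sum(max(v, 0) for v in per_locus) / 2)
        assert expected == pytest.approx(0.25784615384615384, abs=1e-15)
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_locus_contributes_zero_not_dropped(self):
        # adding a monomorphic locus halves the arithmetic mean
        one = build_dataset({"A": [[(1, 1)]] * 4, "B": [[(2, 2)]] * 4})
        two = build_dataset(
            {"A": [[(1, 1), (3, 3)]] * 4, "B": [[(2, 2), (3, 3)]] * 4}
        )
        d1 = jost_d_pairwise(one).values[0, 1]
        d2 = jost_d_pairwise(two).values[0, 1]
        assert d2 == pytest.approx(d1 / 2, abs=1e-12)

    def test_permuting_individuals_is_invariant(self, rng):
        ds = random_dataset(rng, n_sites=3, n_ind=8, n_loci=4)
        base = jost_d_pairwise(ds).values
        for site in ds.sites:
            perm = rng.permutation(ds.calls[site].shape[0])
            ds.calls[site] = ds.calls[site][perm]
        assert np.allclose(jost_d_pairwise(ds).values, base, atol=1e-14)

    def test_bounds_and_diagonal(self, rng):
        for _ in range(5):
            ds = random_dataset(rng, n_sites=4, n_ind=6, n_loci=3, missing_rate=0.1)
            d = jost_d_pairwise(ds)
            assert (d.values >= 0).all() and (d.values <= 1).all()
            assert np.diagonal(d.values).sum() == 0

    def test_harmonic_combination_never_exceeds_arithmetic(self, rng):
        for _ in range(5):
            ds = random_dataset(rng, n_sites=3, n_ind=8, n_loci=4)
            arith = jost_d_pairwise(ds, combine="arithmetic").values
            harm = jost_d_pairwise(ds, combine="harmonic").values
            assert (harm <= arith + 1e-12).all()

    def test_single_site_errors(self):
        ds = build_dataset({"A": [[(1, 1)]]})
        with pytest.raises(GensurrError, match="two sites"):
            jost_d_pairwise(ds)

    def test_no_shared_typed_locus_errors(self):
        ds = build_dataset({"A": [[(1, 1), (0, 0)]], "B": [[(0, 0), (2, 2)]]})
        with pytest.raises(GensurrError, match="share no typed locus"):
            jost_d_pairwise(ds)


class TestDilution:
    def test_identical_extra_locus_never_increases_d(self, rng):
        """Appending a locus with identical counts in both populations can
        only dilute the combined (arithmetic) differentiation."""
        for _ in range(10):
            ds = random_dataset(rng, n_sites=2, n_ind=6, n_loci=3)
            base = jost_d_pairwise(ds).values[0, 1]
            shared = rng.integers(1, 5, size=(6, 1, 2))
            wide = {
                site: np.concatenate([ds.calls[site], shared], axis=1)
                for site in ds.sites
            }
            from gensurr import GenotypeDataset

            ds2 = GenotypeDataset(
                sites=ds.sites, loci=ds.loci + ["extra"], calls=wide
            )
            assert jost_d_pairwise(ds2).values[0, 1] <= base + 1e-12
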