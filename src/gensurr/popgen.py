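"""Site-level and broad-scale genetic diversity from microsatellite genotypes.

Two metrics drive the whole evaluation:

* **Rarefied allelic richness** (Hurlbert rarefaction) — the expected number
  of distinct alleles in a standardized subsample of ``g`` allele copies,
  averaged over loci.  Rarefaction makes allele counts comparable across
  sites with unequal sample sizes: for a locus with ``N`` observed copies of
  which ``N_a`` carry allele ``a``,

      AR = sum_a [ 1 - C(N - N_a, g) / C(N, g) ]

  where ``C(m, g) = 0`` whenever ``m < g``.

* **Jost's D** — pairwise allele-frequency differentiation built on
  Nei/Chesser-style unbiased heterozygosity estimates.  For two populations
  (k = 2) with harmonic-mean sample size ``ñ`` individuals,

      Hs = (2ñ / (2ñ - 1)) * (1 - mean_pop sum_a p_a^2)
      Ht = 1 - sum_a pbar_a^2 + Hs / (2 ñ k)
      D  = (k / (k - 1)) * (Ht - Hs) / (1 - Hs)

  D is 0 for identical allele-frequency profiles and 1 when the two
  populations share no alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    DistanceMatrix,
    GensurrError,
    GenotypeDataset,
    ScoreVector,
)


@dataclass(frozen=True)
class AlleleCountTable:
    """Observed allele-copy counts per site x locus.

    ``counts[site][locus]`` maps allele ID -> number of observed copies;
    missing calls are excluded, so a half-missing genotype contributes one
    copy.  ``n_copies`` returns N, the total observed copies in a cell.
    """

    sites: tuple[str, ...]
    loci: tuple[str, ...]
    counts: dict[str, dict[str, dict[int, int]]]

    def n_copies(self, site: str, locus: str) -> int:
        return sum(self.counts[site][locus].values())

    def min_copies(self) -> int:
        return min(
            self.n_copies(site, locus) for site in self.sites for locus in self.loci
        )


def allele_counts(genotypes: GenotypeDataset) -> AlleleCountTable:
    """Tally observed allele copies per site and locus.

    Raises a flagged-site error when a site has zero observed copies at
    every locus (such a site carries no genetic information at all).
    """
    if genotypes.n_sites == 0 or not genotypes.loci:
        raise GensurrError("empty genotype dataset")
    counts: dict[str, dict[str, dict[int, int]]] = {}
    empty_sites = []
    for site in genotypes.sites:
        arr = genotypes.calls[site]
        per_locus: dict[str, dict[int, int]] = {}
        total = 0
        for l, locus in enumerate(genotypes.loci):
            flat = arr[:, l, :].ravel()
            observed = flat[flat != MISSING]
            alleles, n = np.unique(observed, return_counts=True)
            per_locus[locus] = {int(a): int(c) for a, c in zip(alleles, n)}
            total += observed.size
        if total == 0:
            empty_sites.append(site)
        counts[site] = per_locus
    if empty_sites:
        raise GensurrError(
            f"sites with no observed allele copies at any locus: {empty_sites}"
        )
    return AlleleCountTable(tuple(genotypes.sites), tuple(genotypes.loci), counts)


def _rarefied_locus_richness(locus_counts: dict[int, int], g: int) -> float:
    """Expected distinct alleles in a subsample of g copies (exact)."""
    n_total = sum(locus_counts.values())
    denom = comb(n_total, g)
    acc = Fraction(0)
    for n_a in locus_counts.values():
        m = n_total - n_a
        acc += 1 - Fraction(comb(m, g) if m >= g else 0, denom)
    return float(acc)


def rarefied_allelic_richness(
    counts: AlleleCountTable, g: int | str = "auto"
) -> ScoreVector:
    """Per-site allelic richness rarefied to ``g`` allele copies.

    ``g="auto"`` uses one global rarefaction size per dataset: the minimum
    observed copy count over all site x locus cells, so every site is
    rarefied to the same depth and scores stay comparable across sites.
    """
    if g == "auto":
        g = counts.min_copies()
    g = int(g)
    if g < 2:
        raise GensurrError(f"rarefaction size g={g} must be >= 2")
    scores = {}
    for site in counts.sites:
        per_locus = []
        for locus in counts.loci:
            n_total = counts.n_copies(site, locus)
            if n_total < g:
                raise GensurrError(
                    f"cannot rarefy upward: site {site!r} locus {locus!r} has "
                    f"N={n_total} < g={g}"
                )
            per_locus.append(_rarefied_locus_richness(counts.counts[site][locus], g))
        scores[site] = float(np.mean(per_locus))
    return ScoreVector(pd.Series(scores, index=list(counts.sites)), "allelic_richness")


def _jost_d_locus(
    counts_a: dict[int, int], counts_b: dict[int, int]
) -> float | None:
    """Per-locus pairwise Jost's D; None when the estimator is undefined."""
    n_copies_a = sum(counts_a.values())
    n_copies_b = sum(counts_b.values())
    alleles = set(counts_a) | set(counts_b)
    if len(alleles) <= 1:
        return 0.0  # monomorphic across the pair: no differentiation
    p_a = np.array([counts_a.get(al, 0) / n_copies_a for al in alleles])
    p_b = np.array([counts_b.get(al, 0) / n_copies_b for al in alleles])
    # sample sizes in individuals; half-missing genotypes give fractional n
    n_ind_a = n_copies_a / 2.0
    n_ind_b = n_copies_b / 2.0
    n_tilde = 2.0 / (1.0 / n_ind_a + 1.0 / n_ind_b)
    h_s = (2 * n_tilde / (2 * n_tilde - 1)) * (
        1 - (np.sum(p_a**2) + np.sum(p_b**2)) / 2.0
    )
    p_bar = (p_a + p_b) / 2.0
    h_t = 1 - np.sum(p_bar**2) + h_s / (4 * n_tilde)
    if 1.0 - h_s <= 1e-12:
        return None
    return float(2.0 * (h_t - h_s) / (1.0 - h_s))


def _combine_loci(values: list[float], rule: str) -> float:
    clamped = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    if rule == "arithmetic":
        return float(clamped.mean())
    if rule == "harmonic":
        # harmonic mean penalizes loci with (near-)zero differentiation; a
        # tiny floor keeps it defined when a per-locus estimate is exactly 0
        floored = np.maximum(clamped, 1e-12)
        hm = len(floored) / np.sum(1.0 / floored)
        return float(0.0 if hm < 1e-9 else hm)
    raise GensurrError(f"unknown locus-combination rule {rule!r}")


def jost_d_pairwise(
    genotypes: GenotypeDataset, combine: str = "arithmetic"
) -> DistanceMatrix:
    """Pairwise Jost's D between all sites, combined across loci.

    Per-locus estimates are clamped to [0, 1] (negative finite-sample
    estimates mean "no detectable differentiation") and combined with the
    arithmetic mean by default; ``combine="harmonic"`` is available because
    common implementations differ on this point.  Loci monomorphic across a
    pair contribute D = 0; loci with an undefined estimator (within-pair
    heterozygosity exactly 1) are dropped for that pair with a warning.
    """
    if genotypes.n_sites < 2:
        raise GensurrError("pairwise Jost's D needs at least two sites")
    table = allele_counts(genotypes)
    n = len(table.sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            site_i, site_j = table.sites[i], table.sites[j]
            per_locus: list[float] = []
            dropped = 0
            for locus in table.loci:
                ci = table.counts[site_i][locus]
                cj = table.counts[site_j][locus]
                if not ci or not cj:
                    continue  # locus untyped in one member of the pair
                d = _jost_d_locus(ci, cj)
                if d is None:
                    dropped += 1
                else:
                    per_locus.append(d)
            if not per_locus:
                raise GensurrError(
                    f"sites {site_i!r} and {site_j!r} share no typed locus"
                )
            if dropped:
                warnings.warn(
                    f"dropped {dropped} loci with undefined D for pair "
                    f"({site_i}, {site_j})",
                    stacklevel=2,
                )
            out[i, j] = out[j, i] = _combine_loci(per_locus, combine)
    return DistanceMatrix(table.sites, out, "jost_d")
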