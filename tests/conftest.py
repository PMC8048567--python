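"""Shared fixtures: tiny hand-built genotype datasets and distance matrices."""

from __future__ import annotations

import numpy as np
import pytest

from gensurr import DistanceMatrix, GenotypeDataset


def build_dataset(site_calls: dict[str, list[list[tuple[int, int]]]], loci=None):
    """Build a GenotypeDataset from {site: [per-individual list of (a1, a2)
    per locus]} literals."""
    sites = list(site_calls)
    n_loci = len(next(iter(site_calls.values()))[0])
    loci = loci or [f"L{i + 1}" for i in range(n_loci)]
    calls = {
        site: np.array(ind_calls, dtype=np.int64)
        for site, ind_calls in site_calls.items()
    }
    return GenotypeDataset(sites=sites, loci=loci, calls=calls)


def random_dataset(
    rng: np.random.Generator,
    n_sites: int = 4,
    n_ind: int = 6,
    n_loci: int = 3,
    n_alleles: int = 4,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    sites = [f"P{i + 1}" for i in range(n_sites)]
    calls = {}
    for site in sites:
        arr = rng.integers(1, n_alleles + 1, size=(n_ind, n_loci, 2))
        if missing_rate:
            arr[rng.random(arr.shape) < missing_rate] = 0
        calls[site] = arr
    return GenotypeDataset(sites=sites, loci=[f"L{l + 1}" for l in range(n_loci)], calls=calls)


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(tuple(f"S{i + 1}" for i in range(n)), d, "test")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
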