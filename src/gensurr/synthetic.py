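"""Synthetic landscapes, sampling sites and microsatellite genotypes.

The generator reproduces the statistical structure the surrogate evaluation
assumes, without claiming demographic realism (no coalescent, no mutation
model, no selection):

* suitability rasters for a contemporary and several historical periods,
  spatially smooth and temporally autocorrelated, optionally with refugia —
  neighborhoods that stay highly suitable in every period;
* sampling sites placed on suitable cells with a minimum separation;
* diploid multi-locus genotypes whose allele frequencies combine discrete
  lineages, isolation by distance (or resistance), drift that intensifies
  where long-term suitability is low, and admixture near lineage contact
  zones.

Everything is driven by explicit integer seeds: identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.cluster import KMeans

from .containers import (
    MISSING,
    GensurrError,
    GenotypeDataset,
    RasterStack,
    SiteTable,
)
from .surrogates import longterm_suitability, resistance_from_stack

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class LandscapeConfig:
    """Controls the synthetic suitability raster stack.

    ``stability`` is the lag-1 temporal autocorrelation of the latent
    suitability field across periods (1.0 = identical periods);
    ``smoothness`` is the Gaussian spatial-correlation length in cells.
    Defaults emulate the study grid: 10 km cells, one contemporary plus six
    historical periods.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    cell_size: float = 10_000.0
    n_periods: int = 7
    stability: float = 0.8
    smoothness: float = 6.0
    refugia_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise GensurrError("grid must be at least 4x4")
        if self.n_periods < 1:
            raise GensurrError("n_periods must be >= 1")
        if not 0.0 <= self.stability <= 1.0:
            raise GensurrError("stability must lie in [0, 1]")
        if self.smoothness <= 0:
            raise GensurrError("smoothness must be positive")
        if self.refugia_count < 0:
            raise GensurrError("refugia_count must be >= 0")


@dataclass(frozen=True)
class GenotypeConfig:
    """Controls the genotype generative model.

    Ranges follow the envelope of the study datasets: 10-37 sites per
    species, 10-30 samples per site, 6-20 microsatellite loci.
    ``ibd_scale`` is the e-folding distance (meters) of allele-frequency
    correlation; ``stability_effect`` scales drift toward fixation at sites
    with low long-term suitability; ``admixture_width`` (meters) is the
    reach of lineage mixing around contact zones.
    """

    n_sites: int = 20
    samples_per_site: tuple[int, int] = (10, 30)
    n_loci: tuple[int, int] = (6, 20)
    alleles_per_locus: tuple[int, int] = (4, 12)
    n_lineages: int = 2
    ibd_scale: float = 150_000.0
    use_resistance: bool = False
    stability_effect: float = 0.5
    admixture_width: float = 0.0
    missing_rate: float = 0.02
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise GensurrError("need at least two sites")
        if self.alleles_per_locus[0] < 2:
            raise GensurrError("alleles_per_locus must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise GensurrError("missing_rate must lie in [0, 1)")
        if self.n_lineages < 1:
            raise GensurrError("n_lineages must be >= 1")
        if self.stability_effect < 0:
            raise GensurrError("stability_effect must be >= 0")
        for name in ("samples_per_site", "n_loci", "alleles_per_locus"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise GensurrError(f"invalid range for {name}")


@dataclass(frozen=True)
class TrueStructure:
    """Ground truth retained from the generative model for recovery tests."""

    lineage_of_site: dict[str, int]
    expected_diversity_rank: dict[str, int]  # 1 = highest expected diversity
    generating_params: dict

    def __post_init__(self) -> None:
        ranks = sorted(self.expected_diversity_rank.values())
        if ranks != list(range(1, len(ranks) + 1)):
            raise GensurrError("diversity ranks must be a permutation of 1..n")


# ---------------------------------------------------------------------------
# landscape


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    return ndimage.gaussian_filter(white, sigma=smoothness, mode="reflect")


def _rank_to_unit(grid: np.ndarray) -> np.ndarray:
    flat = stats.rankdata(grid.ravel(), method="average") - 1.0
    return (flat / (flat.size - 1)).reshape(grid.shape)


def make_landscape(config: LandscapeConfig) -> RasterStack:
    """Generate aligned suitability rasters for all periods.

    Latent Gaussian fields follow an AR(1) process across periods with
    coefficient ``stability``; each field is Gaussian-smoothed white noise,
    rank-transformed to [0, 1] per period.  Requested refugia are disjoint
    3x3 neighborhoods forced to suitability >= 0.8 in every period.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    fields = [_smooth_field(rng, shape, config.smoothness)]
    rho = config.stability
    for _ in range(1, config.n_periods):
        innovation = _smooth_field(rng, shape, config.smoothness)
        fields.append(rho * fields[-1] + np.sqrt(1.0 - rho**2) * innovation)
    grids = np.stack([_rank_to_unit(f) for f in fields])

    if config.refugia_count:
        centers = _place_refugia(rng, shape, config.refugia_count)
        for r, c in centers:
            block = (slice(r - 1, r + 2), slice(c - 1, c + 2))
            bump = np.full((3, 3), 0.82)
            bump[1, 1] = 0.95
            for p in range(config.n_periods):
                grids[p][block] = np.maximum(grids[p][block], bump)

    periods = ["contemporary"] + [f"hist{i}" for i in range(1, config.n_periods)]
    return RasterStack(
        tuple(periods), grids, xllcorner=0.0, yllcorner=0.0, cellsize=config.cell_size
    )


def _place_refugia(
    rng: np.random.Generator, shape: tuple[int, int], count: int
) -> list[tuple[int, int]]:
    nrows, ncols = shape
    candidates = [
        (r, c) for r in range(1, nrows - 1) for c in range(1, ncols - 1)
    ]
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, int]] = []
    for idx in order:
        r, c = candidates[idx]
        if all(max(abs(r - r0), abs(c - c0)) >= 4 for r0, c0 in chosen):
            chosen.append((r, c))
            if len(chosen) == count:
                return chosen
    raise GensurrError(f"cannot place {count} disjoint refugia on a {shape} grid")


# ---------------------------------------------------------------------------
# sites


def place_sites(
    stack: RasterStack,
    n_sites: int,
    min_separation: float = 0.0,
    seed: int = 0,
    min_suitability: float = 0.05,
) -> SiteTable:
    """Place sites at centers of suitable cells, at least ``min_separation``
    apart, by seeded greedy rejection sampling."""
    rng = np.random.default_rng(seed)
    grid = stack.contemporary
    eligible = np.argwhere(np.nan_to_num(grid, nan=-1.0) > min_suitability)
    if n_sites > len(eligible):
        raise GensurrError(
            f"requested {n_sites} sites but only {len(eligible)} cells have "
            f"contemporary suitability > {min_suitability}"
        )
    order = rng.permutation(len(eligible))
    chosen: list[tuple[float, float]] = []
    for idx in order:
        r, c = eligible[idx]
        x, y = stack.cell_center(int(r), int(c))
        if all(
            np.hypot(x - x0, y - y0) >= min_separation for x0, y0 in chosen
        ):
            chosen.append((x, y))
            if len(chosen) == n_sites:
                break
    if len(chosen) < n_sites:
        raise GensurrError(
            f"could not place {n_sites} sites with min_separation="
            f"{min_separation}: only {len(chosen)} fit"
        )
    width = max(2, len(str(n_sites)))
    frame = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:0{width}d}" for i in range(n_sites)],
            "x": [xy[0] for xy in chosen],
            "y": [xy[1] for xy in chosen],
        }
    )
    return SiteTable(frame)


# ---------------------------------------------------------------------------
# genotypes


def _lineage_assignment(
    coords: np.ndarray, n_lineages: int, seed: int
) -> np.ndarray:
    if n_lineages == 1:
        return np.zeros(len(coords), dtype=int)
    km = KMeans(n_clusters=n_lineages, n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(coords)
    # relabel in order of first appearance so labels are stable under
    # cluster-index permutation (ties broken by site order)
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def _site_correlation(
    sites: SiteTable,
    stack: RasterStack,
    config: GenotypeConfig,
) -> np.ndarray:
    """Correlation of allele-frequency noise between sites: exp(-d / scale).

    Under ``use_resistance`` the resistance matrix is rescaled to the mean
    of the geographic matrix so ``ibd_scale`` keeps its metric meaning.
    """
    coords = sites.coords
    geo = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    if config.use_resistance:
        res = resistance_from_stack(stack, sites).values
        off = ~np.eye(len(coords), dtype=bool)
        if res[off].mean() > 0:
            d = res * (geo[off].mean() / res[off].mean())
        else:
            d = geo
    else:
        d = geo
    return np.exp(-d / config.ibd_scale)


def simulate_genotypes(
    sites: SiteTable, stack: RasterStack, config: GenotypeConfig
) -> tuple[GenotypeDataset, TrueStructure]:
    """Simulate diploid multi-locus genotypes at the given sites.

    Generative model (in order): (1) sites are assigned to lineages by
    k-means on coordinates; (2) each lineage gets an independent Dirichlet
    ancestral allele-frequency vector per locus; (3) site frequencies
    perturb the lineage frequencies on the log scale with multivariate
    Gaussian noise whose between-site correlation decays as
    exp(-d / ibd_scale); (4) each site's frequencies shrink toward the
    locally dominant allele by a drift factor
    (1 - long-term suitability) * stability_effect (capped at 0.9);
    (5) sites within ``admixture_width`` of another lineage mix frequencies
    with their nearest other-lineage site; (6) allele copies are drawn from
    the site frequencies under within-site Hardy-Weinberg equilibrium;
    (7) individual allele calls are masked at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = len(sites)
    site_ids = sites.ids
    coords = sites.coords

    lineages = _lineage_assignment(coords, config.n_lineages, config.seed)
    corr = _site_correlation(sites, stack, config)
    chol = np.linalg.cholesky(corr + 1e-8 * np.eye(n_sites))
    suitability = longterm_suitability(stack, sites).series.reindex(site_ids).to_numpy()
    drift = np.clip((1.0 - suitability) * config.stability_effect, 0.0, 0.9)

    n_loci = int(rng.integers(config.n_loci[0], config.n_loci[1] + 1))
    loci = [f"L{l + 1:02d}" for l in range(n_loci)]
    samples = rng.integers(
        config.samples_per_site[0], config.samples_per_site[1] + 1, size=n_sites
    )

    # nearest other-lineage site, for admixture mixing
    mix_partner = np.full(n_sites, -1)
    mix_weight = np.zeros(n_sites)
    if config.n_lineages > 1 and config.admixture_width > 0:
        geo = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        for i in range(n_sites):
            other = np.flatnonzero(lineages != lineages[i])
            if other.size == 0:
                continue
            j = other[np.argmin(geo[i, other])]
            d = geo[i, j]
            if d <= config.admixture_width:
                mix_partner[i] = j
                mix_weight[i] = 0.5 * (1.0 - d / config.admixture_width)

    calls = {
        site: np.zeros((int(samples[i]), n_loci, 2), dtype=np.int64)
        for i, site in enumerate(site_ids)
    }
    expected_het = np.zeros(n_sites)
    for l in range(n_loci):
        n_alleles = int(
            rng.integers(config.alleles_per_locus[0], config.alleles_per_locus[1] + 1)
        )
        ancestral = rng.dirichlet(
            np.full(n_alleles, 0.8), size=config.n_lineages
        )  # (lineages, alleles)
        # spatially correlated perturbation of log-frequencies
        noise = chol @ rng.standard_normal((n_sites, n_alleles))
        logits = np.log(ancestral[lineages] + 1e-9) + config.noise_sd * noise
        freqs = np.exp(logits - logits.max(axis=1, keepdims=True))
        freqs /= freqs.sum(axis=1, keepdims=True)
        # drift toward the locally dominant allele where suitability is low
        dominant = np.argmax(freqs, axis=1)
        onehot = np.eye(n_alleles)[dominant]
        freqs = (1.0 - drift[:, None]) * freqs + drift[:, None] * onehot
        # admixture near lineage boundaries
        mixed = freqs.copy()
        for i in range(n_sites):
            if mix_partner[i] >= 0:
                w = mix_weight[i]
                mixed[i] = (1.0 - w) * freqs[i] + w * freqs[mix_partner[i]]
        freqs = mixed / mixed.sum(axis=1, keepdims=True)
        expected_het += 1.0 - np.sum(freqs**2, axis=1)
        for i, site in enumerate(site_ids):
            draws = rng.choice(n_alleles, size=(int(samples[i]), 2), p=freqs[i])
            calls[site][:, l, :] = draws + 1  # allele IDs are 1-based

    if config.missing_rate > 0:
        for site in site_ids:
            mask = rng.random(calls[site].shape) < config.missing_rate
            calls[site][mask] = MISSING

    dataset = GenotypeDataset(sites=list(site_ids), loci=loci, calls=calls)
    order = np.lexsort((np.arange(n_sites), -expected_het))
    ranks = np.empty(n_sites, dtype=int)
    ranks[order] = np.arange(1, n_sites + 1)
    structure = TrueStructure(
        lineage_of_site={site_ids[i]: int(lineages[i]) for i in range(n_sites)},
        expected_diversity_rank={site_ids[i]: int(ranks[i]) for i in range(n_sites)},
        generating_params={"genotypes": asdict(config)},
    )
    return dataset, structure
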