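"""Designed synthetic study conditions.

Three named scenarios isolate the mechanisms the evaluation is about:

* ``lineage_structured`` — several spatially clustered genetic lineages with
  isolation by distance inside them.  Genetic-distance prioritizations
  should dominate; geographic/resistance spreading should beat random but
  miss lineage boundaries.
* ``stability_driven`` — a single lineage whose site-level diversity tracks
  long-term environmental suitability (drift erodes diversity outside
  refugia).  Suitability-ranked prioritizations should beat random.
* ``admixture_driven`` — two lineages with a wide contact zone; admixed
  sites carry alleles of both lineages and hence high allelic richness that
  suitability cannot see.  Suitability-ranked prioritizations should be
  indistinguishable from random.

Each factory returns (LandscapeConfig, GenotypeConfig) for one seed; sizes
default to a compact grid and site count so hundred-seed Monte-Carlo runs
stay cheap while keeping the Table-1-like envelope (>=10 sites, >=10
samples, >=6 loci).
"""

from __future__ import annotations

from .synthetic import GenotypeConfig, LandscapeConfig

_GRID = dict(grid_rows=40, grid_cols=40, cell_size=10_000.0, n_periods=4)


def lineage_structured(seed: int, n_sites: int = 14) -> tuple[LandscapeConfig, GenotypeConfig]:
    landscape = LandscapeConfig(**_GRID, stability=0.85, smoothness=5.0, seed=seed)
    genotypes = GenotypeConfig(
        n_sites=n_sites,
        samples_per_site=(10, 20),
        n_loci=(10, 10),
        alleles_per_locus=(4, 10),
        n_lineages=3,
        ibd_scale=120_000.0,
        stability_effect=0.0,
        admixture_width=0.0,
        noise_sd=0.5,
        missing_rate=0.02,
        seed=seed + 1,
    )
    return landscape, genotypes


def stability_driven(seed: int, n_sites: int = 14) -> tuple[LandscapeConfig, GenotypeConfig]:
    landscape = LandscapeConfig(
        **_GRID, stability=0.7, smoothness=4.0, refugia_count=3, seed=seed
    )
    genotypes = GenotypeConfig(
        n_sites=n_sites,
        samples_per_site=(10, 20),
        n_loci=(10, 10),
        alleles_per_locus=(4, 10),
        n_lineages=1,
        ibd_scale=200_000.0,
        stability_effect=2.0,
        admixture_width=0.0,
        noise_sd=0.3,
        missing_rate=0.02,
        seed=seed + 1,
    )
    return landscape, genotypes


def admixture_driven(seed: int, n_sites: int = 14) -> tuple[LandscapeConfig, GenotypeConfig]:
    landscape = LandscapeConfig(**_GRID, stability=0.85, smoothness=5.0, seed=seed)
    genotypes = GenotypeConfig(
        n_sites=n_sites,
        samples_per_site=(10, 20),
        n_loci=(10, 10),
        alleles_per_locus=(4, 10),
        n_lineages=2,
        ibd_scale=150_000.0,
        stability_effect=0.0,
        admixture_width=150_000.0,
        noise_sd=0.4,
        missing_rate=0.02,
        seed=seed + 1,
    )
    return landscape, genotypes


SCENARIOS = {
    "lineage_structured": lineage_structured,
    "stability_driven": stability_driven,
    "admixture_driven": admixture_driven,
}
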