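"""Compute site-level and broad-scale genetic diversity metrics.

Rarefied allelic richness summarizes within-site diversity at a common
sample depth; pairwise Jost's D summarizes how different the allele pools
of two sites are (0 = identical, 1 = no shared alleles).
"""

from gensurr import (
    GenotypeConfig,
    LandscapeConfig,
    allele_counts,
    jost_d_pairwise,
    make_landscape,
    place_sites,
    rarefied_allelic_richness,
    simulate_genotypes,
)

landscape = make_landscape(LandscapeConfig(grid_rows=30, grid_cols=30, seed=7))
sites = place_sites(landscape, n_sites=10, min_separation=20_000.0, seed=8)
genotypes, _ = simulate_genotypes(
    sites, landscape, GenotypeConfig(n_sites=10, n_lineages=2, seed=9)
)

counts = allele_counts(genotypes)
richness = rarefied_allelic_richness(counts, g="auto")
print("rarefied allelic richness per site (expected alleles at the shared depth):")
print(richness.series.round(2).to_string())

d = jost_d_pairwise(genotypes)
print("\npairwise Jost's D (differentiation; note the two-lineage block structure):")
print(d.to_frame().round(2).to_string())
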