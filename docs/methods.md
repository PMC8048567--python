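# Methods

This note documents the models, estimators, numerical choices and design
decisions behind `gensurr`, and what the synthetic data do and do not
establish.

## Genetic diversity metrics

**Rarefied allelic richness.** Missing allele calls are excluded from
counts, so a half-missing genotype contributes one copy. Rarefaction uses
one global draw size `g` per dataset — the minimum observed copy count over
all site-by-locus cells — rather than a per-locus size, because the site
scores are compared *across sites* and must share a common depth. The
per-locus expectation is computed with exact integer binomials
(`math.comb` via `fractions.Fraction`), so it agrees with exhaustive
enumeration to machine precision; rarefying to a `g` larger than some
cell's copy count is an error (one cannot rarefy upward).

**Pairwise Jost's D.** Each pair of sites is treated as a two-population
system per locus, with the sample-size-corrected heterozygosity estimates
given in the README. Sample size in individuals is observed copies / 2 and
may be fractional under missing data; the pair's `ñ` is the harmonic mean
of the two. Conventions, where common implementations differ:

* per-locus estimates are clamped into [0, 1] before combining — negative
  finite-sample estimates mean "no detectable differentiation";
* loci are combined by the arithmetic mean of clamped values by default; a
  harmonic-mean variant is available (`combine="harmonic"`) since both
  conventions circulate. The harmonic mean is driven toward zero by any
  undifferentiated locus, which is why it is not the default;
* loci monomorphic across both members of a pair contribute D = 0 rather
  than being dropped, so all pairs average over the same locus set;
* a locus whose within-pair heterozygosity estimate is exactly 1 has an
  undefined estimator and is dropped for that pair with a warning.

## Surrogate layers

**Long-term suitability** is the harmonic mean of the site's cell value
over all periods. Suitabilities are floored at 1e-6 inside the harmonic
mean purely to avoid division by zero; the floor is deliberately far below
the 1e-5 resistance clamp, which is a modeling constant rather than a
numerical guard.

**Resistance distances.** The conductance graph assigns each non-NODATA
cell a conductance `max(suitability, 1e-5)` (i.e. resistance is clamped
inverse suitability). Neighboring cells are connected with edge
conductance equal to the arithmetic mean of the two cell conductances;
with the default 8-connectivity, diagonal edges are divided by √2 to
correct for their longer span. 4-connectivity is available. The focal node
for a site is the single cell containing its coordinates. Effective
resistance is computed by grounding one focal node, factorizing the
reduced Laplacian once (sparse LU), and performing one solve per focal
node — n solves, not n², with all pairwise resistances assembled from the
grounded inverse entries. The result is independent of the ground choice
(verified to 1e-8 in tests) and matches the Laplacian pseudo-inverse
identity R_ij = L⁺_ii + L⁺_jj − 2 L⁺_ij. If the raster has disconnected
islands the computation restricts to the component containing the focal
sites; focal sites in different components are an error naming the pair.

## Prioritization

The distance-based reserve-selection problem is interpreted as the
discrete p-median on the site-by-site distance matrix: choose k sites
minimizing the summed distance from every site to its nearest selected
site. Planning units are sampling sites, not grid cells. The exact solver
is the standard integer program (binary open/assignment variables, each
site assigned to exactly one open site, assignments only to open sites,
exactly k open) solved with HiGHS at a zero relative MIP gap, so solutions
are certified global optima; ties between alternative optima are resolved
arbitrarily by the solver, and any optimal set is accepted. A brute-force
enumerator (`solve_ed_brute`) provides an independent exact method for
C(n, k) ≤ 500,000 and is used as the oracle in tests. Rank-based series
break score ties by ascending site ID, making them deterministic and
nested; optimal series need not be nested.

## Performance metrics

Site-level: the percentile threshold on allelic richness uses linear
interpolation of order statistics and a ≥ comparison, so the top-scoring
site is always in the high set. Capture is the fraction of high sites
selected.

Broad-scale: performance = max(0, 1 − A/B) where A is the selection's
p-median objective on the genetic distances and B is the mean single-site
objective — the expected objective of a uniformly random one-site
prioritization. This baseline yields 100% for a full selection, lets
particularly poor selections go negative before clamping (analogous to
negative R² values), and requires no centroid in the non-Euclidean genetic
space. It is one pluggable function (`broadscale_baseline`); other
normalizations can be swapped in.

Summaries report, per surrogate method: performance relative to the
genetic-data method (percent) and improvement over the random-replicate
mean (percentage points), over all k and over the "realistic" window
(selections up to 25% of sites), with seeded bootstrap 95% CIs over the
pooled per-k values. k values where the reference performance is zero are
skipped in the relative ratio. Performance-curve modeling with mixed
models is out of scope; the summaries are descriptive means and SDs plus
the bootstrap comparison.

## Association statistics

**Spearman test.** rho is the Pearson correlation of mid-ranks. The
one-sided p-value (H1: rho > 0) is exact by full permutation enumeration
for n ≤ 9 and uses the t-approximation with n − 2 df otherwise.

**MLPE.** The pairwise regression y_ij = β0 + β1 x_ij + u_i + u_j + ε_ij
has marginal covariance V = σ²_e I + σ²_u Z Zᵀ with Z the pair-membership
incidence matrix. Estimation is maximum likelihood (not REML), profiling
over the variance ratio φ = σ²_u/σ²_e on [0, 1000] with bounded Brent
search from a deterministic start; Z Zᵀ is diagonalized once so each
profile step is O(m²). The predictor is z-standardized by default
(`standardize=False` for raw-scale slopes). R²β follows the Wald-F
construction: with q = 1 and ν = m − 2, R²β = (F/ν)/(1 + F/ν). Exact
boundary fits (φ = 0) are snapped when the boundary likelihood is at least
as good. Non-convergence is reported in the `converged` flag rather than
raised.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the evaluation needs,
at the scale of the study system it emulates: 10–37 sites per species,
10–30 samples per site, 6–20 microsatellite loci, a contemporary plus
several historical suitability layers on a metric grid (default 10 km
cells).

* **Landscape**: latent Gaussian fields (smoothed white noise, spatial
  correlation length `smoothness` in cells) follow an AR(1) process across
  periods with coefficient `stability`; each period is rank-transformed to
  [0, 1]. This was chosen over FFT-based Gaussian random fields for
  simplicity and exact reproducibility. Refugia are disjoint 3×3
  neighborhoods forced to ≥ 0.8 suitability in every period.
* **Genotypes**: k-means on coordinates assigns sites to lineages (labels
  re-indexed by site order, so they are stable); each lineage gets
  independent Dirichlet(0.8) ancestral frequencies per locus; site
  frequencies perturb lineage frequencies on the log scale with
  multivariate Gaussian noise whose between-site correlation decays as
  exp(−d/`ibd_scale`) (d Euclidean, or resistance rescaled to the
  geographic mean so the scale keeps metric meaning); drift shrinks each
  site's frequencies toward its locally dominant allele by
  (1 − long-term suitability) × `stability_effect`, capped at 0.9; sites
  within `admixture_width` of another lineage mix frequencies with their
  nearest other-lineage site (weight up to 0.5 at zero distance); allele
  copies are drawn under within-site Hardy–Weinberg equilibrium; calls are
  masked at `missing_rate` per allele copy.

Not emulated: coalescent or forward-time demography, mutation-model
realism (SMM/IAM), selection, null alleles and scoring artifacts, and
linkage/genotypic disequilibrium. Passing tests therefore demonstrate that
the pipeline recovers the structure this generative model encodes — not
that any surrogate works on real landscapes; that question can only be
settled with field data.

The three designed scenarios (`gensurr.scenarios`) isolate one mechanism
each: spatially clustered lineages (broad-scale surrogates should work
partially), stability-driven drift (suitability ranking should work), and
a wide admixture zone (suitability ranking should carry no information,
because contact-zone populations have high richness that the landscape
cannot reveal).

## Problem sizes and seeds

Default study conditions use 1,000 random prioritization replicates per k.
Monte-Carlo checks of the designed scenarios use 100 seeds per scenario
with 14 sites, 10 loci and a 40×40-cell landscape, and 100 random
replicates for the baseline mean — sizes chosen so each hundred-seed batch
completes in a couple of minutes while keeping every component inside the
envelope above. The multi-species experiment in `scripts/acceptance.py`
uses 8 species with site counts drawn in 10–24. All randomness flows from
explicit integer seeds through named seed streams
(`gensurr.pipeline.stage_seed`); nothing reads the wall clock.

## Known limitations

* The discrete p-median reading of the distance-based reserve-selection
  problem is an interpretive choice; continuous environmental-diversity
  variants with demand points are not implemented.
* The broad-scale baseline B (mean single-site objective) is this
  package's documented normalization; other published normalizations may
  scale performance differently.
* MLPE standard errors are Wald/ML-based; with few sites they can be
  mildly anticonservative (coverage is verified by simulation at 25
  sites).
* GENEPOP export uses the 3-digit dialect, capping allele IDs at 999.
* No multi-species joint prioritization: species are analyzed separately,
  and pooled summaries aggregate per-species curves.
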