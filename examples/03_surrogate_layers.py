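"""Build the three surrogate layers from the landscape alone.

Long-term suitability (harmonic mean over periods) stands in for site-level
diversity; geographic and circuit-theory resistance distances stand in for
genetic distances.  None of these uses genotype data.
"""

from gensurr import (
    LandscapeConfig,
    geographic_distances,
    longterm_suitability,
    make_landscape,
    place_sites,
    resistance_from_stack,
)

landscape = make_landscape(
    LandscapeConfig(grid_rows=30, grid_cols=30, n_periods=4, refugia_count=2, seed=21)
)
sites = place_sites(landscape, n_sites=8, min_separation=30_000.0, seed=22)

suit = longterm_suitability(landscape, sites)
print("long-term suitability (harmonic mean across periods; high = stable refugium):")
print(suit.series.round(3).to_string())

geo = geographic_distances(sites)
print("\ngeographic distance, km:")
print((geo.to_frame() / 1000).round(0).to_string())

res = resistance_from_stack(landscape, sites)
print("\nresistance distance (effective resistance through the suitability surface):")
print(res.to_frame().round(2).to_string())
print("\nhigh resistance between nearby sites means unsuitable habitat lies between them")
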