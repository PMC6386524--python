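"""Compute and export the MGC-Map of a quadratic relationship.

The map holds one local correlation per neighborhood-size pair (k, l);
its shape distinguishes linear from nonlinear dependence at a glance.
Writes a TSV of the map and (if matplotlib can render) a PNG heat map.
"""

from mgcorr import (
    SimulationSpec,
    mgc_statistic_from_distances,
    pairwise_distances,
    plot_mgc_map,
    sample_relationship,
    write_map,
)

pair = sample_relationship(SimulationSpec(type_id=6, n=50, p=1, kappa=1, seed=3))
Dx, Dy = pairwise_distances(pair.X), pairwise_distances(pair.Y)
c_star, scales, C, region = mgc_statistic_from_distances(Dx, Dy)

write_map(C, "quadratic_map.tsv")
plot_mgc_map(C, path="quadratic_map.png")

k, l = scales[0]
print(f"MGC statistic          : {c_star:.4f} at scale ({k}, {l})")
print(f"global correlation     : {C[-1, -1]:.4f} at scale (50, 50)")
print(f"significant region size: {region.size} scales above tau={region.tau:.4f}")
print()
print("The statistic exceeding the global correlation means a neighborhood-")
print("restricted correlation amplifies this nonlinear dependence.")
print("Wrote quadratic_map.tsv and quadratic_map.png.")
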