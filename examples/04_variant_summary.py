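"""Per-sample SNP/indel summary from a simulated 4-sample variant table.

Plants a known indel length spectrum and impact annotations, then summarizes
transitions/transversions, zygosity and the indel histogram per sample.
"""

from bsascan import (
    DepthModel, GenomeModel, impact_tally, indel_length_spectrum,
    simulate_bulk_depths, simulate_cross, summary_table,
)

genome = GenomeModel.default()
pop = simulate_cross(genome, 200, seed=11)
sites, truth = simulate_bulk_depths(
    pop, pop.ids[:30], pop.ids[30:60], DepthModel(mean_depth=40), seed=12,
    impacts={"HIGH": 6, "MODERATE": 12, "LOW": 20},
    indel_lengths={1: 15, 2: 8, 3: 4, -1: 12, -2: 6, -3: 3})

print(summary_table(sites).to_string(index=False))
print("\ndonor indel spectrum (signed length -> count):")
print(dict(sorted(indel_length_spectrum(sites, "donor").items())))
print("\ndonor impact tally:", impact_tally(sites, "donor"))
print("(planted HIGH=6, MODERATE=12, LOW=20; the rest are MODIFIER)")
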