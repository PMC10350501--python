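"""Correlated seedling traits, descriptive statistics, and bulk construction.

Seven traits (SL, RL, SFW, RFW, SDW, RDW, CHL) are drawn with the default
stressed-seedling means/SDs and correlation structure; a planted QTL adds one
phenotypic SD per donor-allele copy to SFW, SDW and RFW.  Bulks are the 30
highest- and 30 lowest-ranked lines by mean z-score over those three traits.
"""

from bsascan import (
    GenomeModel, QTLSpec, correlation_matrix, replicate_table,
    select_bulks, simulate_cross, simulate_traits, trait_stats_table,
)

genome = GenomeModel.default()
pop = simulate_cross(genome, 200, seed=3)
qtl = QTLSpec.default(genome)
table = replicate_table(simulate_traits(pop, qtl, seed=4), n_replicates=3, seed=5)

stats = trait_stats_table(table)
print(stats.round(2).to_string(index=False))

corr = correlation_matrix(table)
print("\nSFW-SDW correlation:",
      f"r = {corr.r.loc['SFW', 'SDW']:.3f}{corr.stars.loc['SFW', 'SDW']}",
      "(generator correlation 0.929)")

sel = select_bulks(table, n=30)
print("\nbulk trait ranges (line means):")
print(sel.range_table().round(2).to_string(index=False))
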