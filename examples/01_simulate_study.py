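"""Simulate a BC2F2 mapping population and check its pedigree expectation.

Two backcrosses to the recurrent parent followed by one selfing leave each
marker with an expected donor-allele frequency of (1/2)^3 = 0.125.
"""

import numpy as np

from bsascan import GenomeModel, simulate_cross

genome = GenomeModel.default()  # 3 chromosomes x 2 Mb, 400 SNP markers each
pop = simulate_cross(genome, n_offspring=2_000, seed=1)

print(f"population: {pop.n} {pop.generation} individuals")
for chrom in genome.chrom_names:
    f = pop.donor_frequency(chrom)
    print(f"  {chrom}: mean donor-allele frequency {f.mean():.4f} "
          f"(pedigree expectation 0.125)")

dos = pop.dosages["chr1"][:, 200]
counts = np.bincount(dos, minlength=3)
print(f"dosage counts at one chr1 marker (0/1/2): {counts.tolist()} "
      f"(expected near {2000 * 13 / 16:.0f}/{2000 / 8:.0f}/{2000 / 16:.0f})")
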