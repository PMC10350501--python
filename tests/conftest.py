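import numpy as np
import pytest

from bsascan import DepthModel, GenomeModel, Population, simulate_cross


@pytest.fixture(scope="session")
def genome():
    return GenomeModel.default(seed=0)


@pytest.fixture(scope="session")
def small_pop(genome):
    return simulate_cross(genome, 200, seed=11)


@pytest.fixture()
def het_population():
    """A population where every individual is heterozygous at every marker (f=0.5)."""
    g = GenomeModel.default(n_chromosomes=1, chrom_length=1_000_000,
                            markers_per_chrom=2_000, seed=2)
    n = 40
    dosages = {c: np.ones((n, g.n_markers(c)), dtype=np.int8) for c in g.chrom_names}
    return Population(g, "BC2F2", [f"H{i}" for i in range(n)], dosages)


@pytest.fixture()
def depth_model():
    return DepthModel(mean_depth=40.0, error_rate=0.0)
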