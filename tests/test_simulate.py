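"""Generator tests: pedigree expectations, trait model, bulk depths, FASTQ truth."""

import numpy as np
import pandas as pd
import pytest

from bsascan import (
    DepthModel,
    FastqDefects,
    GenomeModel,
    Population,
    QTLSpec,
    select_bulks,
    simulate_bulk_depths,
    simulate_cross,
    simulate_traits,
    synth_fastq,
)
from bsascan.simulate import TRAITS, default_trait_cov


def expected_bc2f2_dosage_distribution():
    """Exhaustive single-locus pedigree enumeration through the crossing scheme.

    Returns P(dosage = 0, 1, 2) for a BC2F2 individual at an unlinked marker.
    """
    # genotype distributions as dicts dosage -> prob, starting from F1 (het)
    def backcross(dist):  # cross to recurrent parent (all dosage 0)
        out = {0: 0.0, 1: 0.0}
        for d, p in dist.items():
            # gamete carries donor allele with prob d/2
            out[1] += p * (d / 2)
            out[0] += p * (1 - d / 2)
        return out

    def self_(dist):
        out = {0: 0.0, 1: 0.0, 2: 0.0}
        for d, p in dist.items():
            q = d / 2  # donor-allele transmission prob per gamete
            out[0] += p * (1 - q) ** 2
            out[1] += p * 2 * q * (1 - q)
            out[2] += p * q * q
        return out

    f1 = {1: 1.0}
    bc1 = backcross(f1)
    bc2 = backcross(bc1)
    return self_(bc2)


class TestCross:
    def test_exhaustive_pedigree_expectation(self):
        dist = expected_bc2f2_dosage_distribution()
        mean_f = sum(d * p for d, p in dist.items()) / 2
        assert mean_f == pytest.approx(0.125)
        assert dist == pytest.approx({0: 13 / 16, 1: 1 / 8, 2: 1 / 16})

    def test_donor_frequency_matches_pedigree(self, genome):
        pop = simulate_cross(genome, 4_000, seed=5)
        # per-individual donor fraction at one marker; binomial-style s.e.
        freq = pop.donor_frequency("chr1")[::50]
        se = np.sqrt(0.3125 / 4) / np.sqrt(4_000)  # sd(dosage)/2 / sqrt(n)
        assert np.all(np.abs(freq - 0.125) < 4 * se)

    def test_selfing_ratio_is_1_2_1(self, genome):
        pop, ped = simulate_cross(genome, 6_000, seed=7, return_pedigree=True)
        m = 100
        het_parents = ped["chr1"][:, m] == 1
        assert het_parents.sum() > 1_000
        dosages = pop.dosages["chr1"][het_parents, m]
        counts = np.bincount(dosages, minlength=3)
        frac = counts / counts.sum()
        assert np.allclose(frac, [0.25, 0.5, 0.25], atol=0.04)

    def test_parents_and_f1_invariants(self, genome):
        # homozygous donor transmits the donor allele at every marker
        from bsascan.simulate import _gamete
        rng = np.random.default_rng(0)
        m = genome.n_markers("chr1")
        ones = np.ones(m, dtype=np.int8)
        g = _gamete(ones, ones, genome.markers["chr1"], genome.lengths["chr1"], 1.0, rng)
        assert np.all(g == 1)

    def test_deterministic_under_seed(self, genome):
        a = simulate_cross(genome, 50, seed=42)
        b = simulate_cross(genome, 50, seed=42)
        for c in genome.chrom_names:
            np.testing.assert_array_equal(a.dosages[c], b.dosages[c])

    def test_rejects_bad_inputs(self, genome):
        with pytest.raises(ValueError):
            simulate_cross(genome, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_cross(genome, 5, seed=1, scheme=("P1xP2->F1",))


class TestTraits:
    def test_zero_noise_zero_effect_gives_base_means(self, small_pop):
        traits = simulate_traits(small_pop, qtl=None, cov=np.zeros((7, 7)), seed=0)
        for t in TRAITS:
            assert np.allclose(traits[t], traits[t].iloc[0])

    def test_additive_effect_closed_form(self, genome):
        pop = simulate_cross(genome, 5_000, seed=3)
        qtl = QTLSpec("chr1", int(genome.markers["chr1"][10]), {"SFW": 3.0})
        traits = simulate_traits(pop, qtl, seed=4)
        dos = pop.dosage_at("chr1", qtl.pos)
        m2 = traits["SFW"].to_numpy()[dos == 2].mean()
        m0 = traits["SFW"].to_numpy()[dos == 0].mean()
        sd = default_trait_cov()[2, 2] ** 0.5
        se = sd * np.sqrt(1 / (dos == 2).sum() + 1 / (dos == 0).sum())
        assert abs((m2 - m0) - 6.0) < 3 * se

    def test_correlation_oracle(self, genome):
        pop = simulate_cross(genome, 5_000, seed=8)
        corr = np.eye(7)
        corr[2, 4] = corr[4, 2] = 0.9  # SFW-SDW
        sd = np.ones(7)
        cov = np.outer(sd, sd) * corr
        # large means so the zero-truncation never bites
        means = {t: 100.0 for t in TRAITS}
        traits = simulate_traits(pop, None, base_means=means, cov=cov, seed=9)
        r = np.corrcoef(traits["SFW"], traits["SDW"])[0, 1]
        assert abs(r - 0.9) < 0.03

    def test_truncation_and_validation(self, small_pop):
        traits = simulate_traits(small_pop, seed=1)
        for t in ("SL", "RL", "SFW", "RFW", "SDW", "RDW"):
            assert (traits[t] >= 0).all()
        with pytest.raises(ValueError):
            simulate_traits(small_pop, cov=-np.eye(7))
        with pytest.raises(ValueError):
            QTLSpec("chr1", 100, {"SFW": 0.0})
        with pytest.raises(ValueError):
            simulate_traits(small_pop, QTLSpec("chr1", 123456789, {"SFW": 1.0}))


class TestBulkDepths:
    def test_all_recurrent_bulk_zero_donor_depth(self, genome):
        n = 20
        dosages = {c: np.zeros((n, genome.n_markers(c)), dtype=np.int8)
                   for c in genome.chrom_names}
        pop = Population(genome, "BC2F2", [f"I{i}" for i in range(n)], dosages)
        dm = DepthModel(mean_depth=30, error_rate=0.0)
        sites, _ = simulate_bulk_depths(pop, [f"I{i}" for i in range(10)],
                                        [f"I{i}" for i in range(10, 20)], dm, seed=0)
        assert (sites["AD:bulk_res"] == 0).all()
        assert (sites["AD:bulk_sus"] == 0).all()

    def test_binomial_mean_at_half(self, het_population):
        dm = DepthModel(mean_depth=40, error_rate=0.0)
        ids = het_population.ids
        sites, truth = simulate_bulk_depths(het_population, ids[:20], ids[20:], dm, seed=1)
        idx = sites["AD:bulk_res"] / (sites["AD:bulk_res"] + sites["RD:bulk_res"])
        assert (truth["f_res"] == 0.5).all()
        assert abs(idx.mean() - 0.5) < 0.01  # binomial s.e. ~ 0.0018 over 2000 sites

    def test_selected_bulks_enrich_qtl_allele(self, genome):
        pop = simulate_cross(genome, 400, seed=21)
        qtl = QTLSpec.default(genome)
        traits = simulate_traits(pop, qtl, seed=22)
        from bsascan.simulate import replicate_table
        bulks = select_bulks(replicate_table(traits, 2, seed=23), n=30)
        f_res = pop.donor_frequency(qtl.chrom, bulks.resistant)
        f_sus = pop.donor_frequency(qtl.chrom, bulks.susceptible)
        qi = genome.marker_index(qtl.chrom, qtl.pos)
        assert f_res[qi] > f_sus[qi]

    def test_planted_impacts_and_indels_recorded(self, small_pop):
        dm = DepthModel(mean_depth=20)
        sites, truth = simulate_bulk_depths(
            small_pop, small_pop.ids[:30], small_pop.ids[30:60], dm, seed=2,
            impacts={"HIGH": 5, "MODERATE": 3}, indel_lengths={2: 4, -3: 6})
        assert (sites["impact"] == "HIGH").sum() == 5
        assert (sites["impact"] == "MODERATE").sum() == 3
        assert (sites["vclass"] == "INS").sum() == 4
        assert (sites["vclass"] == "DEL").sum() == 6
        assert truth["is_qtl"].sum() == 0

    def test_bulk_validation(self, small_pop, depth_model):
        with pytest.raises(ValueError):
            simulate_bulk_depths(small_pop, small_pop.ids[:5], small_pop.ids[:5],
                                 depth_model, seed=0)
        with pytest.raises(KeyError):
            simulate_bulk_depths(small_pop, ["nope"], small_pop.ids[:5],
                                 depth_model, seed=0)


class TestSynthFastq:
    def test_clean_reads_have_full_quality(self):
        reads, truth = synth_fastq(50, 100, FastqDefects(), seed=0)
        assert (truth["category"] == "clean").all()
        assert all(q == chr(40 + 33) * 100 for _, _, q in reads)

    def test_defect_proportions_and_truth(self):
        defects = FastqDefects(p_adapter=0.2, p_low3=0.2, p_n=0.2)
        reads, truth = synth_fastq(500, 150, defects, seed=3)
        assert set(truth["category"]) == {"adapter", "low3", "n_run", "clean"}
        assert (~truth.loc[truth["category"] == "n_run", "expect_kept"]).all()
        alen = len(defects.adapter)
        exp = truth.loc[truth["category"] == "adapter", "expect_len"]
        assert (exp == 150 - alen).all()

    def test_deterministic(self):
        a, ta = synth_fastq(30, 80, FastqDefects(p_low5=0.5), seed=9)
        b, tb = synth_fastq(30, 80, FastqDefects(p_low5=0.5), seed=9)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_read_len_validation(self):
        with pytest.raises(ValueError):
            synth_fastq(5, 0)
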