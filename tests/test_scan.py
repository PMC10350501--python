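"""SNP-index, window, null-threshold and region-calling tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bsascan import (
    NullModel,
    attach_thresholds,
    call_candidate_regions,
    delta_snp_index,
    filter_informative_sites,
    null_thresholds,
    region_length_mb,
    sliding_windows,
    snp_index,
)
from bsascan.scan import _level_col, regions_to_bed
from bsascan.variants import ad_col, gt_col, rd_col


def site_row(chrom, pos, gt_donor, gt_rec, depths):
    """One 4-sample site; depths = (rd_res, ad_res, rd_sus, ad_sus)."""
    row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G", "vclass": "SNP",
           "impact": None, "consequence": None}
    for s, gt in (("donor", gt_donor), ("recurrent", gt_rec)):
        row[gt_col(s)] = gt
        row[rd_col(s)] = 20
        row[ad_col(s)] = 20
    for s, (rd, ad) in zip(("bulk_res", "bulk_sus"),
                           [depths[:2], depths[2:]]):
        row[gt_col(s)] = "0/1"
        row[rd_col(s)] = rd
        row[ad_col(s)] = ad
    return row


class TestIndices:
    def test_corner_cases(self):
        assert snp_index(7, 0) == 1.0
        assert snp_index(5, 5) == 0.5
        assert snp_index(0, 9) == 0.0
        assert delta_snp_index(1, 0) == 1
        assert delta_snp_index(0.5, 0.5) == 0
        assert delta_snp_index(0, 1) == -1

    def test_zero_depth_and_bounds(self):
        with pytest.raises(ValueError):
            snp_index(0, 0)
        with pytest.raises(ValueError):
            delta_snp_index(1.2, 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_index_bounds_fuzzed(self, m, w):
        if m + w == 0:
            return
        idx = snp_index(m, w)
        assert 0.0 <= idx <= 1.0
        assert -1.0 <= delta_snp_index(idx, 1 - idx) <= 1.0


class TestFilter:
    def test_depth_and_informativeness_rules(self):
        sites = pd.DataFrame([
            site_row("c1", 100, "1/1", "0/0", (4, 5, 15, 15)),   # res depth 9 -> drop
            site_row("c1", 200, "1/1", "1/1", (20, 20, 20, 20)),  # same genotype -> drop
            site_row("c1", 300, "1/1", "0/0", (10, 30, 20, 20)),  # keep
            site_row("c1", 400, "./.", "0/0", (20, 20, 20, 20)),  # missing parent -> drop
            site_row("c1", 500, "0/0", "1/1", (30, 10, 5, 35)),   # keep, donor = ref
        ])
        rec, drops = filter_informative_sites(sites, "bulk_res", "bulk_sus",
                                              "donor", "recurrent", min_depth=10)
        assert list(rec["pos"]) == [300, 500]
        assert drops["low_depth"] == 1
        assert drops["non_informative"] == 1
        assert drops["missing_parent_gt"] == 1
        # orientation: when donor is 1/1 DepM is the alt depth, else the ref depth
        assert rec.loc[rec["pos"] == 300, "index_res"].iloc[0] == pytest.approx(30 / 40)
        assert rec.loc[rec["pos"] == 500, "index_res"].iloc[0] == pytest.approx(30 / 40)

    def test_planted_informative_count(self, small_pop, depth_model):
        from bsascan import simulate_bulk_depths
        sites, _ = simulate_bulk_depths(small_pop, small_pop.ids[:30],
                                        small_pop.ids[30:60], depth_model, seed=7)
        rec, drops = filter_informative_sites(sites, "bulk_res", "bulk_sus",
                                              "donor", "recurrent", min_depth=10)
        # every simulated marker is parent-polymorphic; only depth can drop sites
        assert len(rec) + drops["low_depth"] + drops["zero_depth"] == len(sites)


class TestWindows:
    def test_single_site_mean(self):
        rec = pd.DataFrame({"chrom": ["c1"], "pos": [500_000],
                            "depm_res": [20], "depw_res": [20],
                            "depm_sus": [20], "depw_sus": [20],
                            "index_res": [0.9], "index_sus": [0.5], "delta": [0.4]})
        win = sliding_windows(rec, {"c1": 1_000_000}, window=1_000_000,
                              step=5_000, min_sites=1)
        covering = win.loc[win["n_sites"] == 1]
        assert len(covering) > 0
        assert np.allclose(covering["mean_delta"], 0.4)

    def test_window_means_match_bruteforce_oracle(self):
        rng = np.random.default_rng(31)
        n = 1_000
        pos = np.sort(rng.choice(2_000_000, n, replace=False)) + 1
        delta = rng.uniform(-1, 1, n)
        idx_res = rng.uniform(0, 1, n)
        rec = pd.DataFrame({"chrom": "c1", "pos": pos,
                            "depm_res": 20, "depw_res": 20,
                            "depm_sus": 20, "depw_sus": 20,
                            "index_res": idx_res, "index_sus": idx_res - delta,
                            "delta": delta})
        win = sliding_windows(rec, {"c1": 2_000_000}, window=100_000,
                              step=7_000, min_sites=1)
        for row in win.sample(60, random_state=0).itertuples():
            in_win = (pos >= row.start) & (pos <= row.end)
            assert row.n_sites == in_win.sum()
            if row.n_sites:
                assert row.mean_delta == pytest.approx(delta[in_win].mean(), abs=1e-12)

    def test_window_step_validation_and_flags(self):
        rec = pd.DataFrame({"chrom": [], "pos": [], "depm_res": [], "depw_res": [],
                            "depm_sus": [], "depw_sus": [], "index_res": [],
                            "index_sus": [], "delta": []})
        with pytest.raises(ValueError):
            sliding_windows(rec, {"c1": 100}, window=10, step=20)
        win = sliding_windows(rec, {"c1": 1_500_000})
        assert win["partial"].any()
        assert win["masked"].all()  # no sites anywhere


class TestNullThresholds:
    def test_exact_enumeration_oracle_depth_10(self):
        """MC thresholds at depth (10,10), n=30 match exhaustive enumeration.

        Oracle: bulk frequency ~ Binomial(60, 1/2)/60 (sum of 30 iid 1:2:1
        dosages), read count ~ Binomial(10, f); |delta| CDF enumerated exactly.
        """
        n, d = 30, 10
        pf = sps.binom.pmf(np.arange(2 * n + 1), 2 * n, 0.5)
        fs = np.arange(2 * n + 1) / (2 * n)
        pk = (pf[:, None] * sps.binom.pmf(np.arange(d + 1)[None, :], d, fs[:, None])).sum(axis=0)
        joint = np.outer(pk, pk)
        dvals = np.abs(np.subtract.outer(np.arange(d + 1), np.arange(d + 1))) / d
        order = np.argsort(dvals.ravel(), kind="stable")
        xs, ps = dvals.ravel()[order], joint.ravel()[order]
        cdf = np.cumsum(ps)
        exact_q95 = xs[np.searchsorted(cdf, 0.95)]
        exact_q99 = xs[np.searchsorted(cdf, 0.99)]

        nm = NullModel(n_bulk=30, replicates=200_000)
        thr = null_thresholds(nm, [(10, 10)], seed=2)
        assert thr[_level_col(0.95)].iloc[0] == pytest.approx(exact_q95, abs=0.01)
        assert thr[_level_col(0.99)].iloc[0] == pytest.approx(exact_q99, abs=0.01)

    def test_thresholds_shrink_with_depth(self):
        nm = NullModel(replicates=20_000)
        thr = null_thresholds(nm, [(10, 10), (40, 40), (100, 100)], seed=3)
        q95 = thr.sort_values("depth_res")[_level_col(0.95)].to_numpy()
        assert q95[0] > q95[-1]
        assert (np.diff(q95) <= 1e-12).all()  # isotonic: non-increasing

    def test_null_delta_centered_at_zero(self):
        from bsascan.scan import _simulate_null_delta
        nm = NullModel(replicates=50_000)
        deltas = _simulate_null_delta(nm, 1_000, 1_000, np.random.default_rng(4))
        assert abs(deltas.mean()) < 0.002

    def test_zero_depth_masked(self):
        nm = NullModel()
        thr = null_thresholds(nm, [(0, 10)], seed=0)
        assert np.isnan(thr[_level_col(0.95)].iloc[0])

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            NullModel(replicates=10)


class TestRegions:
    def _windows_with_thresholds(self, sig_spans, chrom="chr18", length=70_000_000,
                                 step=5_000, window=1_000_000):
        """Windows whose mean delta is 0.6 inside sig_spans (start points) else 0."""
        starts = np.arange(1, length + 1, step, dtype=np.int64)
        # keep the table small: only windows near the significant spans
        keep = np.zeros(len(starts), bool)
        for lo, hi in sig_spans:
            keep |= (starts >= lo - 2 * window) & (starts <= hi + 2 * window)
        starts = starts[keep]
        ends = np.minimum(starts + window - 1, length)
        sig = np.zeros(len(starts), bool)
        for lo, hi in sig_spans:
            sig |= (starts >= lo) & (starts <= hi)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                           "n_sites": 50, "mean_index_res": 0.5, "mean_index_sus": 0.5,
                           "mean_delta": np.where(sig, 0.6, 0.0),
                           "mean_depth_res": 40.0, "mean_depth_sus": 40.0,
                           "masked": False, "partial": False})
        for level in (0.95, 0.99, 0.999):
            df[_level_col(level)] = 0.3
        return df

    def test_merge_and_geometry(self):
        win = self._windows_with_thresholds([(60_120_001, 60_980_001)])
        regions = call_candidate_regions(win, 0.999, step=5_000)
        assert len(regions) == 1
        r = regions[0]
        assert r.start == 60_120_001
        assert r.level == 0.999
        assert r.length_mb == region_length_mb(r.start, r.end)

    def test_no_significant_windows(self):
        win = self._windows_with_thresholds([])
        assert call_candidate_regions(win, 0.99, step=5_000) == []

    def test_distant_runs_stay_separate(self):
        win = self._windows_with_thresholds([(10_000_001, 11_000_001),
                                             (30_000_001, 31_500_001)])
        regions = call_candidate_regions(win, 0.99, step=5_000)
        assert len(regions) == 2

    def test_effective_variants_attached(self):
        win = self._windows_with_thresholds([(10_000_001, 11_000_001)])
        sites = pd.DataFrame({
            "chrom": ["chr18"] * 4, "pos": [10_100_000, 10_200_000, 10_300_000, 50_000_000],
            "ref": "A", "alt": "G",
            "impact": ["HIGH", "MODERATE", "MODIFIER", "HIGH"],
            "consequence": ["stop_gained", "missense_variant", None, "stop_gained"],
        })
        regions = call_candidate_regions(win, 0.99, step=5_000, sites=sites)
        eff = regions[0].effective_variants
        assert list(eff["pos"]) == [10_100_000, 10_200_000]  # MODIFIER and outside excluded

    def test_bed_output(self):
        win = self._windows_with_thresholds([(10_000_001, 11_000_001)])
        regions = call_candidate_regions(win, 0.99, step=5_000)
        bed = regions_to_bed(regions)
        chrom, start, end = bed.split("\t")[:3]
        assert chrom == "chr18" and int(start) == regions[0].start - 1
        assert int(end) == regions[0].end
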