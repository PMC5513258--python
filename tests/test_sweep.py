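"""Depth sweep, distribution comparisons, coverage diagnostics."""

import numpy as np
import pytest

import radpara as rp
from radpara.containers import Locus, PileSet

from conftest import rank_sum_permutation_pvalue


class TestCompareDistributions:
    def test_identical_samples_not_significant(self):
        x = np.linspace(0, 1, 50)
        _, p = rp.compare_distributions(x, x.copy())
        assert p > 0.99

    def test_known_shift_detected(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.1, 200)
        _, p = rp.compare_distributions(y + 0.3, y)
        assert p < 1e-6

    def test_rank_sum_statistic_matches_permutation_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        u_oracle, p_oracle = rank_sum_permutation_pvalue(x, y)
        stat, _ = rp.compare_distributions(x, y)
        assert stat == pytest.approx(u_oracle)
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert exact.pvalue == pytest.approx(p_oracle, abs=1e-12)

    def test_all_tied_p_is_one(self):
        _, p = rp.compare_distributions([1.0] * 5, [1.0] * 7)
        assert p == 1.0

    def test_paired_variant(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 80)
        _, p_null = rp.compare_distributions(y, y, paired=True)
        _, p_shift = rp.compare_distributions(y + 0.5, y, paired=True)
        assert p_null == 1.0
        assert p_shift < 1e-6
        with pytest.raises(ValueError):
            rp.compare_distributions([1.0, 2.0], [1.0], paired=True)


class TestCoverageByClass:
    def _uniform_pileset(self, depth_a=6, depth_b=12):
        piles = PileSet(individuals=["i1", "i2"])
        for lid, d in (("LA", depth_a), ("LB", depth_b)):
            counts = np.zeros((10, 2, 4), dtype=np.int64)
            counts[:, :, 0] = d
            piles.add_locus(Locus(lid, "A" * 10, counts))
        return piles

    def test_uniform_depth_recovered(self):
        piles = self._uniform_pileset()
        status = [rp.LocusParaStatus("LA", True, 1, 0), rp.LocusParaStatus("LB", False, 0, 1)]
        cov_p, cov_n, ratio = rp.coverage_by_class(piles, status)
        assert cov_p == pytest.approx(6.0)
        assert cov_n == pytest.approx(12.0)
        assert ratio == pytest.approx(0.5)

    def test_empty_class_ratio_undefined(self):
        piles = self._uniform_pileset()
        status = [rp.LocusParaStatus("LA", False, 0, 0), rp.LocusParaStatus("LB", False, 0, 0)]
        _, _, ratio = rp.coverage_by_class(piles, status)
        assert np.isnan(ratio)

    def test_two_copy_collapse_doubles_coverage(self):
        """copy_number=2 with equal per-copy rate: para/non-para depth ratio ~2."""
        cfg = rp.SimConfig(
            n_loci=250, locus_length=60, paralog_fraction=0.5, copy_number=2,
            coverage_mean=8.0, theta_sim=0.0, seed=12,
        )
        piles, truth = rp.simulate_dataset(cfg)
        _, _, ratio = rp.coverage_by_class(piles, truth.paralogs)
        assert 1.8 <= ratio <= 2.2


class TestRunDepthSweep:
    def test_monotone_called_genotypes_and_zero_depth_handling(self):
        piles, _ = rp.simulate_dataset(
            rp.SimConfig(n_loci=40, coverage_mean=5.0, paralog_fraction=0.0, seed=13)
        )
        res = rp.run_depth_sweep(
            piles, rp.SweepConfig(depths=(2, 20, 50), error_rate=0.005)
        )
        tab = res.table.set_index("min_depth")
        assert tab.loc[20, "n_called_genotypes"] <= tab.loc[2, "n_called_genotypes"]
        # far beyond coverage: reported with zero counts, not an error
        assert tab.loc[50, "n_snps"] == 0
        assert tab.loc[50, "n_loci"] == 0

    def test_paralog_free_simulation_low_para_rate(self):
        piles, _ = rp.simulate_dataset(
            rp.SimConfig(
                n_loci=120, paralog_fraction=0.0, coverage_mean=15.0,
                copy_number=2, error_rate=0.002, seed=14,
            )
        )
        res = rp.run_depth_sweep(piles, rp.SweepConfig(depths=(10,), error_rate=0.002))
        assert res.table.pct_para.iloc[0] <= 5.0

    def test_filtering_reduces_theta_and_high_maf(self, paralog_sweep):
        tab = paralog_sweep.table
        valid = tab.dropna(subset=["theta_all", "theta_nonpara"])
        assert (valid.theta_all >= valid.theta_nonpara - 1e-12).all()
        snp4 = paralog_sweep.snp_tables[4]
        para_ids = set(
            paralog_sweep.locus_status[4].query("is_paralog").locus_id
        )
        maf_all = snp4.maf.dropna()
        maf_np = snp4[~snp4.locus_id.isin(para_ids)].maf.dropna()
        hi = lambda s: (s.between(0.45, 0.5)).sum()
        # removing paralog loci never increases the number of near-0.5 MAFs
        assert hi(maf_np) <= hi(maf_all)

    def test_fis_median_moves_toward_zero_after_filtering(self, paralog_sweep):
        tab = paralog_sweep.table.set_index("min_depth")
        for depth in (4, 18):
            all_med = tab.loc[depth, "fis_median_all"]
            np_med = tab.loc[depth, "fis_median_nonpara"]
            assert abs(np_med) <= abs(all_med) + 1e-9

    def test_para_detection_rises_with_depth(self, paralog_sweep):
        tab = paralog_sweep.table.set_index("min_depth")
        assert tab.loc[18, "pct_para"] > tab.loc[4, "pct_para"]
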