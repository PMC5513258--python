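"""Nei diversity statistics: hand-computed checks and summary bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radpara as rp
from radpara.popgen import stats_from_call_indices

ALL_HET = ["AG"] * 9
MIXED = ["AA"] * 5 + ["AG"] * 3 + ["GG"]


class TestMAF:
    def test_all_heterozygous_is_half(self):
        assert rp.maf(ALL_HET) == pytest.approx(0.5, abs=1e-12)

    def test_monomorphic_is_zero(self):
        assert rp.maf(["AA"] * 9) == 0.0

    def test_direct_count(self):
        assert rp.maf(MIXED) == pytest.approx(5 / 18, abs=1e-12)

    def test_no_calls_is_nan(self):
        assert np.isnan(rp.maf([None, "./."]))


class TestNeiStats:
    def test_monomorphic(self):
        ho, hs, fis = rp.nei_stats(["AA"] * 5)
        assert ho == 0.0 and hs == 0.0 and np.isnan(fis)

    def test_all_heterozygous_exact_values(self):
        ho, hs, fis = rp.nei_stats(ALL_HET)
        assert ho == 1.0
        assert hs == pytest.approx(9 / 17, abs=1e-10)
        assert fis == pytest.approx(1 - 17 / 9, abs=1e-10)

    def test_mixed_hand_computation(self):
        ho, hs, fis = rp.nei_stats(MIXED)
        hs_hand = (18 / 17) * (1 - (13 / 18) ** 2 - (5 / 18) ** 2)
        assert ho == pytest.approx(3 / 9, abs=1e-10)
        assert hs == pytest.approx(hs_hand, abs=1e-10)
        assert fis == pytest.approx(1 - (3 / 9) / hs_hand, abs=1e-10)

    def test_fewer_than_two_called_undefined(self):
        assert all(np.isnan(v) for v in rp.nei_stats(["AG", None]))

    @given(
        genos=st.lists(
            st.sampled_from(["AA", "AG", "GG", "AC", "CC", None]), min_size=2, max_size=12
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_fis_zero_iff_equal(self, genos):
        ho, hs, fis = rp.nei_stats(genos)
        if np.isnan(hs):
            return
        assert 0.0 <= ho <= 1.0 and 0.0 <= hs <= 1.0
        if not np.isnan(fis):
            assert fis == pytest.approx(1 - ho / hs, abs=1e-12)
            if ho == hs:
                assert fis == pytest.approx(0.0, abs=1e-12)

    def test_vectorised_path_matches_scalar(self):
        from radpara.likelihood import GENOTYPE_INDEX

        rows = [ALL_HET, MIXED, ["AA"] * 9]
        idx = np.array(
            [[GENOTYPE_INDEX["".join(sorted(g))] for g in row] for row in rows]
        )
        table = stats_from_call_indices(idx)
        for k, row in enumerate(rows):
            ho, hs, fis = rp.nei_stats(row)
            assert table.ho[k] == pytest.approx(ho, abs=1e-12)
            assert table.hs[k] == pytest.approx(hs, abs=1e-12)
            assert table.maf[k] == pytest.approx(rp.maf(row), abs=1e-12)
            if np.isnan(fis):
                assert np.isnan(table.fis[k])
            else:
                assert table.fis[k] == pytest.approx(fis, abs=1e-12)


class TestNucleotideDiversity:
    def test_monomorphic_loci_zero(self):
        assert rp.nucleotide_diversity([["AA"] * 4, ["CC"] * 4], 200) == 0.0

    def test_single_segregating_site_arithmetic(self):
        # one site with Hs = 0.5 in a 100-bp locus -> 0.005
        genos = ["AA", "AA", "AG", "AG", "GG"]  # p=(4+2)/10 -> check Hs directly
        _, hs, _ = rp.nei_stats(genos)
        assert rp.nucleotide_diversity([genos], 100) == pytest.approx(hs / 100, abs=1e-12)

    def test_recovery_against_truth_on_simulation(self):
        """Deep-coverage estimate within 20% of the truth-genotype diversity."""
        cfg = rp.SimConfig(
            n_loci=500, paralog_fraction=0.0, coverage_mean=30.0, theta_sim=0.01,
            error_rate=0.002, seed=11,
        )
        piles, truth = rp.simulate_dataset(cfg)
        # truth diversity: per-site Hs of the true genotypes over all sites
        truth_calls = (
            truth.genotypes.groupby(["locus_id", "pos"]).genotype.apply(list).tolist()
        )
        total = cfg.n_loci * cfg.locus_length
        theta_truth = rp.nucleotide_diversity(truth_calls, total)
        snp_df, _, geno_idx = rp.snp_table_at_depth(piles, 10, 0.002)
        from radpara.sweep import theta_for_loci

        theta_est = theta_for_loci(geno_idx, piles)
        assert theta_est == pytest.approx(theta_truth, rel=0.2)


class TestSummaryTable:
    def _snp_table(self, counts_per_locus, flags=None):
        rows = []
        for lid, n in counts_per_locus.items():
            for k in range(n):
                rows.append(
                    {"locus_id": lid, "pos": k, "n_alleles": 2,
                     "flag": flags.get((lid, k), "PASS") if flags else "PASS"}
                )
        return pd.DataFrame(rows, columns=["locus_id", "pos", "n_alleles", "flag"])

    def test_direct_counts_and_percentages(self):
        snp = self._snp_table({"L2": 1, "L3": 2, "L4": 3})
        status = pd.DataFrame(
            {"locus_id": ["L1", "L2", "L3", "L4"], "is_paralog": [False] * 4}
        )
        out = rp.summary_table(snp, status)["nonparalogous"]
        assert out["n_loci"] == 4
        assert out["pct_monomorphic"] == pytest.approx(25.0)
        assert out["pct_1or2_snps"] == pytest.approx(50.0)
        assert out["pct_gt2_snps"] == pytest.approx(25.0)
        assert out["mean_snps_per_locus"] == pytest.approx(2.0)
        total = out["pct_monomorphic"] + out["pct_1or2_snps"] + out["pct_gt2_snps"]
        assert total == pytest.approx(100.0, abs=0.1)

    def test_pass_fraction_on_para_locus(self):
        flags = {("P1", 0): "PARA", ("P1", 1): "PARA", ("P1", 2): "PARA",
                 ("P1", 3): "PASS", ("P1", 4): "PASS"}
        snp = self._snp_table({"P1": 5}, flags)
        status = pd.DataFrame({"locus_id": ["P1"], "is_paralog": [True]})
        out = rp.summary_table(snp, status)["paralogous"]
        assert out["pct_pass_of_total"] == pytest.approx(40.0)
        assert out["n_para_loci_with_pass"] == 1

    def test_no_polymorphism(self):
        snp = self._snp_table({})
        status = pd.DataFrame(
            {"locus_id": [f"L{i}" for i in range(10)], "is_paralog": [False] * 10}
        )
        out = rp.summary_table(snp, status)["nonparalogous"]
        assert out["pct_monomorphic"] == pytest.approx(100.0)
        assert out["n_snps"] == 0
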