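"""One-locus vs two-locus LRT: oracles, symmetries, power and calibration."""

import numpy as np
import pytest

import radpara as rp
from radpara.parafilter import PARA, PASS

from conftest import oracle_one_locus_loglik

EPS = 0.005


def balanced_paralog_piles(rng, n_ind=9, depth=20, eps=EPS):
    """Every individual reads both collapsed copies at a 50:50 ratio."""
    p = [0.5 * (1 - eps) + 0.5 * eps / 3] * 2 + [eps / 3] * 2
    return rng.multinomial(depth, np.array(p) / sum(p), size=n_ind)


class TestOneLocusModel:
    def test_pure_major_allele_degenerate(self):
        counts = np.tile([[20, 0, 0, 0]], (9, 1))
        lnl1, p_hat = rp.one_locus_loglik(counts, ("A", "C"), 0.0)
        assert p_hat == pytest.approx(1.0, abs=1e-6)
        assert lnl1 == pytest.approx(0.0, abs=1e-9)

    def test_matches_independent_grid_oracle(self):
        rng = np.random.default_rng(1)
        from radpara.likelihood import GENOTYPE_INDEX, emission_matrix

        genos = [(0, 0), (0, 1), (1, 1), (0, 1), (0, 0), (0, 1), (1, 1), (0, 0), (0, 1)]
        em = emission_matrix(0.01)
        counts = np.array(
            [rng.multinomial(12, em[GENOTYPE_INDEX["".join(sorted("AC"[i] + "AC"[j]))]])
             for i, j in genos]
        )
        lnl1, _ = rp.one_locus_loglik(counts, ("A", "C"), 0.01)
        oracle = oracle_one_locus_loglik(counts, 0, 1, 0.01)
        assert lnl1 >= oracle - 1e-9          # refinement never loses to the grid
        assert lnl1 == pytest.approx(oracle, abs=1e-6)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        counts = rng.multinomial(15, [0.6, 0.39, 0.005, 0.005], size=9)
        l_ab, p_ab = rp.one_locus_loglik(counts, ("A", "C"), EPS)
        l_ba, p_ba = rp.one_locus_loglik(counts, ("C", "A"), EPS)
        assert l_ab == pytest.approx(l_ba, abs=1e-8)
        assert p_ab == pytest.approx(1 - p_ba, abs=1e-5)

    def test_requires_two_individuals_at_depth(self):
        counts = np.array([[10, 5, 0, 0], [2, 1, 0, 0]])
        with pytest.raises(ValueError):
            rp.one_locus_loglik(counts, ("A", "C"), EPS, min_depth=4)


class TestTwoLocusModel:
    def test_balanced_piles_recover_half_ratio(self):
        rng = np.random.default_rng(3)
        counts = balanced_paralog_piles(rng)
        lnl2, r_hat = rp.two_locus_loglik(counts, ("A", "C"), EPS)
        lnl1, _ = rp.one_locus_loglik(counts, ("A", "C"), EPS)
        assert r_hat == pytest.approx(0.5, abs=0.1)
        assert lnl2 > lnl1

    def test_pure_reads_collapse_to_one_allele(self):
        counts = np.tile([[20, 0, 0, 0]], (9, 1))
        lnl2, r_hat = rp.two_locus_loglik(counts, ("A", "C"), 0.0)
        lnl1, _ = rp.one_locus_loglik(counts, ("A", "C"), 0.0)
        assert r_hat == pytest.approx(1.0, abs=1e-6)
        assert lnl2 <= lnl1 + 1e-6

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        counts = balanced_paralog_piles(rng)
        l_ab, r_ab = rp.two_locus_loglik(counts, ("A", "C"), EPS)
        l_ba, r_ba = rp.two_locus_loglik(counts, ("C", "A"), EPS)
        assert l_ab == pytest.approx(l_ba, abs=1e-8)
        assert r_ab == pytest.approx(1 - r_ba, abs=1e-5)


class TestParaLRT:
    def test_collapsed_duplicate_flagged(self):
        rng = np.random.default_rng(5)
        res = rp.para_lrt(balanced_paralog_piles(rng), ("A", "C"), EPS, th2=0.01)
        assert res.flag == PARA
        assert res.lrt_stat == pytest.approx(
            max(0.0, 2 * (res.lnl2 - res.lnl1)), abs=1e-12
        )
        assert 0 <= res.p_value <= 1

    def test_monomorphic_looking_site_passes(self):
        counts = np.tile([[18, 0, 0, 0]], (9, 1))
        res = rp.para_lrt(counts, ("A", "C"), EPS, th2=0.01)
        assert res.flag == PASS

    def test_true_hwe_snp_passes_most_replicates(self):
        """Calibration at p = 0.3, depth 20: the one-locus truth wins >= 95%."""
        rng = np.random.default_rng(6)
        from radpara.likelihood import emission_matrix

        em = emission_matrix(EPS)
        n_pass = 0
        reps = 60
        for _ in range(reps):
            n_c = (rng.random((9, 2)) < 0.3).sum(axis=1)
            gidx = np.select([n_c == 0, n_c == 1, n_c == 2], [0, 1, 4])
            counts = rng.multinomial(20, em[gidx])
            res = rp.para_lrt(counts, ("A", "C"), EPS, th2=0.01)
            n_pass += res.flag == PASS
        assert n_pass / reps >= 0.95

    def test_lrt_stat_nonnegative_on_random_piles(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.multinomial(12, [0.4, 0.4, 0.1, 0.1], size=5)
            res = rp.para_lrt(counts, ("A", "C"), 0.01)
            assert res.lrt_stat >= 0.0
            assert 0.0 <= res.p_value <= 1.0


class TestLocusClassification:
    def _res(self, lid, pos, flag):
        return rp.ParaTestResult(lid, pos, ("A", "C"), 0, 0, 0, 1, flag, 0.5, 0.5, 9)

    def test_mixed_flags(self):
        results = [
            self._res("L1", 0, PASS),
            self._res("L1", 5, PARA),
            self._res("L1", 9, PASS),
            self._res("L2", 3, PASS),
            self._res("L2", 7, PASS),
        ]
        status = {s.locus_id: s for s in rp.classify_loci(results, loci=["L1", "L2", "L3"])}
        assert status["L1"].is_paralog and status["L1"].n_pass_sites == 2
        assert status["L1"].n_para_sites == 1
        assert not status["L2"].is_paralog and status["L2"].n_pass_sites == 2
        assert not status["L3"].is_paralog
        assert status["L3"].n_pass_sites == status["L3"].n_para_sites == 0


class TestParalogLRTFilterEstimator:
    def test_predict_flags_paralog_sites(self):
        rng = np.random.default_rng(8)
        para_site = balanced_paralog_piles(rng)
        from radpara.likelihood import emission_matrix

        mono_site = rng.multinomial(20, emission_matrix(EPS)[0], size=9)
        X = np.stack([para_site, mono_site])
        filt = rp.ParalogLRTFilter(error_rate=EPS, min_depth=4, th2=0.01).fit(X)
        flags = filt.predict(X)
        assert flags[0] == PARA
        assert flags[1] in ("NA", PASS)  # monomorphic: no second allele to test
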