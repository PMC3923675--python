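"""Generator correctness: determinism, level laws, sampling distributions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import pmdseq as pq
from pmdseq.sequence import CG_CODE, TT_CODE, dinuc_code
from pmdseq.simulate import truncated_poisson, stage_rng

from conftest import null_config, small_config


class TestGroundTruth:
    def test_bit_identical_for_same_config_and_seed(self):
        cfg = small_config()
        a = pq.make_ground_truth(cfg, seed=3)
        b = pq.make_ground_truth(cfg, seed=3)
        assert all((a.genome[c] == b.genome[c]).all() for c in a.genome)
        pd.testing.assert_frame_equal(a.cpgs, b.cpgs)
        assert np.array_equal(a.coeffs.matrix, b.coeffs.matrix)
        c = pq.make_ground_truth(cfg, seed=4)
        assert not a.cpgs.equals(c.cpgs)

    def test_null_coefficients_give_flat_pmd_probability(self):
        gt = pq.make_ground_truth(null_config(intercept=0.5), seed=1)
        pmd = gt.pmd_cpgs
        assert len(pmd) > 100
        assert (pmd["p"] == 0.5).all()

    def test_single_coefficient_shifts_p_linearly(self):
        cfg = small_config()
        coeffs = pq.build_coefficients(cfg)
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 16, size=(1, 78))
        inner_right = 39
        a = codes.copy()
        a[0, inner_right] = TT_CODE
        b = codes.copy()
        b[0, inner_right] = CG_CODE
        diff = coeffs.linear_predictor(b)[0] - coeffs.linear_predictor(a)[0]
        want = coeffs.matrix[inner_right, CG_CODE] - coeffs.matrix[inner_right, TT_CODE]
        assert diff == pytest.approx(want, abs=1e-12)

    def test_region_level_laws(self, default_gt):
        g = default_gt.cpgs
        bg = g[g["region"] == "background"]["p"]
        assert (bg >= 0.9).all()
        isl = g[g["region"] == "island"]["p"]
        assert (isl <= 0.1).all()

    def test_pmd_p_spans_range_and_cv_matches_enumeration(self, default_gt):
        p = default_gt.pmd_cpgs["p"].to_numpy()
        assert p.min() < 0.2 and p.max() > 0.9
        # CV of a random 10% subsample vs exhaustive enumeration over all
        # simulated contexts
        rng = np.random.default_rng(2)
        sub = rng.choice(p, size=len(p) // 10, replace=False)
        cv_sub = sub.std() / sub.mean()
        cv_all = p.std() / p.mean()
        assert abs(cv_sub - cv_all) / cv_all < 0.10

    def test_clamping_is_rare(self, default_gt):
        assert default_gt.clamp_fraction < 0.01

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            pq.make_ground_truth(pq.SimConfig(cpg_density=0.5), seed=0)
        with pytest.raises(ValueError):
            pq.make_ground_truth(pq.SimConfig(chrom_lengths={}), seed=0)


class TestSimulateMethylome:
    def test_extreme_probabilities(self):
        for intercept, check in [(1.0, lambda c: (c["meth"] == c["total"]).all()),
                                 (0.0, lambda c: (c["meth"] == 0).all())]:
            gt = pq.make_ground_truth(null_config(intercept=intercept), seed=2)
            calls = pq.simulate_methylome(gt, seed=3)
            pmd_pos = set(gt.pmd_cpgs["pos"])
            sub = calls[calls["pos"].isin(pmd_pos | {p + 1 for p in pmd_pos})]
            assert check(sub)

    def test_mean_level_concentrates_at_high_coverage(self):
        gt = pq.make_ground_truth(null_config(intercept=0.5, chrom_len=1_200_000), seed=2)
        assert len(gt.cpgs) >= 10_000
        calls = pq.simulate_methylome(gt, coverage_mean=1000, seed=4)
        cpgs = pq.combine_strands(calls)
        assert 0.49 <= cpgs["level"].mean() <= 0.51

    def test_counts_are_binomial_given_p(self, default_gt):
        calls = pq.simulate_methylome(default_gt, seed=9)
        cpgs = pq.combine_strands(calls)
        merged = cpgs.merge(default_gt.cpgs[["chrom", "pos", "p"]], on=["chrom", "pos"])
        interior = merged[(merged["p"] > 0.02) & (merged["p"] < 0.98)]
        m = interior["meth"].to_numpy()
        t = interior["total"].to_numpy()
        p = interior["p"].to_numpy()
        z = (m - t * p) / np.sqrt(t * p * (1 - p))
        n = len(z)
        # aggregate location and dispersion of the standardized counts
        assert abs(z.mean()) < 4 / np.sqrt(n)
        chi2 = float((z**2).sum())
        pval = scipy.stats.chi2.sf(chi2, df=n)
        assert pval > 0.01

    def test_truncated_poisson_law(self):
        rng = np.random.default_rng(5)
        draws = truncated_poisson(rng, 1.2, 20_000)
        assert draws.min() >= 1
        lam = 1.2
        expected_mean = lam / (1 - np.exp(-lam))
        assert abs(draws.mean() - expected_mean) < 0.03


@pytest.fixture(scope="module")
def dip(default_gt):
    return pq.simulate_diploid(default_gt, snp_count=2000, coverage_mean=60, seed=21)


class TestSimulateDiploid:
    def test_true_dm_is_exact_coefficient_difference(self, default_gt, dip):
        m = default_gt.coeffs.matrix
        want = m[dip.truth["block"], dip.truth["d_A"]] - m[dip.truth["block"], dip.truth["d_R"]]
        assert np.allclose(dip.truth["true_dm"], want)

    def test_equal_coefficient_swap_has_zero_dm(self, default_gt, dip):
        m = default_gt.coeffs.matrix
        same = np.isclose(
            m[dip.truth["block"], dip.truth["d_A"]],
            m[dip.truth["block"], dip.truth["d_R"]],
        )
        assert same.any()  # outer blocks are full of zero-coefficient states
        assert np.allclose(dip.truth.loc[same, "true_dm"], 0.0)

    def test_focal_cpg_intact_and_single_snp_spacing(self, dip):
        assert ((dip.snps["pos"] != dip.truth["pos"]) & (dip.snps["pos"] != dip.truth["pos"] + 1)).all()
        for _, sub in dip.truth.groupby("chrom"):
            pos = np.sort(sub["pos"].to_numpy())
            assert (np.diff(pos) > 84).all()

    def test_observed_dm_unbiased_for_true_dm(self, dip):
        m_r = dip.ref_table["meth"] / dip.ref_table["total"]
        m_a = dip.alt_table["meth"] / dip.alt_table["total"]
        resid = (m_a - m_r) - dip.truth["true_dm"]
        se = np.sqrt(
            (dip.truth["p_ref"] * (1 - dip.truth["p_ref"]) / dip.ref_table["total"]
             + dip.truth["p_alt"] * (1 - dip.truth["p_alt"]) / dip.alt_table["total"]).mean()
            / len(resid)
        )
        assert abs(resid.mean()) < 4 * se

    def test_impossible_density_raises(self, small_gt):
        with pytest.raises(ValueError):
            pq.simulate_diploid(small_gt, snp_count=10**6, seed=0)


class TestSimulateMnase:
    def test_single_dyad_plus_reads_share_one_center(self):
        cfg = null_config(chrom_len=100_000)
        gt = pq.make_ground_truth(cfg, seed=6)
        # spacing equal to the chromosome length leaves exactly one dyad
        reads = pq.simulate_mnase_reads(
            gt, reads_per_kb=5, spacing=100_000, spacing_jitter=0,
            center_jitter=0, coupling=0.0, seed=8,
        )
        plus = reads[reads["strand"] == "+"]
        minus = reads[reads["strand"] == "-"]
        assert plus["start"].nunique() == 1
        if len(minus):  # both strands point at the same dyad
            assert int(minus["start"].iloc[0]) - int(plus["start"].iloc[0]) == 148

    def test_autocorrelation_peaks_near_nucleosome_spacing(self, default_gt):
        reads = pq.simulate_mnase_reads(default_gt, reads_per_kb=60, seed=31)
        sub = reads[reads["chrom"] == "chr1"]
        length = default_gt.config.chrom_lengths["chr1"]
        track = np.zeros(length)
        plus = sub["strand"] == "+"
        centers = np.where(plus, sub["start"] + 74, sub["start"] - 74)
        centers = centers[(centers >= 0) & (centers < length)]
        np.add.at(track, centers[:2_000_00 * 10], 1)
        arr = track[:2_000_000] - track[:2_000_000].mean()
        lags = np.arange(120, 260)
        ac = np.array([arr[:-k] @ arr[k:] for k in lags])  # brute-force scan
        best = int(lags[np.argmax(ac)])
        assert 170 <= best <= 190

    def test_determinism(self, small_gt):
        a = pq.simulate_mnase_reads(small_gt, reads_per_kb=20, seed=5)
        b = pq.simulate_mnase_reads(small_gt, reads_per_kb=20, seed=5)
        pd.testing.assert_frame_equal(a, b)
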