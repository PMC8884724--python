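import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from aisle.association import (
    HAPLOTYPE_LABELS,
    additive_logistic,
    conditional_adjust,
    em_haplotypes_2snp,
    expected_haplotype_dosages,
    haplotype_association,
    ld_r2,
    ld_r2_from_frequencies,
)
from aisle.exceptions import CollinearityError, DegenerateDataError, SeparationError


def sim_logistic(rng, n=1000, beta=0.0, maf=0.3, alpha=0.0):
    g = rng.binomial(2, maf, size=n)
    p = 1.0 / (1.0 + np.exp(-(alpha + beta * g)))
    y = rng.binomial(1, p)
    return g, y


class TestAdditiveLogistic:
    def test_null_ci_covers_one_most_of_the_time(self, rng):
        hits, n_sim = 0, 200
        for _ in range(n_sim):
            g, y = sim_logistic(rng, n=600, beta=0.0)
            try:
                res = additive_logistic(g, y)
            except DegenerateDataError:
                continue
            hits += res.ci95[0] <= 1.0 <= res.ci95[1]
        assert hits / n_sim > 0.9

    def test_matches_generic_ml_optimizer(self, rng):
        # brute-force ML oracle: minimize the hand-written negative
        # log-likelihood with scipy and compare coefficients
        for _ in range(40):
            n = int(rng.integers(80, 200))
            g = rng.binomial(2, 0.35, size=n).astype(float)
            x = rng.normal(size=n)
            eta = -0.2 + 0.4 * g + 0.3 * x
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() in (0, n) or np.ptp(g) == 0:
                continue
            X = np.column_stack([np.ones(n), g, x])

            def nll(b):
                eta = X @ b
                return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

            ref = optimize.minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
            try:
                res = additive_logistic(g, y, pd.DataFrame({"x": x}))
            except SeparationError:
                continue
            assert res.beta == pytest.approx(ref.x[1], abs=1e-5)

    def test_or_matches_allele_count_estimate(self, rng):
        # with no covariates the additive logistic OR approximates the
        # 2x(allele count) contingency OR at large n
        g, y = sim_logistic(rng, n=60000, beta=np.log(1.5))
        res = additive_logistic(g, y)
        case_alt = g[y == 1].sum()
        case_ref = 2 * (y == 1).sum() - case_alt
        ctrl_alt = g[y == 0].sum()
        ctrl_ref = 2 * (y == 0).sum() - ctrl_alt
        table_or = (case_alt / case_ref) / (ctrl_alt / ctrl_ref)
        assert res.odds_ratio == pytest.approx(table_or, rel=0.05)

    def test_separation_raises(self):
        g = np.array([0, 0, 0, 2, 2, 2])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(SeparationError):
            additive_logistic(g, y)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            additive_logistic([1, 1, 1, 1], [0, 1, 0, 1])

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            additive_logistic([0, 1, 2], [1, 1, 1])

    def test_missing_dropped_complete_case(self, rng):
        g, y = sim_logistic(rng, n=500, beta=0.2)
        g = g.astype(float)
        g[:50] = np.nan
        res = additive_logistic(g, y)
        assert res.n == 450

    def test_ci_contains_point_estimate(self, rng):
        g, y = sim_logistic(rng, n=500, beta=0.3)
        res = additive_logistic(g, y)
        assert res.ci95[0] < res.odds_ratio < res.ci95[1]


class TestConditionalAdjust:
    def test_independent_index_snp_changes_little(self, rng):
        g, y = sim_logistic(rng, n=3000, beta=0.3)
        other = rng.binomial(2, 0.4, size=3000)
        plain = additive_logistic(g, y)
        adj = conditional_adjust(g, y, None, pd.DataFrame({"idx1": other}))
        assert adj.adjusted_for == ("idx1",)
        assert adj.beta == pytest.approx(plain.beta, abs=0.05)

    def test_perfect_ld_flags_collinearity(self, rng):
        g, y = sim_logistic(rng, n=500, beta=0.2)
        with pytest.raises(CollinearityError):
            conditional_adjust(g, y, None, pd.DataFrame({"idx1": g}))

    def test_mediated_signal_attenuated(self, rng):
        # index SNP carries the causal effect; test SNP only correlates
        # with it, so adjusting must attenuate the test SNP's estimate
        n = 4000
        idx = rng.binomial(2, 0.5, size=n).astype(float)
        flip = rng.random(n) < 0.15
        test = np.where(flip, rng.binomial(2, 0.5, size=n), idx).astype(float)
        p = 1 / (1 + np.exp(-(-0.3 + 0.5 * idx)))
        y = rng.binomial(1, p)
        plain = additive_logistic(test, y)
        adj = conditional_adjust(test, y, None, pd.DataFrame({"idx": idx}))
        assert abs(adj.beta) < abs(plain.beta)


class TestEMHaplotypes:
    def test_double_homozygotes_direct_counts(self):
        # 3 individuals: (0,0)x2 -> 4 RR; (2,2) -> 2 AA
        em = em_haplotypes_2snp([0, 0, 2], [0, 0, 2])
        assert em.frequencies["RR"] == pytest.approx(4 / 6)
        assert em.frequencies["AA"] == pytest.approx(2 / 6)
        assert em.converged

    def test_all_double_heterozygotes_symmetry_fixed_point(self):
        em = em_haplotypes_2snp([1, 1, 1, 1], [1, 1, 1, 1])
        for h in HAPLOTYPE_LABELS:
            assert em.frequencies[h] == pytest.approx(0.25)

    def test_multinomial_recovery(self, rng):
        truth = np.array([0.5, 0.3, 0.15, 0.05])
        n = 2000
        haps = rng.choice(4, size=(n, 2), p=truth)
        g1 = (haps >> 1).sum(axis=1)
        g2 = (haps & 1).sum(axis=1)
        em = em_haplotypes_2snp(g1, g2)
        se = np.sqrt(truth * (1 - truth) / (2 * n))
        assert np.all(np.abs(em.freqs - truth) < 4 * se)

    def test_loglik_monotone(self, rng):
        for _ in range(50):
            g1 = rng.integers(0, 3, size=100)
            g2 = rng.integers(0, 3, size=100)
            em = em_haplotypes_2snp(g1, g2)
            diffs = np.diff(em.loglik_trace)
            assert np.all(diffs >= -1e-9)

    def test_frequencies_sum_to_one(self, rng):
        g1 = rng.integers(0, 3, size=50)
        g2 = rng.integers(0, 3, size=50)
        em = em_haplotypes_2snp(g1, g2)
        assert em.freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            em_haplotypes_2snp([], [])

    def test_missing_dropped(self):
        em = em_haplotypes_2snp([0, np.nan, 2], [0, 1, 2])
        assert em.n == 2


class TestHaplotypeAssociation:
    @staticmethod
    def _cohort(rng, n=2000, risk_beta=0.0):
        truth = np.array([0.4, 0.2, 0.25, 0.15])
        haps = rng.choice(4, size=(n, 2), p=truth)
        g1 = (haps >> 1).sum(axis=1)
        g2 = (haps & 1).sum(axis=1)
        risk_dosage = (haps == 3).sum(axis=1)  # AA haplotype copies
        p = 1 / (1 + np.exp(-(-0.2 + risk_beta * risk_dosage)))
        y = rng.binomial(1, p)
        return g1, g2, y

    def test_expected_dosages_sum_to_two(self, rng):
        g1, g2, _ = self._cohort(rng, n=300)
        em = em_haplotypes_2snp(g1, g2)
        dos = expected_haplotype_dosages(g1, g2, em)
        np.testing.assert_allclose(dos.sum(axis=1), 2.0)

    def test_null_ors_near_one(self, rng):
        g1, g2, y = self._cohort(rng, n=3000, risk_beta=0.0)
        em = em_haplotypes_2snp(g1, g2)
        dos = expected_haplotype_dosages(g1, g2, em)
        res = haplotype_association(dos, y, None, baseline="RR", em=em)
        for h, orr in res.odds_ratios.items():
            lo, hi = res.ci95[h]
            assert lo <= 1.0 <= hi or abs(np.log(orr)) < 0.25

    def test_planted_risk_haplotype_power(self, rng):
        hits, n_sim = 0, 30
        for _ in range(n_sim):
            g1, g2, y = self._cohort(rng, n=2000, risk_beta=0.5)
            em = em_haplotypes_2snp(g1, g2)
            dos = expected_haplotype_dosages(g1, g2, em)
            res = haplotype_association(dos, y, None, baseline="RR", em=em)
            hits += res.odds_ratios["AA"] > 1.0 and res.p_values["AA"] < 0.05
        assert hits / n_sim >= 0.8

    def test_zero_frequency_baseline_rejected(self, rng):
        g1 = np.zeros(100)
        g2 = np.zeros(100)
        em = em_haplotypes_2snp(g1, g2)
        dos = expected_haplotype_dosages(g1, g2, em)
        y = np.tile([0, 1], 50)
        with pytest.raises(DegenerateDataError):
            haplotype_association(dos, y, None, baseline="AA", em=em)

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ValueError):
            haplotype_association(pd.DataFrame(columns=list(HAPLOTYPE_LABELS)), [], None, "XX")


class TestLDr2:
    def test_independent_snps_zero(self):
        assert ld_r2_from_frequencies([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.0)

    def test_identical_snps_one(self, rng):
        g = rng.binomial(2, 0.4, size=500)
        assert ld_r2(g, g, method="dosage") == pytest.approx(1.0)
        assert ld_r2(g, g, method="em") == pytest.approx(1.0, abs=1e-6)

    def test_half_half_frequencies(self):
        # D = 0.25, pA=pB=0.5 -> r2 = 1
        assert ld_r2_from_frequencies([0.5, 0.0, 0.0, 0.5]) == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(DegenerateDataError):
            ld_r2([0, 0, 0], [0, 1, 2], method="dosage")
        with pytest.raises(DegenerateDataError):
            ld_r2([0, 0, 0], [0, 1, 2], method="em")

    def test_em_equals_dosage_on_unambiguous_data(self, rng):
        # each individual carries one haplotype doubled: phase is trivially
        # unambiguous, EM reduces to counting, and the dosage correlation
        # equals the haplotype correlation exactly
        for _ in range(20):
            haps = rng.choice(4, size=400, p=[0.4, 0.2, 0.25, 0.15])
            g1 = 2 * (haps >> 1).astype(float)
            g2 = 2 * (haps & 1).astype(float)
            if np.ptp(g1) == 0 or np.ptp(g2) == 0:
                continue
            r2_em = ld_r2(g1, g2, method="em")
            r2_d = ld_r2(g1, g2, method="dosage")
            assert r2_em == pytest.approx(r2_d, abs=1e-6)
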