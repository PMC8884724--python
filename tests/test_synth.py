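import numpy as np
import pandas as pd
import pytest

from aisle.allelic import allelic_ratio
from aisle.quantify import stage_trend
from aisle.superenhancer import parse_segmentation, call_superenhancers
from aisle.synth import (
    PlantedAI,
    SimConfig,
    beta_binomial,
    gen_allelic_dataset,
    gen_genotypes,
    gen_methylation,
    gen_segmentation,
    gen_window_counts,
)


class TestConfigValidation:
    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            SimConfig(null_allelic_fraction=1.2)

    def test_rejects_rho_one(self):
        with pytest.raises(ValueError):
            SimConfig(rho=1.0)

    def test_rejects_out_of_range_planted_index(self):
        with pytest.raises(ValueError):
            SimConfig(n_snps=5, planted_ai=(PlantedAI(5, 0.6, 0.5),))

    def test_rejects_planted_fraction_outside_unit(self):
        with pytest.raises(ValueError):
            SimConfig(n_snps=5, planted_ai=(PlantedAI(0, 1.5, 0.5),))

    def test_rejects_nonpositive_library(self):
        with pytest.raises(ValueError):
            SimConfig(library_size=0)


class TestAllelicDataset:
    def test_fixed_seed_determinism(self, base_cfg):
        a = gen_allelic_dataset(base_cfg)
        b = gen_allelic_dataset(base_cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_null_mean_ar_near_half(self):
        # binomial oracle: mean AR over m SNPs*samples has SE
        # sqrt(0.25/depth)/sqrt(m); check within 3 MC standard errors
        cfg = SimConfig(seed=5, n_snps=500, n_case=10, n_control=10, rho=0.0,
                        depth_mean=50.0)
        sites, calls, _ = gen_allelic_dataset(cfg)
        hets = calls[calls["genotype"] == "het"]
        ar = allelic_ratio(hets["ref_depth"].to_numpy(), hets["alt_depth"].to_numpy())
        se = np.sqrt(0.25 / 50.0) / np.sqrt(len(ar))
        assert abs(ar.mean() - 0.5) < 3 * se

    def test_planted_ai_raises_case_ar(self, planted_cfg):
        sites, calls, samples = gen_allelic_dataset(planted_cfg)
        snp0 = calls[(calls["snp_id"] == "snp00000") & (calls["genotype"] == "het")]
        merged = snp0.merge(samples, on="sample_id")
        ar = allelic_ratio(merged["ref_depth"].to_numpy(), merged["alt_depth"].to_numpy())
        assert ar[merged["group"] == 1].mean() > ar[merged["group"] == 0].mean()

    def test_direction_flip_between_states(self):
        cfg = SimConfig(
            seed=3, n_snps=4, n_case=40, n_control=40, rho=0.0,
            planted_ai=(PlantedAI(0, 0.8, 0.5, cell_state="T3"),),
            flip_states=("T3", "rN"),
        )
        sites, calls, samples = gen_allelic_dataset(cfg)
        merged = calls[(calls["snp_id"] == "snp00000") & (calls["genotype"] == "het")].merge(
            samples, on="sample_id"
        )
        cases = merged[merged["group"] == 1]
        ar = allelic_ratio(cases["ref_depth"].to_numpy(), cases["alt_depth"].to_numpy())
        states = cases["cell_state"].to_numpy()
        assert ar[states == "T3"].mean() > 0.5 > ar[states == "rN"].mean()

    def test_qc_overrides_propagate(self):
        cfg = SimConfig(seed=1, n_snps=3, site_qc_overrides={1: {"mq": 10.0, "rsid": np.nan}})
        sites, _, _ = gen_allelic_dataset(cfg)
        assert sites.loc[1, "mq"] == 10.0
        assert pd.isna(sites.loc[1, "rsid"])

    def test_beta_binomial_moments(self, rng):
        # moment oracle: var = n f (1-f) (1 + (n-1) rho)
        n, f, rho, m = 50, 0.5, 0.1, 20000
        draws = beta_binomial(rng, np.full(m, n), f, rho)
        expected_var = n * f * (1 - f) * (1 + (n - 1) * rho)
        se_mean = np.sqrt(expected_var / m)
        assert abs(draws.mean() - n * f) < 3 * se_mean
        # variance of the sample variance ~ 2 var^2/(m-1) for near-normal sums;
        # beta-binomial sums are mildly kurtotic, allow 5 sigma
        se_var = expected_var * np.sqrt(2.0 / (m - 1)) * 2
        assert abs(draws.var(ddof=1) - expected_var) < 5 * se_var

    def test_beta_binomial_rho_zero_is_binomial_range(self, rng):
        draws = beta_binomial(rng, np.full(1000, 10), 0.0, 0.0)
        assert np.all(draws == 0)
        draws = beta_binomial(rng, np.full(1000, 10), 1.0, 0.3)
        assert np.all(draws == 10)


class TestSegmentation:
    def test_tiling_sorted_gap_free(self, base_cfg):
        seg = gen_segmentation(base_cfg, planted_runs=[(5000, 3500)])
        assert seg["start"].iloc[0] == 0
        assert seg["end"].iloc[-1] == base_cfg.chrom_length
        assert np.all(seg["start"].to_numpy()[1:] == seg["end"].to_numpy()[:-1])
        assert np.all(seg["end"] > seg["start"])

    def test_determinism(self, base_cfg):
        a = gen_segmentation(base_cfg, planted_runs=[(5000, 3500)])
        b = gen_segmentation(base_cfg, planted_runs=[(5000, 3500)])
        pd.testing.assert_frame_equal(a, b)

    def test_planted_run_recovered_exactly(self, base_cfg):
        seg = gen_segmentation(base_cfg, planted_runs=[(5000, 3500)])
        lines = (f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}" for r in seg.itertuples())
        ses = call_superenhancers(parse_segmentation(lines))
        assert len(ses) == 1
        assert (ses[0].start, ses[0].end) == (5000, 8500)
        assert ses[0].length_bp == 3500

    def test_no_planted_runs_no_ses(self, base_cfg):
        seg = gen_segmentation(base_cfg)
        lines = (f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}" for r in seg.itertuples())
        assert call_superenhancers(parse_segmentation(lines)) == []

    def test_overlapping_runs_rejected(self, base_cfg):
        with pytest.raises(ValueError, match="overlap"):
            gen_segmentation(base_cfg, planted_runs=[(5000, 3500), (6000, 1000)])


class TestWindowCounts:
    def test_determinism(self, base_cfg):
        a, _ = gen_window_counts(base_cfg)
        b, _ = gen_window_counts(base_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_slope_fits_flat(self):
        cfg = SimConfig(seed=9, trend_slope=0.0, n_per_stage=10, base_window_mean=50.0)
        counts, samples = gen_window_counts(cfg)
        cases = samples[samples["group"] == 1]
        means = counts[cases["sample_id"]].mean(axis=0).to_numpy()
        tr = stage_trend(means, cases["stage"].to_numpy())
        # regression oracle: slope CI should cover 0
        assert tr.ci95[0] <= 0.0 <= tr.ci95[1]

    def test_positive_slope_in_cases_only(self):
        cfg = SimConfig(seed=9, trend_slope=10.0, n_per_stage=10, base_window_mean=50.0)
        counts, samples = gen_window_counts(cfg)
        for group, check in ((1, lambda t: t.slope > 5 and t.p_value < 1e-6),
                             (0, lambda t: t.ci95[0] <= 0.0 <= t.ci95[1])):
            sel = samples[samples["group"] == group]
            means = counts[sel["sample_id"]].mean(axis=0).to_numpy()
            assert check(stage_trend(means, sel["stage"].to_numpy()))


class TestMethylation:
    def test_meth_counts_bounded(self, base_cfg):
        cpgs, _ = gen_methylation(base_cfg)
        assert (cpgs["methylated"] <= cpgs["total"]).all()
        assert (cpgs["methylated"] >= 0).all()
        assert (cpgs["total"] >= 1).all()

    def test_pi_one_everywhere(self):
        cfg = SimConfig(seed=4, meth_base=1.0, meth_slope=0.0, n_per_stage=1)
        cpgs, _ = gen_methylation(cfg)
        assert (cpgs["methylated"] == cpgs["total"]).all()

    def test_negative_slope_declines_in_cases(self):
        cfg = SimConfig(seed=6, meth_base=0.9, meth_slope=-0.15, n_per_stage=5)
        cpgs, samples = gen_methylation(cfg)
        frac = cpgs.assign(f=cpgs["methylated"] / cpgs["total"])
        per_sample = frac.groupby("sample_id")["f"].mean()
        cases = samples[samples["group"] == 1]
        tr = stage_trend(per_sample[cases["sample_id"]].to_numpy(), cases["stage"].to_numpy())
        assert tr.slope < -0.1
        assert tr.p_value < 1e-6

    def test_determinism(self, base_cfg):
        a, _ = gen_methylation(base_cfg)
        b, _ = gen_methylation(base_cfg)
        pd.testing.assert_frame_equal(a, b)


class TestGenotypes:
    def test_determinism(self):
        cfg = SimConfig(seed=8)
        for a, b in zip(gen_genotypes(cfg), gen_genotypes(cfg)):
            assert a.equals(b)

    def test_null_effect_or_near_one(self):
        from aisle.association import additive_logistic

        cfg = SimConfig(seed=2, n_individuals=2000, assoc_effect=0.0)
        dosages, pheno, cov = gen_genotypes(cfg)
        res = additive_logistic(dosages["snp1"], pheno, cov)
        assert res.ci95[0] <= 1.0 <= res.ci95[1]

    def test_planted_effect_recovered(self):
        # logistic ML recovery oracle at the published effect scale
        from aisle.association import additive_logistic

        beta = np.log(0.77)
        cfg = SimConfig(seed=13, n_individuals=4000, assoc_effect=beta)
        dosages, pheno, cov = gen_genotypes(cfg)
        res = additive_logistic(dosages["snp1"], pheno, cov)
        assert abs(res.beta - beta) < 3 * res.se

    def test_target_r2_achieved(self):
        # haplotype-frequency oracle: dosage r2 concentrates on the target
        from aisle.association import ld_r2

        cfg = SimConfig(seed=17, n_individuals=5000, maf=0.3, maf2=0.25, target_r2=0.4)
        dosages, _, _ = gen_genotypes(cfg)
        r2 = ld_r2(dosages["snp1"], dosages["snp2"], method="dosage")
        assert abs(r2 - 0.4) < 0.05

    def test_infeasible_r2_rejected(self):
        cfg = SimConfig(seed=1, maf=0.05, maf2=0.9, target_r2=0.9)
        with pytest.raises(ValueError, match="infeasible"):
            gen_genotypes(cfg)

    def test_hwe_allele_frequency(self):
        cfg = SimConfig(seed=21, n_individuals=20000, maf=0.3)
        dosages, _, _ = gen_genotypes(cfg)
        p_hat = dosages["snp1"].mean() / 2
        se = np.sqrt(0.3 * 0.7 / (2 * 20000))
        assert abs(p_hat - 0.3) < 4 * se
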