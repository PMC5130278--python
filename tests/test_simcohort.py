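"""Generator contracts: HWE dosages, sparse effects, phenotype model."""

import numpy as np
import pandas as pd
import pytest

from longprs.simcohort import (GeneticArchitecture, VarianceComponents,
                               default_panel, mother_design, offspring_design,
                               simulate_covariates, simulate_effects,
                               simulate_genotypes, simulate_phenotypes)

from conftest import make_panel, simulate_cohort


class TestSimulateGenotypes:
    def test_shape_and_range(self, full_panel):
        geno = simulate_genotypes(full_panel, 100, seed=1)
        assert geno.dosages.shape == (100, 89)
        assert geno.dosages.min() >= 0 and geno.dosages.max() <= 2

    def test_monomorphic_marker_all_zero(self):
        panel = make_panel([0.0, 0.3])
        geno = simulate_genotypes(panel, 50, seed=1)
        assert np.all(geno.dosages[:, 0] == 0)

    def test_sample_mean_matches_binomial(self):
        panel = make_panel([0.5])
        geno = simulate_genotypes(panel, 10_000, seed=2)
        se = np.sqrt(0.5 / 10_000)
        assert abs(geno.dosages[:, 0].mean() - 1.0) < 3 * se

    def test_hwe_genotype_frequencies(self):
        # hard-called markers should show p^2 / 2pq / q^2 class frequencies
        panel = make_panel([0.1, 0.25, 0.4])
        n = 5000
        geno = simulate_genotypes(panel, n, seed=3)
        for j, p in enumerate([0.1, 0.25, 0.4]):
            expected = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p ** 2}
            for g, f in expected.items():
                obs = np.mean(geno.dosages[:, j] == g)
                se = np.sqrt(f * (1 - f) / n)
                assert abs(obs - f) < 3 * se + 1e-12

    def test_imputed_dosages_continuous_with_matching_mean(self):
        panel = make_panel([0.3], imputed=[True])
        geno = simulate_genotypes(panel, 20_000, seed=4)
        d = geno.dosages[:, 0]
        assert np.any(np.mod(d, 1) != 0)
        assert abs(d.mean() - 0.6) < 3 * np.sqrt(2 * 0.3 * 0.7 / 20_000)

    def test_seed_reproducibility(self, small_panel):
        a = simulate_genotypes(small_panel, 30, seed=9)
        b = simulate_genotypes(small_panel, 30, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_invalid_n(self, small_panel):
        with pytest.raises(ValueError):
            simulate_genotypes(small_panel, 0, seed=1)


class TestSimulateEffects:
    def test_fully_null_architecture(self, small_panel):
        arch = GeneticArchitecture(m=12, vg=0.0, pi0=1.0, seed=1)
        eff = simulate_effects(arch, small_panel)
        assert np.all(eff.beta_std == 0) and np.all(eff.beta_dosage == 0)

    def test_null_count_contract(self, full_panel):
        arch = GeneticArchitecture(m=89, vg=0.1, pi0=0.5, seed=2)
        eff = simulate_effects(arch, full_panel)
        assert eff.m == 89
        assert int(eff.is_null.sum()) == round(89 * 0.5)
        assert np.all(eff.beta_std[eff.is_null] == 0)

    def test_total_variance_law_of_large_numbers(self, full_panel):
        # mean of sum(beta_std^2) over many draws approaches vg
        vg, draws = 0.05, 1000
        totals = np.empty(draws)
        for i in range(draws):
            arch = GeneticArchitecture(m=89, vg=vg, pi0=0.5, seed=i)
            totals[i] = (simulate_effects(arch, full_panel).beta_std ** 2).sum()
        mc_se = totals.std(ddof=1) / np.sqrt(draws)
        assert abs(totals.mean() - vg) < 3 * mc_se

    def test_pi0_one_with_vg_positive_rejected(self):
        with pytest.raises(ValueError):
            GeneticArchitecture(m=10, vg=0.1, pi0=1.0)

    def test_dosage_scale_conversion_uses_marker_variance(self):
        panel = make_panel([0.2, 0.2], imputed=[False, True])
        arch = GeneticArchitecture(m=2, vg=0.3, pi0=0.0, seed=3)
        eff = simulate_effects(arch, panel)
        var_dos = panel.dosage_variance()
        np.testing.assert_allclose(eff.beta_dosage * np.sqrt(var_dos), eff.beta_std)


class TestSimulatePhenotypes:
    def test_noise_free_limit_is_exact_linear_model(self, small_panel):
        geno = simulate_genotypes(small_panel, 40, seed=1)
        arch = GeneticArchitecture(m=12, vg=0.0, pi0=1.0, seed=1)
        eff = simulate_effects(arch, small_panel)
        design = offspring_design(40, p_never_drinker=0.0, p_zero_occasion=0.0,
                                  dropout_per_occasion=0.0)
        vc = VarianceComponents(tau2=0.0, sigma2=1e-12, beta_age=0.02, intercept=0.3)
        ph = simulate_phenotypes(geno, eff, design, vc, seed=2)
        np.testing.assert_allclose(ph.data["log_units"],
                                   0.3 + 0.02 * ph.data["age"], atol=1e-4)

    def test_record_count_without_dropout_or_zeros(self, small_panel):
        geno = simulate_genotypes(small_panel, 100, seed=1)
        eff = simulate_effects(GeneticArchitecture(m=12, vg=0, pi0=1, seed=1),
                               small_panel)
        design = offspring_design(100, p_never_drinker=0.0, p_zero_occasion=0.0,
                                  dropout_per_occasion=0.0)
        ph = simulate_phenotypes(geno, eff, design, VarianceComponents(), seed=2)
        assert ph.n_records == 500

    def test_genetic_value_recovery(self):
        # regressing person-mean log units on the true aggregate genetic value
        # must recover a slope of 1
        panel, geno, eff, pheno, _ = simulate_cohort(
            n=3000, m=20, vg=0.20, pi0=0.0, seed=11,
            design=offspring_design(3000, p_never_drinker=0.0,
                                    p_zero_occasion=0.0,
                                    dropout_per_occasion=0.0))
        pm = pheno.person_means().set_index("person_id")
        g = eff.genetic_values(geno).reindex(pm.index).to_numpy()
        y = pm["mean_log_units"].to_numpy()
        X = np.column_stack([np.ones_like(g), g])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(resid @ resid / (len(y) - 2) /
                     np.sum((g - g.mean()) ** 2))
        assert abs(beta[1] - 1.0) < 3 * se

    def test_variance_decomposition(self):
        # var(log units) ~ realized genetic + tau2 + sigma2 within 5% relative
        panel, geno, eff, pheno, _ = simulate_cohort(
            n=10_000, m=20, vg=0.2, pi0=0.5, seed=21,
            design=offspring_design(10_000, p_never_drinker=0.0,
                                    p_zero_occasion=0.0,
                                    dropout_per_occasion=0.0),
            vc=VarianceComponents(tau2=0.7, sigma2=0.5, beta_age=0.0))
        vg_real = float(np.var(eff.genetic_values(geno)))
        expected = vg_real + 0.7 + 0.5
        observed = float(pheno.data["log_units"].var())
        assert abs(observed - expected) / expected < 0.05

    def test_never_drinker_units_all_zero(self):
        panel, geno, eff, pheno, _ = simulate_cohort(n=400, seed=5)
        flagged = pheno.data.loc[pheno.data["never_drinker"], "units"]
        assert len(flagged) > 0
        assert np.all(flagged == 0)

    def test_seed_reproducibility_byte_identical(self):
        _, _, _, a, _ = simulate_cohort(n=100, seed=7)
        _, _, _, b, _ = simulate_cohort(n=100, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_dimension_mismatch_rejected(self, small_panel):
        geno = simulate_genotypes(small_panel, 10, seed=1)
        eff = simulate_effects(GeneticArchitecture(m=12, vg=0, pi0=1, seed=1),
                               small_panel)
        with pytest.raises(ValueError):
            simulate_phenotypes(geno, eff, offspring_design(11),
                                VarianceComponents(), seed=1)

    def test_mother_design_shape(self):
        d = mother_design(50)
        assert len(d.occasions) == 10
        assert d.occasions[0][1] < d.occasions[-1][1]


class TestSimulateCovariates:
    def test_default_shape(self):
        cov = simulate_covariates(120, seed=1)
        assert cov.data.shape == (120, 1 + 10 + 48)
        assert len(cov.pc_cols) == 10 and len(cov.confounder_cols) == 48

    def test_pcs_standard_normal(self):
        cov = simulate_covariates(5000, seed=2)
        pcs = cov.data[list(cov.pc_cols)].to_numpy()
        assert np.all(np.abs(pcs.mean(axis=0)) < 3 / np.sqrt(5000))
        corr = np.corrcoef(pcs.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.all(np.abs(off) < 4 / np.sqrt(5000))

    def test_injected_confounder_correlates_with_snp(self, small_panel):
        geno = simulate_genotypes(small_panel, 5000, seed=3)
        cov = simulate_covariates(5000, seed=4, sample_ids=geno.sample_ids,
                                  inject=("conf02", "rs1000003", 0.3), geno=geno)
        g = geno.dosage_series("rs1000003").to_numpy()
        r = np.corrcoef(cov.data["conf02"], g)[0, 1]
        assert abs(r - 0.3) < 0.05
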