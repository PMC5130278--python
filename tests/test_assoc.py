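"""Filters, mixed-model association, multiplicity, screens, transforms."""

import numpy as np
import pandas as pd
import pytest

from longprs.assoc import (DegenerateInputError, FilterSpec, apply_filters,
                           bonferroni_threshold, fit_cross_sectional,
                           fit_repeated, format_p, percent_change,
                           percent_change_label, pleiotropy_screen,
                           scan_repeated)
from longprs.simcohort import (GeneticArchitecture, LongPhenotype,
                               VarianceComponents, mother_design,
                               offspring_design, simulate_covariates,
                               simulate_effects, simulate_genotypes)

from conftest import make_panel, simulate_cohort


class TestApplyFilters:
    def test_toy_never_drinker_and_zero_occasions(self, toy_phenotype):
        out, audit = apply_filters(toy_phenotype, FilterSpec())
        assert "A" not in set(out.data["person_id"])
        assert (out.data["person_id"] == "B").sum() == 2
        assert audit.never_drinkers_removed == 1
        assert audit.zero_occasion_records_removed == 1  # B's single zero

    def test_identity_when_everything_disabled(self, toy_phenotype):
        spec = FilterSpec(drop_never_drinkers=False, drop_zero_occasions=False)
        out, audit = apply_filters(toy_phenotype, spec)
        pd.testing.assert_frame_equal(out.data, toy_phenotype.data)
        assert audit.never_drinkers_removed == 0
        assert audit.zero_occasion_records_removed == 0
        assert audit.n_records_in == audit.n_records_out

    def test_sensitivity_occasion_exclusion_on_mother_table(self):
        # dropping the four differently-phrased questionnaire waves leaves 6
        _, _, _, pheno, _ = simulate_cohort(
            n=200, seed=3, design=mother_design(200, dropout_per_occasion=0.0))
        spec = FilterSpec(exclude_occasions=("4y", "7y", "8y", "12y"))
        out, audit = apply_filters(pheno, spec)
        assert set(out.data["occasion"]) == {"0y", "1y", "2y", "3y", "6y", "18y"}
        assert audit.excluded_occasion_records_removed > 0

    def test_unknown_occasion_label_rejected(self, toy_phenotype):
        with pytest.raises(ValueError, match="exclude_occasions"):
            apply_filters(toy_phenotype, FilterSpec(exclude_occasions=("nope",)))

    def test_flagged_person_exclusion(self, toy_phenotype):
        d = toy_phenotype.data.copy()
        d["pregnant"] = d["person_id"] == "B"
        out, audit = apply_filters(
            LongPhenotype(d),
            FilterSpec(drop_never_drinkers=False, drop_zero_occasions=False,
                       exclude_flagged="pregnant"))
        assert set(out.data["person_id"]) == {"A"}
        assert audit.flagged_records_removed == 3


class TestFitRepeated:
    def test_slope_recovery_on_simulated_data(self):
        panel = make_panel([0.3])
        geno = simulate_genotypes(panel, 2000, seed=1)
        eff = simulate_effects(GeneticArchitecture(m=1, vg=0.0, pi0=1.0, seed=1), panel)
        eff.beta_dosage = np.array([0.10])
        design = offspring_design(2000, p_never_drinker=0.0,
                                  p_zero_occasion=0.0, dropout_per_occasion=0.0)
        pheno = simulate_phenotypes_with(geno, eff, design)
        res = fit_repeated(pheno, geno.dosage_series("rs0"))
        assert res.kind == "repeated"
        assert abs(res.beta - 0.10) < 3 * res.se
        assert res.n == 10_000 and res.n_persons == 2000

    def test_monomorphic_snp_rejected(self, toy_phenotype):
        filt, _ = apply_filters(toy_phenotype, FilterSpec())
        dosage = pd.Series(2.0, index=["A", "B"])
        with pytest.raises(DegenerateInputError):
            fit_repeated(filt, dosage)

    def test_scan_agrees_with_exact_mixed_model(self):
        # shared-variance-component GLS scan vs per-SNP REML MixedLM
        panel, geno, eff, pheno, covars = simulate_cohort(n=600, m=5, seed=13)
        filt, _ = apply_filters(pheno, FilterSpec())
        scan = scan_repeated(filt, geno, covars).set_index("snp_id")
        for snp in panel.snp_ids[:3]:
            exact = fit_repeated(filt, geno.dosage_series(snp), covars)
            row = scan.loc[snp]
            assert abs(row["beta"] - exact.beta) < 0.15 * exact.se
            assert abs(row["se"] / exact.se - 1) < 0.05

    def test_scan_invariant_to_row_order(self):
        panel, geno, eff, pheno, covars = simulate_cohort(n=200, m=4, seed=17)
        filt, _ = apply_filters(pheno, FilterSpec())
        base = scan_repeated(filt, geno, covars)
        shuffled = LongPhenotype(
            filt.data.sample(frac=1.0, random_state=5).reset_index(drop=True))
        perm = scan_repeated(shuffled, geno, covars)
        np.testing.assert_allclose(base["beta"], perm["beta"], atol=1e-10)
        np.testing.assert_allclose(base["p"], perm["p"], atol=1e-10)


def simulate_phenotypes_with(geno, eff, design,
                             vc=VarianceComponents(tau2=0.4, sigma2=0.4,
                                                   beta_age=0.02)):
    from longprs.simcohort import simulate_phenotypes
    return simulate_phenotypes(geno, eff, design, vc, seed=99)


class TestFitCrossSectional:
    def test_exact_linear_toy(self):
        rows = [{"person_id": p, "cohort": "offspring", "occasion": "t",
                 "age": 16.0, "units": float(np.exp(lu))}
                for p, lu in zip("abcd", [0.0, 0.1, 0.2, 0.1])]
        pheno = LongPhenotype(pd.DataFrame(rows))
        dosage = pd.Series([0.0, 1.0, 2.0, 1.0], index=list("abcd"))
        res = fit_cross_sectional(pheno, "t", dosage)
        assert res.beta == pytest.approx(0.1, abs=1e-10)
        assert res.occasion == "t"

    def test_occasion_absent(self, toy_phenotype):
        with pytest.raises(ValueError, match="occasion"):
            fit_cross_sectional(toy_phenotype, "t9", pd.Series(dtype=float))

    def test_underdetermined_model_rejected(self):
        rows = [{"person_id": p, "cohort": "offspring", "occasion": "t",
                 "age": 16.0, "units": 2.0} for p in "ab"]
        pheno = LongPhenotype(pd.DataFrame(rows))
        dosage = pd.Series([0.0, 1.0], index=list("ab"))
        with pytest.raises(DegenerateInputError):
            fit_cross_sectional(pheno, "t", dosage)

    def test_per_occasion_estimates_pool_to_repeated_estimate(self):
        # inverse-variance-weighted cross-sectional betas should agree with
        # the repeated-measures estimate on exchangeable simulated data
        panel = make_panel([0.3])
        geno = simulate_genotypes(panel, 2000, seed=2)
        eff = simulate_effects(GeneticArchitecture(m=1, vg=0.0, pi0=1.0, seed=1), panel)
        eff.beta_dosage = np.array([0.08])
        design = offspring_design(2000, p_never_drinker=0.0,
                                  p_zero_occasion=0.0, dropout_per_occasion=0.0)
        pheno = simulate_phenotypes_with(geno, eff, design)
        dosage = geno.dosage_series("rs0")
        rep = fit_repeated(pheno, dosage)
        betas, ws = [], []
        for occ in pheno.occasion_labels:
            cs = fit_cross_sectional(pheno, occ, dosage)
            betas.append(cs.beta)
            ws.append(1 / cs.se ** 2)
        pooled = np.average(betas, weights=ws)
        pooled_se = 1 / np.sqrt(np.sum(ws))
        assert abs(pooled - rep.beta) < 3 * max(pooled_se, rep.se)


class TestMultiplicityAndTransforms:
    @pytest.mark.parametrize("args, value, printed", [
        ((0.05, 89, 1), 0.05 / 89, "0.00056"),
        ((0.05, 89, 15), 0.05 / (89 * 15), "0.000037"),
        ((0.05, 89, 5), 0.05 / (89 * 5), "0.00011"),
        ((0.05, 1, 1), 0.05, "0.05"),
    ])
    def test_bonferroni_thresholds(self, args, value, printed):
        t = bonferroni_threshold(*args)
        assert t == pytest.approx(value, rel=1e-12)
        assert format_p(t) == printed

    def test_bonferroni_scales_linearly_in_alpha(self):
        for n, k in [(89, 1), (89, 15), (7, 3)]:
            assert bonferroni_threshold(0.02, n, k) * 2 == pytest.approx(
                bonferroni_threshold(0.04, n, k), rel=1e-12)

    def test_bonferroni_invalid_counts(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    @pytest.mark.parametrize("beta, expected, label", [
        (-0.177, 16.2, "16.2% fewer"),
        (0.0, 0.0, "0% change"),
        (np.log(0.5), 50.0, "50.0% fewer"),
    ])
    def test_percent_change(self, beta, expected, label):
        assert percent_change(beta) == pytest.approx(expected, abs=0.05)
        assert percent_change_label(beta) == label

    def test_percent_change_roundtrip_identity(self):
        for x in np.linspace(1, 95, 25):
            assert percent_change(np.log(1 - x / 100)) == pytest.approx(x, rel=1e-12)


class TestPleiotropyScreen:
    def test_null_panel_rejection_rate_at_nominal_alpha(self):
        # confounders independent of genotype: per-test rejection at alpha
        # stays within binomial bounds
        panel, geno, _, _, covars = simulate_cohort(n=500, m=20, seed=31,
                                                    n_confounders=24)
        screen = pleiotropy_screen(geno, covars)
        frac = np.mean(screen["p"] < 0.05)
        n_tests = len(screen)
        bound = 3 * np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(frac - 0.05) < bound
        assert screen["significant"].sum() == 0

    def test_injected_confounder_flagged_at_bonferroni_level(self, small_panel):
        geno = simulate_genotypes(small_panel, 5000, seed=33)
        covars = simulate_covariates(5000, n_confounders=8, seed=34,
                                     sample_ids=geno.sample_ids,
                                     inject=("conf02", "rs1000005", 0.3),
                                     geno=geno)
        screen = pleiotropy_screen(geno, covars)
        hit = screen[(screen["instrument"] == "rs1000005") &
                     (screen["target"] == "conf02")]
        assert bool(hit["significant"].iloc[0])

    def test_constant_confounder_rejected(self, small_panel):
        geno = simulate_genotypes(small_panel, 50, seed=35)
        covars = simulate_covariates(50, n_confounders=4, seed=36,
                                     sample_ids=geno.sample_ids)
        covars.data["conf01"] = 1.0
        with pytest.raises(DegenerateInputError):
            pleiotropy_screen(geno, covars)

    def test_outcome_regression_with_age_adjustment(self, small_panel):
        # score-vs-risk-factor use: continuous outcome, adjusting for age
        rng = np.random.default_rng(37)
        geno = simulate_genotypes(small_panel, 800, seed=38)
        covars = simulate_covariates(800, n_confounders=2, seed=39,
                                     sample_ids=geno.sample_ids)
        covars.data["mean_age"] = rng.normal(35, 4, 800)
        score = pd.Series(rng.standard_normal(800), index=geno.sample_ids,
                          name="PGRS")
        covars.data["sbp"] = (120 + 0.3 * covars.data["mean_age"]
                              + 5 * rng.standard_normal(800))
        covars.binary["sbp"] = False
        out = pleiotropy_screen(score.to_frame(), covars, targets=["sbp"],
                                adjust=("mean_age",), kind="outcome")
        assert out["kind"].iloc[0] == "outcome"
        assert not out["significant"].iloc[0]
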