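import numpy as np
import pandas as pd
import pytest

from longprs.simcohort import (CohortDesign, GeneticArchitecture, SnpPanel,
                               VarianceComponents, default_panel,
                               offspring_design, simulate_covariates,
                               simulate_effects, simulate_genotypes,
                               simulate_phenotypes)


@pytest.fixture(scope="session")
def small_panel():
    return default_panel(12, seed=0)


@pytest.fixture(scope="session")
def full_panel():
    return default_panel(89, seed=0)


def make_panel(mafs, imputed=None, seed=0):
    """Hand-built panel with given MAFs (hard-called unless flagged)."""
    m = len(mafs)
    if imputed is None:
        imputed = [False] * m
    return SnpPanel(pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "maf": list(mafs),
        "imputed": list(imputed),
        "source": "gwas",
    }))


def simulate_cohort(n=500, m=20, vg=0.2, pi0=0.5, seed=0, design=None,
                    vc=None, n_confounders=8, panel=None):
    """One-call cohort for tests: (panel, geno, effects, pheno, covars)."""
    if panel is None:
        panel = default_panel(m, seed=seed)
    if design is None:
        design = offspring_design(n, dropout_per_occasion=0.0)
    if vc is None:
        vc = VarianceComponents()
    geno = simulate_genotypes(panel, n, seed=seed + 1)
    arch = GeneticArchitecture(m=panel.m, vg=vg, pi0=pi0, seed=seed + 2)
    effects = simulate_effects(arch, panel)
    pheno = simulate_phenotypes(geno, effects, design, vc, seed=seed + 3)
    covars = simulate_covariates(n, n_pcs=10, n_confounders=n_confounders,
                                 seed=seed + 4, sample_ids=geno.sample_ids)
    return panel, geno, effects, pheno, covars


@pytest.fixture()
def toy_phenotype():
    """Hand-checkable table: person A all zeros, person B mixed."""
    from longprs.simcohort import LongPhenotype
    rows = []
    for occ, (ua, ub) in zip(["t1", "t2", "t3"], [(0, 0), (0, 2), (0, 4)]):
        rows.append({"person_id": "A", "cohort": "offspring", "occasion": occ,
                     "age": 16.0, "units": float(ua)})
        rows.append({"person_id": "B", "cohort": "offspring", "occasion": occ,
                     "age": 16.0, "units": float(ub)})
    return LongPhenotype(pd.DataFrame(rows))
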