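"""Synthetic cohort generator.

Emulates the data structure of a longitudinal birth cohort in which mothers
(10 questionnaire occasions, mean ages ~28 to ~48) and their offspring
(5 occasions, ages ~15 to ~21) report weekly alcohol consumption, and both
are genotyped on a small curated candidate-SNP panel (89 SNPs by default,
a mix of directly genotyped and imputed markers).

The phenotype model is the one the downstream association stage assumes:
natural-log weekly units follow a linear model in age and genotype with a
person-level random intercept and occasion-level residual noise,

    log u_it = mu + beta_age * age_it + sum_j beta_j g_ij + a_i + e_it,

with zero inflation at two levels: a fraction of people never drink
(units are zero at every occasion) and any remaining occasion can be an
incidental zero (no drinks in the reporting week).  Markers are simulated
independent (no LD): the panel emulated is a curated candidate set, and the
polygenic accuracy model used downstream assumes independent markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SnpPanel", "GeneticArchitecture", "CohortDesign", "VarianceComponents",
    "GenotypeMatrix", "EffectVector", "LongPhenotype", "CovariateTable",
    "simulate_genotypes", "simulate_effects", "simulate_phenotypes",
    "simulate_covariates", "default_panel", "mother_design",
    "offspring_design",
]

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "maf", "imputed", "source"]

_BASES = ("A", "C", "G", "T")
_SOURCES = ("gwas", "functional", "unknown")

# accuracy (dosage-vs-true-genotype r^2) emulated for imputed markers; the
# panel emulated retains imputed SNPs only above r^2 = 0.8
IMPUTATION_R2 = 0.9


@dataclass(frozen=True)
class SnpPanel:
    """Candidate-SNP panel metadata: one row per marker.

    ``table`` columns: snp_id, chrom, pos (1-based), effect_allele,
    other_allele, maf, imputed (bool), source ({gwas, functional, unknown}).
    The effect allele is the minor allele; ``maf`` may be 0 only for
    deliberately degenerate test panels.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        if len(t) < 1:
            raise ValueError("panel must contain at least one SNP")
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids in panel: {dups}")
        maf = np.asarray(t["maf"], dtype=float)
        if np.any(maf < 0) or np.any(maf > 0.5):
            raise ValueError("maf must lie in [0, 0.5]")
        bad = set(t["source"]) - set(_SOURCES)
        if bad:
            raise ValueError(f"unknown panel sources: {bad}")
        # normalise dtypes without mutating the caller's frame
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy(dtype=float)

    @property
    def imputed(self) -> np.ndarray:
        return self.table["imputed"].to_numpy(dtype=bool)

    def dosage_variance(self) -> np.ndarray:
        """Model variance of each marker's dosage.

        2 maf (1 - maf) under HWE for hard calls; posterior-mean dosages of
        imputed markers are shrunk towards the mean, scaling the variance by
        the imputation accuracy ``IMPUTATION_R2``.
        """
        base = 2 * self.maf * (1 - self.maf)
        return np.where(self.imputed, IMPUTATION_R2 * base, base)


def default_panel(m: int = 89, seed: int = 0, n_gwas: int | None = None,
                  frac_imputed: float = 58 / 89) -> SnpPanel:
    """Generate a synthetic candidate panel.

    Defaults mirror the emulated design: 89 markers, roughly two thirds
    imputed, most sourced from GWAS hits and the rest from functional
    literature.  MAFs are drawn uniform on [0.05, 0.5] (candidate SNPs are
    common variants).
    """
    if m < 1:
        raise ValueError("panel size m must be >= 1")
    rng = np.random.default_rng(seed)
    if n_gwas is None:
        n_gwas = int(round(m * 68 / 89))
    maf = rng.uniform(0.05, 0.5, m)
    imputed = np.zeros(m, dtype=bool)
    imputed[rng.choice(m, size=int(round(m * frac_imputed)), replace=False)] = True
    alleles = np.array([rng.choice(len(_BASES), size=2, replace=False)
                        for _ in range(m)])
    table = pd.DataFrame({
        "snp_id": [f"rs{1000000 + i}" for i in range(m)],
        "chrom": rng.integers(1, 23, m).astype(str),
        "pos": np.sort(rng.integers(1, 250_000_000, m)),
        "effect_allele": [_BASES[a] for a in alleles[:, 0]],
        "other_allele": [_BASES[a] for a in alleles[:, 1]],
        "maf": maf,
        "imputed": imputed,
        "source": ["gwas"] * n_gwas + ["functional"] * (m - n_gwas),
    })
    return SnpPanel(table)


@dataclass(frozen=True)
class GeneticArchitecture:
    """Sparse polygenic architecture on the standardized-genotype scale.

    ``vg`` is the fraction of log-unit variance jointly explained by the
    panel; ``pi0`` the fraction of null markers.
    """

    m: int
    vg: float
    pi0: float
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 <= self.vg < 1:
            raise ValueError("vg must lie in [0, 1)")
        if not 0 <= self.pi0 <= 1:
            raise ValueError("pi0 must lie in [0, 1]")
        if self.pi0 == 1 and self.vg > 0:
            raise ValueError("pi0 = 1 (all markers null) is incompatible with vg > 0")


@dataclass(frozen=True)
class CohortDesign:
    """Occasion layout and zero-inflation/attrition for one cohort.

    ``occasions`` is a list of (label, mean_age, sd_age).  ``p_never_drinker``
    flags whole persons as lifetime abstainers; ``p_zero_occasion`` zeroes
    individual reporting weeks; ``dropout_per_occasion`` is the per-wave
    hazard of permanently leaving the study after the first occasion.
    """

    n_individuals: int
    occasions: tuple
    cohort: str = "mother"
    p_never_drinker: float = 0.10
    p_zero_occasion: float = 0.15
    dropout_per_occasion: float = 0.05

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        labels = [o[0] for o in self.occasions]
        if len(labels) != len(set(labels)):
            raise ValueError("occasion labels must be unique")
        for lab, mean_age, sd_age in self.occasions:
            if mean_age <= 0 or sd_age < 0:
                raise ValueError(f"invalid age for occasion {lab!r}")
        for name in ("p_never_drinker", "p_zero_occasion", "dropout_per_occasion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "occasions", tuple(tuple(o) for o in self.occasions))

    @property
    def occasion_labels(self) -> list:
        return [o[0] for o in self.occasions]


def mother_design(n_individuals: int = 4000, **overrides) -> CohortDesign:
    """Mothers' design: 10 postal-questionnaire occasions, mean ages ~28-48.

    Occasion labels are years post pregnancy; mean ages follow the emulated
    cohort's questionnaire schedule.
    """
    occasions = (
        ("0y", 28.2, 4.8), ("1y", 29.5, 4.7), ("2y", 30.7, 4.6),
        ("3y", 32.9, 4.5), ("4y", 34.0, 4.5), ("6y", 34.2, 4.5),
        ("7y", 36.3, 4.5), ("8y", 37.5, 4.4), ("12y", 41.5, 4.4),
        ("18y", 48.3, 4.3),
    )
    kw = dict(n_individuals=n_individuals, occasions=occasions, cohort="mother")
    kw.update(overrides)
    return CohortDesign(**kw)


def offspring_design(n_individuals: int = 3000, **overrides) -> CohortDesign:
    """Offspring design: 5 occasions from adolescence to early adulthood."""
    occasions = (
        ("15y", 15.1, 0.3), ("16y", 16.2, 0.4), ("17y", 17.2, 0.4),
        ("18y", 18.2, 0.6), ("21y", 20.5, 0.5),
    )
    kw = dict(n_individuals=n_individuals, occasions=occasions, cohort="offspring")
    kw.update(overrides)
    return CohortDesign(**kw)


@dataclass(frozen=True)
class VarianceComponents:
    """Noise model for log weekly units.

    tau2: person random-intercept variance (log-units^2); sigma2: occasion
    residual variance; beta_age: fixed age slope (log-units per year);
    intercept: grand mean of log units at age 0.
    """

    tau2: float = 0.7
    sigma2: float = 0.5
    beta_age: float = 0.02
    intercept: float = 0.3

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


@dataclass
class GenotypeMatrix:
    """Person x SNP dosage matrix in [0, 2] plus panel metadata."""

    dosages: np.ndarray
    sample_ids: np.ndarray
    panel: SnpPanel

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match dosage rows")
        if len(np.unique(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if m != self.panel.m:
            raise ValueError("dosage columns must match panel size")
        if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def dosage_series(self, snp_id: str) -> pd.Series:
        """Per-person dosage for one SNP, indexed by sample id."""
        j = int(np.flatnonzero(self.panel.snp_ids == snp_id)[0])
        return pd.Series(self.dosages[:, j], index=self.sample_ids, name=snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=pd.Index(self.sample_ids, name="person_id"),
                            columns=self.panel.snp_ids)

    def subset_persons(self, ids) -> "GenotypeMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(ids)
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return GenotypeMatrix(self.dosages[idx], np.asarray(ids), self.panel)


@dataclass
class EffectVector:
    """Per-SNP effects on log units, on both genotype scales.

    ``beta_std`` is per standardized allele (unit-variance genotype);
    ``beta_dosage`` is per copy of the minor allele,
    beta_dosage = beta_std / sqrt(2 maf (1 - maf)).
    """

    beta_std: np.ndarray
    beta_dosage: np.ndarray
    is_null: np.ndarray

    def __post_init__(self):
        self.beta_std = np.asarray(self.beta_std, dtype=float)
        self.beta_dosage = np.asarray(self.beta_dosage, dtype=float)
        self.is_null = np.asarray(self.is_null, dtype=bool)
        if not (len(self.beta_std) == len(self.beta_dosage) == len(self.is_null)):
            raise ValueError("effect arrays must have equal length")

    @property
    def m(self) -> int:
        return len(self.beta_std)

    def genetic_values(self, geno: GenotypeMatrix) -> pd.Series:
        """Aggregate genetic value per person on the dosage scale."""
        vals = geno.dosages @ self.beta_dosage
        return pd.Series(vals, index=geno.sample_ids, name="genetic_value")


@dataclass
class LongPhenotype:
    """Long-format repeated measures of weekly alcohol consumption.

    ``data`` columns: person_id, cohort, occasion, age, units, log_units
    (natural log; NaN where units == 0), never_drinker (person-level flag).
    """

    data: pd.DataFrame

    REQUIRED = ("person_id", "cohort", "occasion", "age", "units")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        d = self.data
        if "log_units" not in d.columns:
            d = d.copy()
            with np.errstate(divide="ignore"):
                d["log_units"] = np.where(d["units"] > 0, np.log(d["units"]), np.nan)
        if "never_drinker" not in d.columns:
            d = d.copy() if d is self.data else d
            ever = d.groupby("person_id")["units"].transform("max") > 0
            d["never_drinker"] = ~ever
        self.data = d.reset_index(drop=True)

    @property
    def persons(self) -> np.ndarray:
        return self.data["person_id"].unique()

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def occasion_labels(self) -> list:
        return list(pd.unique(self.data["occasion"]))

    def subset_persons(self, ids) -> "LongPhenotype":
        keep = self.data["person_id"].isin(set(ids))
        return LongPhenotype(self.data.loc[keep].reset_index(drop=True))

    def person_means(self) -> pd.DataFrame:
        """Per-person mean log units and mean age over non-zero records."""
        ok = self.data.dropna(subset=["log_units"])
        g = ok.groupby("person_id")
        out = g.agg(mean_log_units=("log_units", "mean"),
                    mean_age=("age", "mean"),
                    n_records=("log_units", "size"))
        return out.reset_index()


@dataclass
class CovariateTable:
    """Person-level covariates: ancestry-PC-like columns plus a confounder panel.

    ``binary`` flags which confounder columns are 0/1.
    """

    data: pd.DataFrame
    pc_cols: tuple
    confounder_cols: tuple
    binary: dict = field(default_factory=dict)

    def __post_init__(self):
        if "person_id" not in self.data.columns:
            raise ValueError("covariate table requires a person_id column")
        for c in list(self.pc_cols) + list(self.confounder_cols):
            if c not in self.data.columns:
                raise ValueError(f"declared covariate column {c!r} absent")
        self.pc_cols = tuple(self.pc_cols)
        self.confounder_cols = tuple(self.confounder_cols)

    def pcs(self) -> pd.DataFrame:
        return self.data.set_index("person_id")[list(self.pc_cols)]


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_genotypes(panel: SnpPanel, n: int, seed: int) -> GenotypeMatrix:
    """Draw an n x m dosage matrix under Hardy-Weinberg equilibrium.

    Hard-called markers get dosages in {0, 1, 2} ~ Binomial(2, maf).
    Imputed markers get continuous dosages in [0, 2] built as the sum of two
    Beta-distributed allele doses with mean ``maf``, emulating posterior-mean
    dosages from imputation with accuracy ``r2`` ~ 0.9 (the Beta concentration
    is chosen so the dosage variance is r2 * 2 maf (1 - maf)).  Markers are
    mutually independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    maf = panel.maf
    m = panel.m
    dos = np.empty((n, m), dtype=float)
    for j in range(m):
        p = maf[j]
        if p == 0:
            dos[:, j] = 0.0
        elif panel.imputed[j]:
            # per-allele Beta(a, b) with mean p and var IMPUTATION_R2 * p(1-p)
            # => a + b = 1/IMPUTATION_R2 - 1
            s = 1.0 / IMPUTATION_R2 - 1.0
            a, b = p * s, (1 - p) * s
            dos[:, j] = rng.beta(a, b, n) + rng.beta(a, b, n)
        else:
            dos[:, j] = rng.binomial(2, p, n).astype(float)
    sample_ids = np.array([f"id{i:06d}" for i in range(n)])
    return GenotypeMatrix(dos, sample_ids, panel)


def simulate_effects(arch: GeneticArchitecture, panel: SnpPanel) -> EffectVector:
    """Draw sparse per-SNP effects.

    Exactly round(m * pi0) markers (chosen uniformly at random) are null.
    Non-null standardized effects are N(0, vg / (m (1 - pi0))), so the panel
    jointly explains ``vg`` of the trait variance in expectation.  Dosage-
    scale effects divide by the marker's dosage standard deviation (including
    the imputation shrinkage for imputed markers), so the realized genetic
    variance matches the standardized-scale architecture.
    """
    if panel.m != arch.m:
        raise ValueError("panel size and architecture m disagree")
    rng = np.random.default_rng(arch.seed)
    m = arch.m
    n_null = int(round(m * arch.pi0))
    is_null = np.zeros(m, dtype=bool)
    if n_null > 0:
        is_null[rng.choice(m, size=n_null, replace=False)] = True
    beta_std = np.zeros(m)
    n_causal = m - n_null
    if n_causal > 0 and arch.vg > 0:
        sd = np.sqrt(arch.vg / n_causal)
        beta_std[~is_null] = rng.normal(0.0, sd, n_causal)
    denom = np.sqrt(panel.dosage_variance())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_dosage = np.where(denom > 0, beta_std / denom, 0.0)
    return EffectVector(beta_std, beta_dosage, is_null)


def simulate_phenotypes(geno: GenotypeMatrix, effects: EffectVector,
                        design: CohortDesign, vc: VarianceComponents,
                        seed: int) -> LongPhenotype:
    """Generate long-format weekly units under the random-intercept model.

    log u_it = intercept + beta_age * age_it + g_i + a_i + e_it, units =
    exp(log u); never-drinkers have all occasions zeroed, other occasions are
    independently zeroed with ``p_zero_occasion``, and cumulative dropout
    removes occasions from the first post-baseline wave onwards.
    """
    if geno.n != design.n_individuals:
        raise ValueError("genotype rows must equal design.n_individuals")
    if effects.m != geno.m:
        raise ValueError("effect vector length must equal genotype columns")
    rng = np.random.default_rng(seed)
    n = design.n_individuals
    k = len(design.occasions)
    g = geno.dosages @ effects.beta_dosage
    a = rng.normal(0.0, np.sqrt(vc.tau2), n) if vc.tau2 > 0 else np.zeros(n)

    labels = design.occasion_labels
    means = np.array([o[1] for o in design.occasions])
    sds = np.array([o[2] for o in design.occasions])
    age = rng.normal(means[None, :], sds[None, :], (n, k))
    e = rng.normal(0.0, np.sqrt(vc.sigma2), (n, k))
    log_u = vc.intercept + vc.beta_age * age + (g + a)[:, None] + e

    never = rng.random(n) < design.p_never_drinker
    zero_occ = rng.random((n, k)) < design.p_zero_occasion

    # cumulative dropout: person leaves permanently before occasion t >= 1
    if design.dropout_per_occasion > 0 and k > 1:
        drop = rng.random((n, k - 1)) < design.dropout_per_occasion
        gone = np.concatenate([np.zeros((n, 1), bool),
                               np.cumsum(drop, axis=1) > 0], axis=1)
    else:
        gone = np.zeros((n, k), bool)

    units = np.exp(log_u)
    units[never, :] = 0.0
    units[~never[:, None] & zero_occ] = 0.0

    keep = ~gone
    pid = np.repeat(geno.sample_ids, k).reshape(n, k)
    occ = np.tile(np.array(labels, dtype=object), (n, 1))
    data = pd.DataFrame({
        "person_id": pid[keep],
        "cohort": design.cohort,
        "occasion": occ[keep],
        "age": age[keep],
        "units": units[keep],
    })
    pos = data["units"].to_numpy() > 0
    log_units = np.full(len(data), np.nan)
    log_units[pos] = np.log(data["units"].to_numpy()[pos])
    data["log_units"] = log_units
    data["never_drinker"] = np.repeat(never, k).reshape(n, k)[keep]
    return LongPhenotype(data)


def simulate_covariates(n: int, n_pcs: int = 10, n_confounders: int = 48,
                        seed: int = 0, sample_ids=None,
                        inject: tuple | None = None,
                        geno: GenotypeMatrix | None = None) -> CovariateTable:
    """Simulate person-level covariates.

    PCs are independent standard normals (orthogonal in expectation).  The
    confounder panel mixes binary (half) and continuous (half) columns drawn
    independently of genotype, so the pleiotropy screen is null by
    construction.  ``inject=(confounder_name, snp_id, rho)`` replaces one
    continuous confounder with a variable correlated ``rho`` with the named
    SNP's standardized dosage — a positive control for the screen.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_pcs < 0 or n_confounders < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = np.array([f"id{i:06d}" for i in range(n)])
    cols = {"person_id": np.asarray(sample_ids)}
    pc_cols = tuple(f"PC{i+1}" for i in range(n_pcs))
    for c in pc_cols:
        cols[c] = rng.standard_normal(n)
    conf_cols = tuple(f"conf{i+1:02d}" for i in range(n_confounders))
    binary = {}
    for i, c in enumerate(conf_cols):
        if i % 2 == 0:
            p = rng.uniform(0.1, 0.5)
            cols[c] = rng.binomial(1, p, n).astype(float)
            binary[c] = True
        else:
            cols[c] = rng.standard_normal(n)
            binary[c] = False
    if inject is not None:
        conf_name, snp_id, rho = inject
        if geno is None:
            raise ValueError("inject requires the genotype matrix")
        if conf_name not in conf_cols:
            raise ValueError(f"unknown confounder {conf_name!r}")
        gdos = geno.dosage_series(snp_id).reindex(np.asarray(sample_ids)).to_numpy()
        gstd = (gdos - gdos.mean()) / gdos.std()
        cols[conf_name] = rho * gstd + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        binary[conf_name] = False
    return CovariateTable(pd.DataFrame(cols), pc_cols, conf_cols, binary)
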