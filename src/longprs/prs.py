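"""Weighted polygenic scores and p-value-threshold cross-validation.

A score at threshold t is the dosage-weighted sum over SNPs whose training
p-value is at most t, weighted by the training beta.  The optimal threshold
is chosen by repeated 80/20 person-level cross-validation: per repeat the
per-SNP repeated-measures models are refit on the training persons, a score
is built per threshold, and its predictive R^2 is recorded in the held-out
persons; the threshold with the highest mean R^2 wins (ties go to the
smaller, more parsimonious threshold).

R^2 for repeated measures is defined as the squared Pearson correlation
between the score and the person-mean log units, both residualised on mean
age and ancestry PCs.  A simple, model-free definition that matches the
"predict repeated measures" intent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from longprs.assoc import scan_repeated
from longprs.simcohort import CovariateTable, GenotypeMatrix, LongPhenotype

__all__ = ["ScoreDefinition", "CVResult", "build_score", "evaluate_score",
           "cross_validate", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.4, 0.5)


@dataclass
class ScoreDefinition:
    """A frozen score: threshold, selected SNPs, training weights."""

    threshold: float
    entries: pd.DataFrame  # snp_id, effect_allele, weight, train_p
    n_train_persons: int
    model_kind: str = "repeated"

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def to_plink_frame(self) -> pd.DataFrame:
        """snp_id / effect_allele / weight layout (PLINK --score compatible)."""
        return self.entries[["snp_id", "effect_allele", "weight"]].copy()

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_snps": self.n_snps,
            "n_train_persons": self.n_train_persons,
            "model_kind": self.model_kind,
            "entries": self.entries.to_dict(orient="records"),
        }


@dataclass
class CVResult:
    """Cross-validation grid and the selected score."""

    grid: pd.DataFrame  # index: threshold, columns: repeat_0..repeat_{r-1}
    mean_r2: pd.Series
    best_threshold: float
    repeats: int
    train_fraction: float
    seed: int
    final_score: ScoreDefinition

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(t) for t in self.grid.index],
            "grid": self.grid.to_numpy().tolist(),
            "mean_r2": self.mean_r2.to_numpy().tolist(),
            "best_threshold": float(self.best_threshold),
            "repeats": self.repeats,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "final_score": self.final_score.to_dict(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def build_score(geno: GenotypeMatrix, training_results: pd.DataFrame,
                threshold: float, n_train_persons: int = 0):
    """Score persons with training weights at a p-value threshold.

    ``training_results`` must carry snp_id, beta and p columns (the output of
    :func:`longprs.assoc.scan_repeated`).  Returns ``(scores, definition)``
    where ``scores`` is a person-indexed Series.  An empty selection yields
    all-zero scores and a warning.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    res = training_results.set_index("snp_id")
    panel_ids = list(geno.panel.snp_ids)
    missing = set(panel_ids) - set(res.index)
    if missing:
        raise ValueError(f"training results missing {len(missing)} panel SNPs")
    res = res.loc[panel_ids]
    sel = res["p"].to_numpy() <= threshold
    alleles = geno.panel.table.set_index("snp_id")["effect_allele"].loc[panel_ids]
    entries = pd.DataFrame({
        "snp_id": np.asarray(panel_ids)[sel],
        "effect_allele": alleles.to_numpy()[sel],
        "weight": res["beta"].to_numpy()[sel],
        "train_p": res["p"].to_numpy()[sel],
    })
    definition = ScoreDefinition(threshold=float(threshold), entries=entries,
                                 n_train_persons=n_train_persons)
    if sel.sum() == 0:
        warnings.warn(f"no SNPs pass threshold {threshold}; score is all zero")
        scores = pd.Series(0.0, index=geno.sample_ids, name="score")
    else:
        vals = geno.dosages[:, sel] @ entries["weight"].to_numpy()
        scores = pd.Series(vals, index=geno.sample_ids, name="score")
    return scores, definition


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def evaluate_score(test_pheno: LongPhenotype, scores: pd.Series,
                   covars: CovariateTable | None = None) -> float:
    """Predictive R^2 of a score in a held-out sample.

    Squared Pearson correlation between the score and person-mean log units,
    both residualised on person mean age and ancestry PCs.  Returns 0.0
    (with a warning) for a zero-variance score.
    """
    pm = test_pheno.person_means()
    pm = pm[pm["person_id"].isin(scores.index)]
    if len(pm) < 3:
        raise ValueError("fewer than 3 test persons with scores")
    s = scores.reindex(pm["person_id"]).to_numpy(dtype=float)
    y = pm["mean_log_units"].to_numpy(dtype=float)
    X = [np.ones(len(pm)), pm["mean_age"].to_numpy(dtype=float)]
    if covars is not None:
        pcs = covars.pcs().reindex(pm["person_id"])
        X.extend(pcs[c].to_numpy(dtype=float) for c in pcs.columns)
    X = np.column_stack(X)
    if np.var(s) == 0:
        warnings.warn("zero-variance score; R^2 reported as 0")
        return 0.0
    sr = _residualize(s, X)
    yr = _residualize(y, X)
    denom = np.sqrt((sr @ sr) * (yr @ yr))
    if denom == 0:
        return 0.0
    r = float((sr @ yr) / denom)
    return r * r


def _split_persons(persons: np.ndarray, cohorts: pd.Series | None,
                   train_fraction: float, rng: np.random.Generator):
    """Person-level train/test split, stratified by cohort when present."""
    persons = np.asarray(persons)
    if cohorts is not None and cohorts.nunique() > 1:
        train_parts = []
        for _, ids in cohorts.groupby(cohorts):
            ids = np.asarray(ids.index)
            perm = rng.permutation(ids)
            n_train = int(round(train_fraction * len(ids)))
            train_parts.append(perm[:n_train])
        train = np.concatenate(train_parts)
    else:
        perm = rng.permutation(persons)
        n_train = int(round(train_fraction * len(persons)))
        train = perm[:n_train]
    test = np.setdiff1d(persons, train)
    return np.sort(train), np.sort(test)


def cross_validate(pheno: LongPhenotype, geno: GenotypeMatrix,
                   covars: CovariateTable | None = None,
                   thresholds=DEFAULT_THRESHOLDS, train_fraction: float = 0.8,
                   repeats: int = 5, seed: int = 0) -> CVResult:
    """Select the p-value threshold by repeated person-level CV.

    Per repeat, all persons are split train/test (all of a person's occasions
    stay on one side; stratified by cohort when both cohorts are present);
    the per-SNP repeated-measures scan is refit on the training persons and a
    score per threshold evaluated on the test persons.  The final score is
    refit on all persons at the best threshold.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    thresholds = tuple(sorted(float(t) for t in thresholds))
    persons = np.intersect1d(pheno.persons, geno.sample_ids)
    if len(persons) < 10:
        raise ValueError("too few persons for a train/test split")
    cohort_map = (pheno.data.drop_duplicates("person_id")
                  .set_index("person_id")["cohort"].reindex(persons))
    rng = np.random.default_rng(seed)

    grid = np.zeros((len(thresholds), repeats))
    for rep in range(repeats):
        train, test = _split_persons(persons, cohort_map, train_fraction, rng)
        train_res = scan_repeated(pheno.subset_persons(train),
                                  geno.subset_persons(train), covars)
        test_geno = geno.subset_persons(test)
        test_pheno = pheno.subset_persons(test)
        for i, t in enumerate(thresholds):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores, _ = build_score(test_geno, train_res, t,
                                        n_train_persons=len(train))
                grid[i, rep] = evaluate_score(test_pheno, scores, covars)

    grid_df = pd.DataFrame(grid, index=pd.Index(thresholds, name="threshold"),
                           columns=[f"repeat_{r}" for r in range(repeats)])
    mean_r2 = grid_df.mean(axis=1)
    best = float(mean_r2.index[int(np.argmax(mean_r2.to_numpy()))])

    full_res = scan_repeated(pheno.subset_persons(persons),
                             geno.subset_persons(persons), covars)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, final_def = build_score(geno.subset_persons(persons), full_res, best,
                                   n_train_persons=len(persons))
    return CVResult(grid=grid_df, mean_r2=mean_r2, best_threshold=best,
                    repeats=repeats, train_fraction=train_fraction, seed=seed,
                    final_score=final_def)
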