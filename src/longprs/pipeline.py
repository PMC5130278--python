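"""End-to-end orchestration: simulate -> filter -> associate -> score ->
variance-explained -> MR design report.

Each cohort runs through every stage in order; all artifacts land in the
configured output directory, stamped with the configuration hash and seed.
No timestamps are written, so a rerun with the same configuration and seed
produces a byte-identical directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from longprs import io as lio
from longprs.assoc import apply_filters, pleiotropy_screen, scan_repeated
from longprs.avengeme import ObservedScoreResult, estimate_vg
from longprs.config import RunConfig
from longprs.mrpower import required_n_binary
from longprs.prs import build_score, cross_validate
from longprs.simcohort import (default_panel, simulate_covariates,
                               simulate_effects, simulate_genotypes,
                               simulate_phenotypes)

__all__ = ["PipelineError", "RunReport", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunReport:
    """Summary of a pipeline run: per-cohort key results and output paths."""

    outdir: str
    config_hash: str
    seed: int
    cohorts: dict = field(default_factory=dict)
    mr_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {"outdir": self.outdir, "config_hash": self.config_hash,
             "seed": self.seed, "cohorts": self.cohorts}
        if self.mr_table is not None:
            d["mr_design"] = self.mr_table.to_dict(orient="records")
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - stage-named abort
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig, log=print) -> RunReport:
    """Run every stage for every cohort; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report = RunReport(outdir=str(outdir), config_hash=chash, seed=config.seed)

    for ci, cc in enumerate(config.cohorts):
        name = cc.name
        cdir = outdir / name
        cdir.mkdir(exist_ok=True)
        seed0 = config.seed + 1000 * (ci + 1)
        log(f"[{name}] simulating cohort (n={cc.design.n_individuals}, "
            f"m={config.panel_m}, vg={cc.architecture.vg})")

        panel = _stage("panel")(default_panel)(config.panel_m, seed=seed0)
        geno = _stage("genotypes")(simulate_genotypes)(panel, cc.design.n_individuals,
                                                       seed=seed0 + 1)
        effects = _stage("effects")(simulate_effects)(cc.architecture, panel)
        pheno = _stage("phenotypes")(simulate_phenotypes)(geno, effects, cc.design,
                                                          cc.variance, seed=seed0 + 2)
        covars = _stage("covariates")(simulate_covariates)(
            geno.n, n_pcs=cc.n_pcs, n_confounders=cc.n_confounders,
            seed=seed0 + 3, sample_ids=geno.sample_ids)

        lio.write_panel_tsv(panel, cdir / "panel.tsv", sidecar=True)
        lio.write_vcf(geno, cdir / "genotypes.vcf")
        lio.write_phenotypes_csv(pheno, cdir / "phenotypes.csv", sidecar=True)
        lio.write_covariates_csv(covars, cdir / "covariates.csv", sidecar=True)

        filtered, audit = _stage("filters")(apply_filters)(pheno, config.filters)
        log(f"[{name}] filters: {audit.n_records_in} -> {audit.n_records_out} records, "
            f"{audit.never_drinkers_removed} never-drinkers removed")
        (cdir / "filter_audit.json").write_text(
            json.dumps(audit.to_dict(), indent=2) + "\n")

        assoc_res = _stage("association")(scan_repeated)(filtered, geno, covars)
        lio.write_association_table(assoc_res, cdir / "association.tsv", sidecar=True)
        lio.write_association_table(assoc_res, cdir / "association_report.tsv",
                                    report=True)

        cv = _stage("cross_validation")(cross_validate)(
            filtered, geno, covars, thresholds=config.thresholds,
            train_fraction=config.train_fraction, repeats=config.repeats,
            seed=seed0 + 4)
        (cdir / "cv_result.json").write_text(cv.to_json(indent=2) + "\n")
        cv.final_score.to_plink_frame().to_csv(cdir / "score_definition.tsv",
                                               sep="\t", index=False)
        scores, _ = build_score(geno, scan_repeated(filtered, geno, covars),
                                cv.best_threshold)
        scores.rename_axis("person_id").to_csv(cdir / "scores.csv",
                                               float_format="%.6f")
        log(f"[{name}] best threshold {cv.best_threshold}: "
            f"{cv.final_score.n_snps} SNPs, mean test R^2 = "
            f"{cv.mean_r2.loc[cv.best_threshold]:.4f}")

        n_persons = filtered.n_persons
        n1 = int(round(config.train_fraction * n_persons))
        n2 = n_persons - n1
        obs = ObservedScoreResult(
            p_threshold=cv.best_threshold, n1=n1, n2=n2, m=config.panel_m,
            r2=float(cv.mean_r2.loc[cv.best_threshold]))
        est = _stage("avengeme")(estimate_vg)([obs], pi0=config.avengeme_pi0)
        (cdir / "avengeme_estimate.json").write_text(json.dumps({
            "vg_hat": est.vg_hat, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pi0_mode": est.pi0_mode, "pi0_hat": est.pi0_hat,
            "loglik": est.loglik, "converged": est.converged,
            "observed_r2": obs.r2, "p_threshold": obs.p_threshold,
            "n1": n1, "n2": n2, "config_hash": chash, "seed": config.seed,
        }, indent=2) + "\n")
        log(f"[{name}] variance explained: {100 * est.vg_hat:.2f}% "
            f"(95% CI {100 * est.ci_low:.2f}% to {100 * est.ci_high:.2f}%)")

        screen = _stage("pleiotropy_screen")(pleiotropy_screen)(
            scores.to_frame("PGRS"), covars)
        screen.to_csv(cdir / "pleiotropy_screen.csv", index=False)

        report.cohorts[name] = {
            "n_persons_analysed": int(n_persons),
            "filter_audit": audit.to_dict(),
            "best_threshold": float(cv.best_threshold),
            "n_snps_in_score": int(cv.final_score.n_snps),
            "mean_test_r2": float(cv.mean_r2.loc[cv.best_threshold]),
            "vg_hat": est.vg_hat,
            "vg_ci": [est.ci_low, est.ci_high],
            "score_pleiotropy_hits": int(screen["significant"].sum()),
        }

    if config.mr_queries:
        rows = []
        for q in config.mr_queries:
            n_raw, n_rep = required_n_binary(q)
            rows.append({"odds_ratio": q.odds_ratio, "r2": q.r2,
                         "alpha": q.alpha, "power": q.power,
                         "case_fraction": q.case_fraction,
                         "n_raw": n_raw, "n_reported": n_rep})
        report.mr_table = pd.DataFrame(rows)
        report.mr_table.to_csv(outdir / "mr_design.tsv", sep="\t", index=False)

    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=float) + "\n")
    return report
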