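"""File formats: VCF v4.2 dosage genotypes, TSV/CSV tables, sidecar schemas.

Genotypes travel as VCF v4.2 with a DS (dosage of the effect/ALT allele)
FORMAT field, plus GT for hard calls, or as a wide TSV (person_id x snp_id)
alongside a panel TSV carrying the marker metadata.  Phenotypes and
covariates are long-format/wide CSV.  Every table writer can emit a sidecar
``<file>.schema.json`` declaring the column layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from longprs.simcohort import CovariateTable, GenotypeMatrix, LongPhenotype, SnpPanel

__all__ = [
    "write_vcf", "read_genotypes", "write_genotypes_tsv", "read_genotypes_tsv",
    "write_panel_tsv", "read_panel_tsv", "write_phenotypes_csv",
    "read_phenotypes_csv", "write_covariates_csv", "read_covariates_csv",
    "write_association_table", "write_schema_sidecar",
]


def write_schema_sidecar(path, columns, description: str = "") -> None:
    """Write ``<path>.schema.json`` declaring the table's columns."""
    sidecar = Path(str(path) + ".schema.json")
    sidecar.write_text(json.dumps(
        {"file": Path(path).name, "columns": list(columns),
         "description": description}, indent=2) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele in [0,2]">
##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Marker dosage is imputed">
"""


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write genotypes as VCF v4.2; ALT is the effect (minor) allele.

    Hard-called markers get GT and an integer DS; imputed markers get
    GT = ./. and a fractional DS.
    """
    panel = geno.panel.table
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.sample_ids)))
    for j in range(geno.m):
        row = panel.iloc[j]
        imputed = bool(row["imputed"])
        info = "IMPUTED" if imputed else "."
        fields = [str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                  str(row["other_allele"]), str(row["effect_allele"]),
                  ".", "PASS", info, "GT:DS"]
        dos = geno.dosages[:, j]
        if imputed:
            sample_fields = [f"./.:{d:.6f}" for d in dos]
        else:
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}
            sample_fields = [f"{gt[int(round(d))]}:{d:.6f}" for d in dos]
        lines.append("\t".join(fields + sample_fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes(path, fmt: str | None = None,
                   panel: SnpPanel | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or wide TSV (detected by extension).

    For VCF, the DS FORMAT field is preferred; GT is used as a fallback
    (allele count of ALT).  Multi-allelic records are rejected.  For TSV a
    ``panel`` may be supplied; otherwise marker metadata is reconstructed
    from the data (MAF from dosage means, alleles unknown).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path, panel=panel)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF header")
    cols, meta = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: {variant.CHROM}:{variant.POS} "
                f"{variant.ID} ALT={','.join(variant.ALT)}")
        ds = None
        try:
            arr = variant.format("DS")
        except Exception:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).reshape(-1)
        else:
            gts = variant.genotypes
            if not gts:
                raise ValueError(
                    f"record {variant.ID} at {variant.CHROM}:{variant.POS} "
                    "has neither DS nor GT")
            alleles = np.asarray([g[:2] for g in gts])
            ds = np.where((alleles < 0).any(axis=1), np.nan,
                          alleles.clip(min=0).sum(axis=1)).astype(float)
        cols.append(ds)
        af = np.nanmean(ds) / 2
        meta.append({
            "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
            "chrom": str(variant.CHROM), "pos": int(variant.POS),
            "effect_allele": variant.ALT[0], "other_allele": variant.REF,
            "maf": float(min(af, 1 - af)),
            "imputed": bool(variant.INFO.get("IMPUTED") is not None
                            or np.any(np.mod(ds[~np.isnan(ds)], 1) != 0)),
            "source": "unknown",
        })
    if not cols:
        raise ValueError("VCF contains no records")
    dosages = np.column_stack(cols)
    return GenotypeMatrix(dosages, samples, SnpPanel(pd.DataFrame(meta)))


# ---------------------------------------------------------------------------
# TSV / CSV tables
# ---------------------------------------------------------------------------

def write_genotypes_tsv(geno: GenotypeMatrix, path, sidecar: bool = False) -> None:
    df = geno.to_frame()
    df.to_csv(path, sep="\t", float_format="%.6f")
    if sidecar:
        write_schema_sidecar(path, ["person_id", *df.columns],
                             "wide dosage matrix, one column per SNP")


def read_genotypes_tsv(path, panel: SnpPanel | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="person_id")
    if panel is None:
        maf = np.minimum(df.mean() / 2, 1 - df.mean() / 2)
        frac = np.mod(df.to_numpy(), 1)
        imputed = (frac != 0).any(axis=0)
        panel = SnpPanel(pd.DataFrame({
            "snp_id": df.columns, "chrom": "NA", "pos": np.arange(1, df.shape[1] + 1),
            "effect_allele": "N", "other_allele": "N",
            "maf": maf.to_numpy(), "imputed": imputed, "source": "unknown",
        }))
    else:
        if list(df.columns) != list(panel.snp_ids):
            raise ValueError("TSV columns do not match panel snp_ids")
    return GenotypeMatrix(df.to_numpy(dtype=float), df.index.to_numpy(), panel)


def write_panel_tsv(panel: SnpPanel, path, sidecar: bool = False) -> None:
    panel.table.to_csv(path, sep="\t", index=False)
    if sidecar:
        write_schema_sidecar(path, panel.table.columns, "candidate SNP panel")


def read_panel_tsv(path) -> SnpPanel:
    return SnpPanel(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_phenotypes_csv(pheno: LongPhenotype, path, sidecar: bool = False) -> None:
    cols = ["person_id", "cohort", "occasion", "age", "units"]
    pheno.data[cols].to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        write_schema_sidecar(path, cols, "long-format repeated measures of weekly units")


def read_phenotypes_csv(path) -> LongPhenotype:
    df = pd.read_csv(path, dtype={"person_id": str, "occasion": str})
    return LongPhenotype(df)


def write_covariates_csv(covars: CovariateTable, path, sidecar: bool = False) -> None:
    covars.data.to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        write_schema_sidecar(path, covars.data.columns,
                             "person-level covariates: ancestry PCs and confounder panel")


def read_covariates_csv(path, n_pcs: int | None = None) -> CovariateTable:
    df = pd.read_csv(path, dtype={"person_id": str})
    pc_cols = tuple(c for c in df.columns if c.startswith("PC"))
    conf_cols = tuple(c for c in df.columns if c.startswith("conf"))
    binary = {c: set(df[c].dropna().unique()) <= {0, 1} for c in conf_cols}
    return CovariateTable(df, pc_cols, conf_cols, binary)


def write_association_table(results: pd.DataFrame, path, report: bool = False,
                            sidecar: bool = False) -> None:
    """Ranked association table (rank, snp, n, effect size, SE, t, p-value).

    ``report=True`` rounds p-values to two significant figures for human
    reading; the default keeps full precision for machine use.
    """
    from longprs.assoc import format_p

    df = results.sort_values("p").reset_index(drop=True)
    out = pd.DataFrame({
        "rank": np.arange(1, len(df) + 1),
        "snp": df["snp_id"] if "snp_id" in df else df["target_id"],
        "n": df["n"],
        "effect_size": df["beta"],
        "SE": df["se"],
        "t": df["stat"],
        "p_value": [format_p(p) for p in df["p"]] if report else df["p"],
    })
    out.to_csv(path, sep="\t", index=False)
    if sidecar:
        write_schema_sidecar(path, out.columns,
                             "per-SNP repeated-measures association, ranked by p")
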