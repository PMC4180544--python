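"""Readers and writers for the pipeline's plain-text formats.

Canonical interchange is TSV: expression (rows = genes, columns =
samples), genotype dosages (rows = SNPs), a per-sample phenotype table,
and gene/SNP association tables. Genotypes may alternatively arrive as
VCF 4.2 with a DS (dosage) FORMAT field, parsed with cyvcf2. Every
writer/reader pair round-trips losslessly.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeRecord,
    frame_to_records,
    records_to_frame,
)

PHENOTYPE_COLUMNS = [
    "sample_id", "ldlc_pre1", "ldlc_pre2", "ldlc_post1", "ldlc_post2",
    "age", "sex", "bmi", "smoker",
]


def _read_matrix_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dup = frame.index[frame.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicated {kind} id(s): {list(map(str, dup[:5]))}")
    dup_cols = frame.columns[frame.columns.duplicated()].unique()
    if len(dup_cols):
        raise ValueError(f"{path}: duplicated sample id(s): {list(map(str, dup_cols[:5]))}")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    return frame


def read_expression(path: str | Path, state: str = "raw") -> ExpressionMatrix:
    frame = _read_matrix_tsv(path, "gene")
    if frame.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix.from_frame(frame, state=state)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    # %.17g guarantees exact float64 round-trips through the text format
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return read_vcf_dosages(path)
    frame = _read_matrix_tsv(path, "SNP")
    return GenotypeMatrix.from_frame(frame)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = genotypes.to_frame()
    frame.index.name = "snp_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Genotype dosages from a VCF 4.2 FORMAT/DS field."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, rows = [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = variant.format("DS")
        if ds is None:
            raise ValueError(f"{path}: variant {vid} lacks a DS FORMAT field")
        rows.append(np.asarray(ds, dtype=float).reshape(-1))
        snps.append(str(vid))
    vcf.close()
    return GenotypeMatrix(snps=snps, samples=samples, dosages=np.asarray(rows))


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with per-sample DS dosages (placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.samples) + "\n")
        for i, snp in enumerate(genotypes.snps):
            ds = "\t".join(
                "." if np.isnan(v) else repr(float(v)) for v in genotypes.dosages[i]
            )
            fh.write(f"1\t{i + 1}\t{snp}\tA\tG\t.\tPASS\t.\tDS\t{ds}\n")


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                        float_precision="round_trip")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated sample id(s): {list(dup[:5])}")
    frame = frame.set_index("sample_id", drop=False)
    return frame_to_records(frame)


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    frame = records_to_frame(records)
    out = frame.drop(columns=[c for c in ("log_change", "adjusted_change")
                              if frame[c].isna().all()])
    out.to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "snp": str})
    required = ["gene", "snp", "p_value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "source" not in frame.columns:
        frame["source"] = "unknown"
    bad = frame[(frame["p_value"] <= 0) | (frame["p_value"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: p_value out of (0, 1] at row(s) {list(bad.index[:5])}")
    return frame


def read_gwas_snps(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "snp" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'snp'")
    if "annotation" not in frame.columns:
        frame["annotation"] = ""
    return frame


__all__ = [
    "read_expression", "write_expression",
    "read_genotypes", "write_genotypes",
    "read_vcf_dosages", "write_vcf",
    "read_phenotypes", "write_phenotypes",
    "read_eqtl_table", "read_gwas_snps",
    "PHENOTYPE_COLUMNS",
]
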