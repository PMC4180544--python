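"""Core data containers shared across the pipeline.

The pipeline passes around three kinds of per-cohort data: per-sample
phenotype records (LDL-cholesterol visits plus clinical covariates),
a gene x sample expression matrix, and a SNP x sample genotype dosage
matrix. These are deliberately thin wrappers over numpy/pandas objects
with validated invariants, so every stage can state its contract in
terms of them.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EXPRESSION_STATES = ("raw", "array_normalized", "fully_normalized")


@dataclass
class PhenotypeRecord:
    """One study participant.

    LDL-cholesterol (mg/dL) is measured at two pre-treatment and two
    post-treatment visits; duplicate visits are averaged before the log
    response is formed, to damp visit-to-visit technical variation.
    """

    sample_id: str
    ldlc_pre: tuple[float, float]
    ldlc_post: tuple[float, float]
    age: float
    sex: str  # "F" or "M"
    bmi: float
    smoker: bool
    log_change: float | None = None
    adjusted_change: float | None = None

    def validate(self) -> None:
        vals = (*self.ldlc_pre, *self.ldlc_post)
        if len(self.ldlc_pre) != 2 or len(self.ldlc_post) != 2:
            raise ValueError(f"{self.sample_id}: need two pre and two post LDLC visits")
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError(f"{self.sample_id}: LDLC visit values must be positive")


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued expression matrix.

    ``state`` tracks how far normalization has progressed; operations
    that require a particular state (e.g. the non-negativization ahead
    of NMF) check it explicitly.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in EXPRESSION_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, state: str = "raw") -> "ExpressionMatrix":
        return cls(
            genes=[str(g) for g in frame.index],
            samples=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            state=state,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=list(sample_ids),
            values=self.values[:, cols].copy(),
            state=self.state,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            genes=list(gene_ids),
            samples=list(self.samples),
            values=self.values[rows, :].copy(),
            state=self.state,
        )


@dataclass
class GenotypeMatrix:
    """SNP x sample additive dosage matrix, values in [0, 2].

    Dosages may be fractional (expected alternate-allele counts from
    imputation). Missing calls are NaN and are mean-imputed downstream,
    inside the cross-validation loop, from training samples only.
    """

    snps: list[str]
    samples: list[str]
    dosages: np.ndarray  # shape (n_snps, n_samples)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snps), len(self.samples)):
            raise ValueError("dosage shape inconsistent with snp/sample lists")
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP identifiers")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] (or NaN for missing)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.snps, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeMatrix":
        return cls(
            snps=[str(s) for s in frame.index],
            samples=[str(s) for s in frame.columns],
            dosages=frame.to_numpy(dtype=float),
        )


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Tabulate phenotype records, one row per sample."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "ldlc_pre1": r.ldlc_pre[0],
                "ldlc_pre2": r.ldlc_pre[1],
                "ldlc_post1": r.ldlc_post[0],
                "ldlc_post2": r.ldlc_post[1],
                "age": r.age,
                "sex": r.sex,
                "bmi": r.bmi,
                "smoker": r.smoker,
                "log_change": r.log_change,
                "adjusted_change": r.adjusted_change,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def frame_to_records(frame: pd.DataFrame) -> list[PhenotypeRecord]:
    records = []
    for _, row in frame.iterrows():
        records.append(
            PhenotypeRecord(
                sample_id=str(row["sample_id"]),
                ldlc_pre=(float(row["ldlc_pre1"]), float(row["ldlc_pre2"])),
                ldlc_post=(float(row["ldlc_post1"]), float(row["ldlc_post2"])),
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                smoker=bool(row["smoker"]),
                log_change=float(row["log_change"])
                if "log_change" in row and pd.notna(row["log_change"])
                else None,
                adjusted_change=float(row["adjusted_change"])
                if "adjusted_change" in row and pd.notna(row["adjusted_change"])
                else None,
            )
        )
    return records


__all__ = [
    "PhenotypeRecord",
    "ExpressionMatrix",
    "GenotypeMatrix",
    "EXPRESSION_STATES",
    "records_to_frame",
    "frame_to_records",
    "replace",
    "field",
]
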