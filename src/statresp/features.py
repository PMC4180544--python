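"""Feature-matrix construction for the prediction model variants.

Models combine three feature kinds: signature-gene expression levels,
best-eQTL genotype dosages for the covered signature genes, and GWAS
SNP dosages. The canned variants cover the standard comparisons:
expression only (SG), the alternative no-fudge signature (SG_NO),
eQTL genotypes only, expression plus eQTLs, the substitution model
(eQTL genotypes replacing expression for covered genes), GWAS SNPs
only, and the all-features model.

SNPs are encoded additively (dosage 0-2, fractional allowed).
Standardization is deferred to the prediction stage so that scaling
statistics are always fit on training partitions only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix

KINDS = ("expression", "eqtl_genotype", "gwas_snp")


@dataclass
class FeatureModelSpec:
    """A named model variant: ordered (feature id, kind) components."""

    name: str
    components: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [f"{kind}:{fid}" for fid, kind in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate features")
        bad = [k for _, k in self.components if k not in KINDS]
        if bad:
            raise ValueError(f"{self.name}: unknown feature kinds {set(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return [f"{kind}:{fid}" for fid, kind in self.components]


def select_best_eqtls(
    eqtls: pd.DataFrame,
    signature: list[str],
    p_threshold: float = 5e-8,
) -> dict[str, str]:
    """Best (smallest-p) eQTL SNP per signature gene below the threshold.

    Ties on p are broken by the lexicographically smallest SNP id.
    Returns a possibly partial gene -> snp map; warns when no gene is
    covered at all.
    """
    if eqtls.empty:
        raise ValueError("eQTL table is empty")
    required = {"gene", "snp", "p_value"}
    if not required <= set(eqtls.columns):
        raise ValueError(f"eQTL table needs columns {sorted(required)}")
    sub = eqtls[eqtls["gene"].isin(signature) & (eqtls["p_value"] < p_threshold)]
    sub = sub.sort_values(["gene", "p_value", "snp"], kind="stable")
    mapping = dict(zip(sub.drop_duplicates("gene")["gene"], sub.drop_duplicates("gene")["snp"]))
    if not mapping:
        warnings.warn(f"no signature gene has an eQTL at p < {p_threshold:g}")
    return mapping


def canned_specs(
    signature: list[str],
    eqtl_map: dict[str, str],
    gwas_snps: list[str],
    sg_no: list[str] | None = None,
) -> dict[str, FeatureModelSpec]:
    """The named model variants compared by the pipeline."""
    expr = [(g, "expression") for g in signature]
    eqtl = [(s, "eqtl_genotype") for s in eqtl_map.values()]
    gwas = [(s, "gwas_snp") for s in gwas_snps]
    substitution = [
        (eqtl_map[g], "eqtl_genotype") if g in eqtl_map else (g, "expression")
        for g in signature
    ]
    specs = {
        "SG": FeatureModelSpec("SG", expr),
        "eqtl_only": FeatureModelSpec("eqtl_only", eqtl),
        "SG_plus_eqtl": FeatureModelSpec("SG_plus_eqtl", expr + eqtl),
        "substitution": FeatureModelSpec("substitution", substitution),
        "gwas_only": FeatureModelSpec("gwas_only", gwas),
        "SG_plus_gwas": FeatureModelSpec("SG_plus_gwas", expr + gwas),
        "all": FeatureModelSpec("all", expr + eqtl + gwas),
    }
    if sg_no is not None:
        specs["SG_NO"] = FeatureModelSpec("SG_NO", [(g, "expression") for g in sg_no])
    return specs


def assemble_features(
    spec: FeatureModelSpec,
    expression: ExpressionMatrix | None,
    genotypes: GenotypeMatrix | None,
    samples: list[str],
    impute: bool = False,
) -> pd.DataFrame:
    """Sample x feature matrix with columns in spec order.

    With ``impute=True`` missing dosages are replaced by the feature
    mean over the supplied samples (clipped back into [0, 2]); inside
    cross-validation leave imputation to the prediction stage, which
    uses training-partition means only.
    """
    expr_frame = expression.to_frame() if expression is not None else None
    geno_frame = genotypes.to_frame() if genotypes is not None else None
    cols = {}
    for fid, kind in spec.components:
        if kind == "expression":
            if expr_frame is None or fid not in expr_frame.index:
                raise KeyError(f"expression feature {fid!r} not available")
            col = expr_frame.loc[fid, samples].to_numpy(dtype=float)
        else:
            if geno_frame is None or fid not in geno_frame.index:
                raise KeyError(f"genotype feature {fid!r} not available")
            col = geno_frame.loc[fid, samples].to_numpy(dtype=float)
            if impute and np.isnan(col).any():
                mean = np.nanmean(col)
                col = np.where(np.isnan(col), mean, col)
                col = np.clip(col, 0.0, 2.0)
        cols[f"{kind}:{fid}"] = col
    return pd.DataFrame(cols, index=samples)


__all__ = [
    "FeatureModelSpec",
    "select_best_eqtls",
    "canned_specs",
    "assemble_features",
    "KINDS",
]
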