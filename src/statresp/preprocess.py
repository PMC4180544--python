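"""Response phenotype derivation and expression normalization.

The response trait is the relative LDL-cholesterol change,
log(mean post-treatment LDLC) - log(mean pre-treatment LDLC), with
duplicate visits averaged first to damp technical variation. Candidate
clinical covariates (sex, age, BMI) are screened by simple linear
regression and the response is residualized on those retained.

Expression normalization follows the array pipeline: each array
(sample) is quantile-transformed to the average empirical distribution
across arrays; each gene is then rank-based inverse-normal transformed,
residualized on known batch covariates, and inverse-normal transformed
again, leaving every gene approximately standard normal.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, PhenotypeRecord

DEFAULT_COVARIATES = ("age", "sex", "bmi")


def compute_log_change(record: PhenotypeRecord) -> float:
    """Natural-log relative LDLC change: log(mean post) - log(mean pre)."""
    record.validate()
    pre = (record.ldlc_pre[0] + record.ldlc_pre[1]) / 2.0
    post = (record.ldlc_post[0] + record.ldlc_post[1]) / 2.0
    return math.log(post) - math.log(pre)


def add_log_change(records: Sequence[PhenotypeRecord]) -> list[PhenotypeRecord]:
    return [replace(r, log_change=compute_log_change(r)) for r in records]


def exclude_smokers(records: Sequence[PhenotypeRecord]) -> list[PhenotypeRecord]:
    """Drop smokers, mirroring the cohort's non-smoker restriction."""
    return [r for r in records if not r.smoker]


def _covariate_column(records: Sequence[PhenotypeRecord], name: str) -> np.ndarray:
    if name == "sex":
        return np.array([1.0 if r.sex == "M" else 0.0 for r in records])
    if name == "smoker":
        return np.array([float(r.smoker) for r in records])
    return np.array([float(getattr(r, name)) for r in records])


def screen_and_adjust_covariates(
    records: Sequence[PhenotypeRecord],
    candidates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> tuple[list[str], list[PhenotypeRecord]]:
    """Screen covariates one at a time; residualize the response on the keepers.

    Each candidate is tested by simple linear regression of the log
    LDLC change on it; candidates with slope p < ``alpha`` are retained
    and the adjusted response is the residual of a joint regression on
    them (with intercept). With nothing retained the adjusted response
    is the centered log change.
    """
    if len(records) < max(3, len(candidates)):
        raise ValueError("need at least 3 samples per covariate for screening")
    records = [
        r if r.log_change is not None else replace(r, log_change=compute_log_change(r))
        for r in records
    ]
    y = np.array([r.log_change for r in records])

    kept: list[str] = []
    for name in candidates:
        x = _covariate_column(records, name)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; excluded from screening")
            continue
        res = stats.linregress(x, y)
        if res.pvalue < alpha:
            kept.append(name)

    if kept:
        design = np.column_stack(
            [np.ones(len(records))] + [_covariate_column(records, n) for n in kept]
        )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        adjusted = y - design @ beta
    else:
        adjusted = y - y.mean()

    out = [replace(r, adjusted_change=float(a)) for r, a in zip(records, adjusted)]
    return kept, out


# ---------------------------------------------------------------------------
# expression normalization


def _quantile_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Map each column onto the mean order-statistic profile (ties -> average)."""
    n = values.shape[0]
    sorted_vals = np.sort(values, axis=0)
    reference = sorted_vals.mean(axis=1)
    ranks = stats.rankdata(values, axis=0, method="average")
    return np.interp(ranks, np.arange(1, n + 1), reference)


def rank_inverse_normal(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps x to Phi^-1((r - c)/(n - 2c + 1)) with average ranks for ties;
    a constant vector maps to zeros.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        return np.zeros(n)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - c) / (n - 2.0 * c + 1.0))


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each row of ``values`` on the column space of ``design``."""
    q, _ = np.linalg.qr(design)
    return values - (values @ q) @ q.T


def _batch_design(batch_covariates: pd.DataFrame, samples: Sequence[str]) -> np.ndarray:
    table = batch_covariates.loc[list(samples)]
    cols = [np.ones(len(table))]
    for name in table.columns:
        col = table[name]
        if col.dtype.kind in "ifu":
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
    return np.column_stack(cols)


def normalize_expression(
    matrix: ExpressionMatrix,
    batch_covariates: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Full expression normalization; output per gene ~ N(0, 1).

    Steps: (1) column-wise quantile normalization to the mean empirical
    distribution; (2) per-gene rank inverse-normal transform; (3)
    per-gene residualization on batch covariates; (4) per-gene inverse-
    normal transform again. The final step is a monotone function of
    the step-3 ranks, so downstream rank-based steps are unaffected by
    the exact residual scale.
    """
    if matrix.state != "raw":
        raise ValueError(f"expected raw expression, got state {matrix.state!r}")
    values = np.asarray(matrix.values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values")

    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} all-constant gene(s) set to zero")

    step1 = _quantile_normalize_columns(values)
    step2 = np.apply_along_axis(rank_inverse_normal, 1, step1)
    if batch_covariates is not None:
        design = _batch_design(batch_covariates, matrix.samples)
        step3 = _residualize(step2, design)
    else:
        step3 = step2
    step4 = np.apply_along_axis(rank_inverse_normal, 1, step3)
    step4[constant] = 0.0
    return ExpressionMatrix(
        genes=list(matrix.genes),
        samples=list(matrix.samples),
        values=step4,
        state="fully_normalized",
    )


__all__ = [
    "compute_log_change",
    "add_log_change",
    "exclude_smokers",
    "screen_and_adjust_covariates",
    "normalize_expression",
    "rank_inverse_normal",
    "DEFAULT_COVARIATES",
]
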