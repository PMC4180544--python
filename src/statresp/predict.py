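"""RBF-SVM prediction models and repeated-holdout evaluation.

Classification discriminates extreme high vs low responders from the
feature matrix; regression predicts the continuous adjusted response.
Both use a Gaussian kernel k(x, y) = exp(-gamma ||x - y||^2) with the
bandwidth set by the median-pairwise-squared-distance heuristic on the
training data, soft-margin cost C = 1 and (for regression) an
epsilon-insensitive tube of 0.1 on the standardized response.

Evaluation repeats stratified random 90/10 train/test splits many
times (Monte-Carlo cross-validation). Classification is summarized by
the ROC AUC of the held-out decision scores; regression by the
explained variance, the squared Pearson correlation between held-out
predictions and observations (pooled across repeats by default).
All preprocessing (mean imputation of missing dosages, z-scoring) is
fit on the training partition only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC, SVR


@dataclass
class CvScheme:
    """Repeated random-holdout scheme: 1,000 x 90/10 by default."""

    n_repeats: int = 1000
    holdout_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


@dataclass
class EvalResult:
    model: str
    tail_fraction: float | None = None
    auc: float | None = None
    auc_se: float | None = None
    explained_variance: float | None = None  # percent
    explained_variance_se: float | None = None
    n_samples: int = 0
    per_repeat: np.ndarray = field(default_factory=lambda: np.array([]))


def median_heuristic_gamma(X: np.ndarray) -> float:
    """gamma = 1 / median pairwise squared distance of the training rows."""
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X, "sqeuclidean")
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    return float(1.0 / np.median(d))


class _TrainScaler:
    """Impute-by-train-mean then z-score with train statistics only."""

    def fit(self, X: np.ndarray) -> "_TrainScaler":
        self.means_ = np.nanmean(X, axis=0)
        filled = np.where(np.isnan(X), self.means_, X)
        self.center_ = filled.mean(axis=0)
        self.scale_ = filled.std(axis=0)
        self.keep_ = self.scale_ > 0
        if not self.keep_.all():
            warnings.warn(f"dropping {int((~self.keep_).sum())} constant feature(s)")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        filled = np.where(np.isnan(X), self.means_, X)
        Z = (filled - self.center_)[:, self.keep_] / self.scale_[self.keep_]
        return Z


def svm_train_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    mode: str = "classify",
    C: float = 1.0,
    epsilon: float = 0.1,
    kernel: str = "rbf",
    gamma: float | str = "median",
) -> np.ndarray:
    """Fit an RBF-SVM on standardized training data, score the test rows.

    Classification returns signed decision scores (margins);
    regression returns continuous predictions on the original response
    scale (the model is fit on the z-scored response so the epsilon
    tube is scale-free). The kernel is swappable for the comparison
    hook (linear/poly/sigmoid), untuned.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    scaler = _TrainScaler().fit(X_train)
    Ztr, Zte = scaler.transform(X_train), scaler.transform(X_test)
    if Ztr.shape[1] == 0:
        raise ValueError("no non-constant features left after standardization")
    g = median_heuristic_gamma(Ztr) if gamma == "median" else gamma
    kw = dict(kernel=kernel)
    if kernel == "rbf":
        kw["gamma"] = g
    if mode == "classify":
        classes = np.unique(y_train)
        if classes.size < 2:
            raise ValueError("single-class training set")
        model = SVC(C=C, **kw)
        model.fit(Ztr, y_train)
        return model.decision_function(Zte)
    if mode == "regress":
        sd = y_train.std()
        if sd == 0:
            return np.full(Zte.shape[0], y_train.mean())
        model = SVR(C=C, epsilon=epsilon, **kw)
        model.fit(Ztr, (y_train - y_train.mean()) / sd)
        return model.predict(Zte) * sd + y_train.mean()
    raise ValueError("mode must be 'classify' or 'regress'")


def _stratified_split(
    y: np.ndarray, holdout_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random test indices with at least one sample per class held out."""
    test_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_test = max(1, int(round(holdout_fraction * members.size)))
        test_idx.append(rng.permutation(members)[:n_test])
    test = np.concatenate(test_idx)
    mask = np.ones(y.size, dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test


def repeated_holdout_auc(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    scheme: CvScheme,
    model_name: str = "model",
    pooling: str = "per_repeat",
    **svm_kw,
) -> EvalResult:
    """Mean ROC AUC over repeated stratified 90/10 holdouts.

    AUC uses the rank (Mann-Whitney) formulation with tie correction on
    the held-out decision scores. ``pooling="pooled"`` instead computes
    one AUC over all held-out scores pooled across repeats.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("labels must be binary")
    rng = np.random.default_rng(scheme.seed)
    aucs, pooled_scores, pooled_labels = [], [], []
    done = 0
    attempts = 0
    while done < scheme.n_repeats:
        attempts += 1
        if attempts > 50 * scheme.n_repeats:
            raise RuntimeError("could not draw enough two-class holdout folds")
        train, test = _stratified_split(y, scheme.holdout_fraction, rng)
        if np.unique(y[test]).size < 2:
            continue  # resample single-class folds
        scores = svm_train_predict(X[train], y[train], X[test], mode="classify", **svm_kw)
        aucs.append(roc_auc_score(y[test], scores))
        pooled_scores.append(scores)
        pooled_labels.append(y[test])
        done += 1
    aucs = np.asarray(aucs)
    if pooling == "pooled":
        auc = float(roc_auc_score(np.concatenate(pooled_labels), np.concatenate(pooled_scores)))
    else:
        auc = float(aucs.mean())
    return EvalResult(
        model=model_name,
        auc=auc,
        auc_se=float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size > 1 else 0.0,
        n_samples=int(y.size),
        per_repeat=aucs,
    )


def tail_sweep(
    features: pd.DataFrame,
    responses: pd.Series,
    fractions: list[float] | None = None,
    scheme: CvScheme | None = None,
    model_name: str = "model",
    min_tail: int = 4,
    **svm_kw,
) -> list[EvalResult]:
    """AUC of the high/low classifier as the tail fraction grows.

    For fraction f, the top f/2 of responders are labeled high and the
    bottom f/2 low (f = 1 is a plain median split); the classifier is
    evaluated on that subset by repeated holdout. Fractions whose tails
    would hold fewer than ``min_tail`` samples are skipped with a warning.
    """
    if scheme is None:
        scheme = CvScheme()
    if fractions is None:
        fractions = [round(0.10 + 0.05 * i, 2) for i in range(19)]  # 0.10 .. 1.00
    responses = responses.loc[features.index]
    order = np.lexsort((responses.index.to_numpy(), responses.to_numpy()))
    ordered_ids = responses.index.to_numpy()[order]
    m = len(ordered_ids)
    results = []
    seeds = np.random.SeedSequence(scheme.seed).spawn(len(fractions))
    for f, ss in zip(fractions, seeds):
        n_half = int(round(f * m / 2)) if f < 1.0 else m // 2
        if n_half < min_tail:
            warnings.warn(f"fraction {f}: tails of {n_half} < {min_tail} samples; skipped")
            continue
        low_ids = ordered_ids[:n_half]
        high_ids = ordered_ids[-n_half:]
        ids = np.concatenate([low_ids, high_ids])
        labels = np.array([0] * n_half + [1] * n_half)
        sub_scheme = CvScheme(scheme.n_repeats, scheme.holdout_fraction,
                              int(ss.generate_state(1)[0] % 2**31))
        res = repeated_holdout_auc(
            features.loc[ids], labels, sub_scheme, model_name=model_name, **svm_kw
        )
        res.tail_fraction = f
        results.append(res)
    return results


def auc_decline_spearman(results: list[EvalResult]) -> float:
    """Spearman correlation of (fraction, AUC) from the AUC maximum on.

    A strongly negative value reproduces the qualitative decline of
    prediction power as less-extreme responders are included.
    """
    fr = np.array([r.tail_fraction for r in results])
    auc = np.array([r.auc for r in results])
    start = int(np.argmax(auc))
    if fr.size - start < 3:
        raise ValueError("need at least 3 fractions beyond the AUC maximum")
    rho, _ = spearmanr(fr[start:], auc[start:])
    return float(rho)


def explained_variance(
    features: pd.DataFrame | np.ndarray,
    responses: pd.Series | np.ndarray,
    scheme: CvScheme | None = None,
    model_name: str = "model",
    statistic: str = "pooled_r2",
    **svm_kw,
) -> EvalResult:
    """Cross-validated explained variance of the SVM regression, in percent.

    Per repeat, a random 90/10 split is drawn, the regression fit, and
    the held-out samples predicted. ``statistic`` controls the summary:

    - ``pooled_r2`` (default): squared Pearson correlation between all
      held-out predictions and observations pooled across repeats.
    - ``mean_r2``: mean of per-repeat squared correlations.
    - ``oos_r2``: pooled out-of-sample 1 - SSE/SST.

    The result is floored at zero and reported as a percentage.
    """
    if scheme is None:
        scheme = CvScheme()
    X = np.asarray(features, dtype=float)
    y = np.asarray(responses, dtype=float)
    if y.size < 30:
        raise ValueError("explained variance needs n >= 30")
    rng = np.random.default_rng(scheme.seed)
    n_test = max(2, int(round(scheme.holdout_fraction * y.size)))
    preds, obs, per_repeat = [], [], []
    done, attempts = 0, 0
    while done < scheme.n_repeats:
        attempts += 1
        if attempts > 50 * scheme.n_repeats:
            raise RuntimeError("could not draw enough non-degenerate holdout folds")
        perm = rng.permutation(y.size)
        test, train = perm[:n_test], perm[n_test:]
        if np.ptp(y[test]) == 0 or np.ptp(y[train]) == 0:
            continue  # resample folds with zero response variance
        p = svm_train_predict(X[train], y[train], X[test], mode="regress", **svm_kw)
        preds.append(p)
        obs.append(y[test])
        if np.ptp(p) > 0:
            r = np.corrcoef(p, y[test])[0, 1]
            per_repeat.append(r * r)
        else:
            per_repeat.append(0.0)
        done += 1
    preds = np.concatenate(preds)
    obs = np.concatenate(obs)
    per_repeat = np.asarray(per_repeat)
    if statistic == "pooled_r2":
        ev = np.corrcoef(preds, obs)[0, 1] ** 2 if np.ptp(preds) > 0 else 0.0
    elif statistic == "mean_r2":
        ev = per_repeat.mean()
    elif statistic == "oos_r2":
        ev = 1.0 - np.sum((obs - preds) ** 2) / np.sum((obs - obs.mean()) ** 2)
    else:
        raise ValueError("statistic must be pooled_r2, mean_r2 or oos_r2")
    ev = max(float(ev), 0.0)
    return EvalResult(
        model=model_name,
        explained_variance=100.0 * ev,
        explained_variance_se=float(100.0 * per_repeat.std(ddof=1) / np.sqrt(per_repeat.size))
        if per_repeat.size > 1
        else 0.0,
        n_samples=int(y.size),
        per_repeat=per_repeat,
    )


def model_comparison_report(
    results: list[EvalResult], baseline: str | None = None
) -> pd.DataFrame:
    """Side-by-side table of AUCs and explained variances with deltas."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.model,
                "tail_fraction": r.tail_fraction,
                "auc": r.auc,
                "auc_se": r.auc_se,
                "explained_variance_pct": r.explained_variance,
                "explained_variance_se": r.explained_variance_se,
                "n": r.n_samples,
            }
        )
    table = pd.DataFrame(rows)
    if baseline is not None:
        base = table[table["model"] == baseline]
        if base.empty:
            raise ValueError(f"baseline {baseline!r} not among results")
        for col in ("auc", "explained_variance_pct"):
            ref = base[col].iloc[0]
            table[f"delta_{col}"] = table[col] - ref if pd.notna(ref) else np.nan
    return table


__all__ = [
    "CvScheme",
    "EvalResult",
    "median_heuristic_gamma",
    "svm_train_predict",
    "repeated_holdout_auc",
    "tail_sweep",
    "auc_decline_spearman",
    "explained_variance",
    "model_comparison_report",
]
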