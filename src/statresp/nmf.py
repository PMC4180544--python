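"""NMF consensus clustering and extreme-responder subset selection.

A fully-normalized expression submatrix is made non-negative by mapping
each per-gene standard-normal value z to the normal CDF Phi(z) (one
minus its upper-tail P value), then factorized as A ~ WH with
multiplicative updates under the Frobenius objective. Sample cluster
assignments come from the argmax over the rows of H per column.

Cluster quality against known class labels is scored by purity
(fraction of samples in their cluster's majority class) and a
normalized entropy; rank stability is assessed by consensus matrices
averaged over repeated runs, their cophenetic correlation under
average-linkage clustering, and a dispersion coefficient.

The tail-selection procedure sweeps subset sizes N, clustering the N/2
highest plus N/2 lowest responders on the genes with the largest
between-group mean difference, and compares the achieved purity with a
random-subset baseline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix

_EPS_CLIP = 1e-12
_EPS_DIV = 1e-12


@dataclass
class NonNegativeData:
    """Matrix of 1 - P entries in (0, 1), ready for NMF."""

    matrix: np.ndarray  # (n_genes, m_samples)
    genes: list[str]
    samples: list[str]
    provenance: str = "Phi(z) per gene (1 minus upper-tail P under normality)"


@dataclass
class NmfFit:
    W: np.ndarray
    H: np.ndarray
    k: int
    reconstruction_error: float
    assignments: np.ndarray  # cluster index per sample, 0..k-1
    error_trace: np.ndarray
    converged: bool


@dataclass
class ClusterQuality:
    purity: float
    entropy: float
    n: int
    l: int
    counts: np.ndarray  # cluster x class contingency table


@dataclass
class ConsensusSummary:
    k: int
    consensus: np.ndarray  # (m, m)
    cophenetic_correlation: float
    dispersion: float


@dataclass
class TailSelection:
    chosen_N: int
    high_ids: list[str]
    low_ids: list[str]
    curve: pd.DataFrame  # N, purity_true, purity_random, entropy_true, entropy_random
    met_cutoff: bool


def nonnegativize(matrix: ExpressionMatrix) -> NonNegativeData:
    """Replace each normalized value z with Phi(z), clipped into (0, 1).

    Requires a fully-normalized matrix, whose per-gene values are
    already standard-normal scores; the transform is strictly monotone
    within each gene.
    """
    if matrix.state != "fully_normalized":
        raise ValueError("nonnegativize requires a fully_normalized matrix")
    A = stats.norm.cdf(matrix.values)
    A = np.clip(A, _EPS_CLIP, 1.0 - _EPS_CLIP)
    return NonNegativeData(matrix=A, genes=list(matrix.genes), samples=list(matrix.samples))


def _mu_nmf_run(
    A: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One multiplicative-update run from a random initialization."""
    n, m = A.shape
    scale = A.mean()
    W = rng.uniform(size=(n, k)) * scale
    H = rng.uniform(size=(k, m)) * scale
    trace = []
    err_prev = np.inf
    norm_A = float(np.linalg.norm(A))
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS_DIV)
        W *= (A @ H.T) / (W @ (H @ H.T) + _EPS_DIV)
        err = float(np.linalg.norm(A - W @ H))
        trace.append(err)
        if err_prev - err < tol * max(err_prev, _EPS_DIV) or err <= tol * norm_A:
            converged = True
            break
        err_prev = err
    return W, H, np.asarray(trace), converged


def nmf_factorize(
    A: NonNegativeData | np.ndarray,
    k: int,
    n_runs: int = 500,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmfFit:
    """Best-of-``n_runs`` multiplicative-update NMF at rank ``k``.

    Per-run seeds are spawned from the master seed, so results are
    reproducible and runs are independent. Returns the run with the
    smallest Frobenius reconstruction error; warns if that run did not
    converge within ``max_iter``.
    """
    mat = A.matrix if isinstance(A, NonNegativeData) else np.asarray(A, dtype=float)
    if k < 1:
        raise ValueError("rank k must be >= 1")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if np.any(mat < 0):
        raise ValueError("input matrix must be non-negative")
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    best = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        W, H, trace, converged = _mu_nmf_run(mat, k, rng, max_iter, tol)
        err = trace[-1]
        if best is None or err < best[3]:
            best = (W, H, trace, err, converged)
    W, H, trace, err, converged = best
    if not converged:
        warnings.warn(f"best NMF run did not converge within {max_iter} iterations")
    assignments = np.argmax(H, axis=0)
    return NmfFit(
        W=W,
        H=H,
        k=k,
        reconstruction_error=float(err),
        assignments=assignments,
        error_trace=trace,
        converged=converged,
    )


def purity_entropy(assignments: np.ndarray, labels: np.ndarray) -> ClusterQuality:
    """Cluster purity and normalized entropy against true class labels.

    purity = (1/n) * sum_i max_j n_i^j and
    entropy = -(1/(n log2 l)) * sum_i sum_j n_i^j log2(n_i^j / n_i),
    with n_i^j the count of class-j samples in cluster i. Perfect
    clustering gives purity 1, entropy 0. Empty clusters contribute
    nothing; a single true class leaves entropy undefined (error).
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape != labels.shape:
        raise ValueError("assignments and labels must cover the same samples")
    n = assignments.size
    clusters, cl_idx = np.unique(assignments, return_inverse=True)
    classes, la_idx = np.unique(labels, return_inverse=True)
    l = classes.size
    if l < 2:
        raise ValueError("entropy requires at least two true classes")
    counts = np.zeros((clusters.size, l))
    np.add.at(counts, (cl_idx, la_idx), 1.0)
    purity = counts.max(axis=1).sum() / n
    n_i = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log2(np.where(counts > 0, counts / n_i, 1.0))
    entropy = -terms.sum() / (n * np.log2(l))
    return ClusterQuality(purity=float(purity), entropy=float(entropy), n=n, l=l, counts=counts)


def _connectivity(assignments: np.ndarray) -> np.ndarray:
    return (assignments[:, None] == assignments[None, :]).astype(float)


def consensus_diagnostics(
    A: NonNegativeData | np.ndarray,
    ranks: list[int],
    n_runs: int = 500,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> list[ConsensusSummary]:
    """Consensus matrix, cophenetic correlation and dispersion per rank.

    The consensus matrix averages co-clustering indicators over
    ``n_runs`` independently initialized runs. Its complement (1 - C)
    is clustered by average linkage; the cophenetic correlation of that
    dendrogram against the (1 - C) distances measures how tree-like
    (i.e. stable) the clustering is. Dispersion is mean(4 (C - 1/2)^2),
    equal to 1 exactly when all runs agree.
    """
    mat = A.matrix if isinstance(A, NonNegativeData) else np.asarray(A, dtype=float)
    m = mat.shape[1]
    if n_runs < 2:
        raise ValueError("consensus diagnostics need n_runs >= 2")
    if any(k < 2 or k > m - 1 for k in ranks):
        raise ValueError("ranks must lie in {2, ..., m-1}")
    out = []
    master = np.random.SeedSequence(seed).spawn(len(ranks))
    for k, ss in zip(ranks, master):
        C = np.zeros((m, m))
        for run_ss in ss.spawn(n_runs):
            rng = np.random.default_rng(run_ss)
            _, H, _, _ = _mu_nmf_run(mat, k, rng, max_iter, tol)
            C += _connectivity(np.argmax(H, axis=0))
        C /= n_runs
        np.fill_diagonal(C, 1.0)
        dist = squareform(1.0 - C, checks=False)
        if np.ptp(dist) == 0:
            coph = 1.0  # degenerate: all pairs equidistant, trivially tree-like
        else:
            Z = _average_linkage(dist)
            coph, _ = cophenet(Z, dist)
        dispersion = float(np.mean(4.0 * (C - 0.5) ** 2))
        out.append(
            ConsensusSummary(
                k=k, consensus=C, cophenetic_correlation=float(coph), dispersion=dispersion
            )
        )
    return out


def _order_by_response(responses: pd.Series) -> list[str]:
    """Sample ids sorted ascending by response; ties broken by id (stable)."""
    s = responses.copy()
    s = s.iloc[np.argsort(s.index.to_numpy(), kind="stable")]
    return list(s.iloc[np.argsort(s.to_numpy(), kind="stable")].index)


def preselect_genes(
    matrix: ExpressionMatrix, group_a: list[str], group_b: list[str], n_genes: int
) -> list[str]:
    """Genes with the largest |mean(group_a) - mean(group_b)| difference."""
    frame = matrix.to_frame()
    diff = (frame[group_a].mean(axis=1) - frame[group_b].mean(axis=1)).abs()
    order = np.argsort(-diff.to_numpy(), kind="stable")[: min(n_genes, len(diff))]
    return [matrix.genes[i] for i in order]


def select_tail_subset(
    expression: ExpressionMatrix,
    responses: pd.Series,
    N_grid: list[int] | None = None,
    n_genes_preselect: int = 2000,
    n_runs: int = 500,
    n_random_sets: int = 500,
    n_runs_random: int | None = None,
    purity_cutoff: float = 0.9,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> TailSelection:
    """Choose how many extreme responders to carry forward.

    For each even N in the grid the N/2 highest and N/2 lowest
    responders are clustered (NMF, k=2) on their most group-different
    genes and scored by purity against the true high/low split. The
    baseline repeats the same machinery on randomly drawn N-sample sets
    split into two arbitrary pseudo-groups. The chosen N is the largest
    whose true-tails purity meets ``purity_cutoff``; if none does, the
    argmax-purity N is returned with a warning.
    """
    if expression.state != "fully_normalized":
        raise ValueError("tail selection expects fully normalized expression")
    m = len(expression.samples)
    if N_grid is None:
        N_grid = list(range(20, 82, 2))
    if any(N % 2 or N > m for N in N_grid):
        raise ValueError("N_grid entries must be even and <= number of samples")
    if n_runs_random is None:
        n_runs_random = n_runs
    responses = responses.loc[expression.samples]
    order = _order_by_response(responses)

    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    rows = []
    tails: dict[int, tuple[list[str], list[str]]] = {}
    for N in N_grid:
        half = N // 2
        low_ids, high_ids = order[:half], order[-half:]
        tails[N] = (high_ids, low_ids)
        subset = low_ids + high_ids
        labels = np.array([0] * half + [1] * half)
        genes = preselect_genes(expression, high_ids, low_ids, n_genes_preselect)
        sub = expression.subset_genes(genes).subset_samples(subset)
        fit = nmf_factorize(
            nonnegativize(sub), k=2, n_runs=n_runs, max_iter=max_iter, tol=tol,
            seed=int(rng.integers(2**31)),
        )
        q_true = purity_entropy(fit.assignments, labels)

        pur_rand, ent_rand = [], []
        for _ in range(n_random_sets):
            pick = rng.permutation(m)[:N]
            ids = [expression.samples[i] for i in pick]
            pseudo_a, pseudo_b = ids[:half], ids[half:]
            pseudo_labels = np.array([0] * half + [1] * half)
            rgenes = preselect_genes(expression, pseudo_a, pseudo_b, n_genes_preselect)
            rsub = expression.subset_genes(rgenes).subset_samples(pseudo_a + pseudo_b)
            rfit = nmf_factorize(
                nonnegativize(rsub), k=2, n_runs=n_runs_random, max_iter=max_iter,
                tol=tol, seed=int(rng.integers(2**31)),
            )
            q = purity_entropy(rfit.assignments, pseudo_labels)
            pur_rand.append(q.purity)
            ent_rand.append(q.entropy)
        rows.append(
            {
                "N": N,
                "purity_true": q_true.purity,
                "purity_random": float(np.mean(pur_rand)) if pur_rand else np.nan,
                "entropy_true": q_true.entropy,
                "entropy_random": float(np.mean(ent_rand)) if ent_rand else np.nan,
            }
        )
    curve = pd.DataFrame(rows)
    meeting = curve[curve["purity_true"] >= purity_cutoff]
    if len(meeting):
        chosen = int(meeting["N"].max())
        met = True
    else:
        chosen = int(curve.loc[curve["purity_true"].idxmax(), "N"])
        met = False
        warnings.warn(
            f"no N reached purity cutoff {purity_cutoff}; falling back to "
            f"argmax-purity N={chosen}"
        )
    high_ids, low_ids = tails[chosen]
    return TailSelection(
        chosen_N=chosen, high_ids=high_ids, low_ids=low_ids, curve=curve, met_cutoff=met
    )


__all__ = [
    "NonNegativeData",
    "NmfFit",
    "ClusterQuality",
    "ConsensusSummary",
    "TailSelection",
    "nonnegativize",
    "nmf_factorize",
    "purity_entropy",
    "consensus_diagnostics",
    "preselect_genes",
    "select_tail_subset",
]
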