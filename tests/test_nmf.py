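"""NMF factorization, cluster-quality metrics, consensus diagnostics,
and tail-subset selection."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from statresp.datatypes import ExpressionMatrix
from statresp.nmf import (
    consensus_diagnostics,
    nmf_factorize,
    nonnegativize,
    preselect_genes,
    purity_entropy,
    select_tail_subset,
)


def _brute_force_purity_entropy(assignments, labels):
    """Literal double-loop evaluation of the purity/entropy formulas."""
    n = len(assignments)
    clusters = sorted(set(assignments))
    classes = sorted(set(labels))
    l = len(classes)
    purity = 0.0
    entropy = 0.0
    for i in clusters:
        members = [labels[t] for t in range(n) if assignments[t] == i]
        n_i = len(members)
        counts = [sum(1 for m in members if m == j) for j in classes]
        purity += max(counts)
        for nij in counts:
            if nij > 0:
                entropy += nij * math.log2(nij / n_i)
    return purity / n, -entropy / (n * math.log2(l))


@pytest.mark.parametrize("n, k, l", [(6, 2, 2), (5, 3, 3), (8, 2, 3), (7, 3, 2)])
def test_purity_entropy_match_exhaustive_enumeration(n, k, l, rng):
    labels = rng.integers(0, l, size=n)
    while len(set(labels.tolist())) < l:  # ensure all classes present
        labels = rng.integers(0, l, size=n)
    for assignment in itertools.product(range(k), repeat=n):
        q = purity_entropy(np.array(assignment), labels)
        p_ref, e_ref = _brute_force_purity_entropy(list(assignment), labels.tolist())
        assert q.purity == pytest.approx(p_ref, abs=1e-12)
        assert q.entropy == pytest.approx(e_ref, abs=1e-12)


@pytest.mark.parametrize(
    "assignments, labels, purity, entropy",
    [
        # perfect 2-cluster/2-class match
        ([0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1], 1.0, 0.0),
        # one cluster holding 4 + 4 of each class
        ([0] * 8, [0, 0, 0, 0, 1, 1, 1, 1], 0.5, 1.0),
        # clusters {3A, 1B} and {0A, 4B}
        ([0, 0, 0, 0, 1, 1, 1, 1], [0, 0, 0, 1, 1, 1, 1, 1], 7.0 / 8.0, None),
    ],
)
def test_purity_entropy_hand_values(assignments, labels, purity, entropy):
    q = purity_entropy(np.array(assignments), np.array(labels))
    assert q.purity == pytest.approx(purity, abs=1e-12)
    if entropy is not None:
        assert q.entropy == pytest.approx(entropy, abs=1e-12)


def test_purity_invariant_under_relabeling(rng):
    assignments = rng.integers(0, 3, size=30)
    labels = rng.integers(0, 2, size=30)
    base = purity_entropy(assignments, labels)
    perm_c = rng.permutation(3)[assignments]
    perm_l = rng.permutation(2)[labels]
    assert purity_entropy(perm_c, labels).purity == pytest.approx(base.purity)
    assert purity_entropy(assignments, perm_l).entropy == pytest.approx(base.entropy)


def test_single_true_class_entropy_undefined():
    with pytest.raises(ValueError, match="two true classes"):
        purity_entropy(np.array([0, 1, 0]), np.array([1, 1, 1]))


# ---------------------------------------------------------------------------


def test_exact_rank2_matrix_recovered(rng):
    A = rng.uniform(size=(20, 2)) @ rng.uniform(size=(2, 10))
    fit = nmf_factorize(A, k=2, n_runs=5, seed=1)
    assert fit.reconstruction_error / np.linalg.norm(A) < 1e-6


def test_reconstruction_error_monotone_per_iteration(rng):
    A = rng.uniform(size=(60, 25))
    fit = nmf_factorize(A, k=3, n_runs=3, seed=2)
    trace = fit.error_trace
    assert np.all(np.diff(trace) <= 1e-10 * trace[0])
    assert np.all(fit.W >= 0) and np.all(fit.H >= 0)


def test_rank_one_assigns_single_cluster(rng):
    A = rng.uniform(0.5, 1.5, size=(30, 12))
    fit = nmf_factorize(A, k=1, n_runs=3, seed=3)
    assert set(fit.assignments.tolist()) == {0}
    norms = np.linalg.norm(A, axis=0)
    assert np.corrcoef(fit.H.ravel(), norms)[0, 1] > 0.95


def test_best_error_competitive_with_sklearn(rng):
    from sklearn.decomposition import NMF as SkNMF

    A = rng.uniform(size=(50, 20))
    ours = nmf_factorize(A, k=3, n_runs=10, seed=4).reconstruction_error
    best_sk = min(
        np.linalg.norm(A - (m := SkNMF(3, init="random", solver="mu", max_iter=2000,
                                       random_state=s, tol=1e-6)).fit_transform(A) @ m.components_)
        for s in range(10)
    )
    assert ours <= best_sk * 1.05


def test_planted_two_blocks_recovered_matches_kmeans(rng):
    from sklearn.cluster import KMeans

    labels = np.array([0] * 15 + [1] * 15)
    X = rng.normal(size=(80, 30))
    X[:40, labels == 1] += 2.0
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    A = np.clip(stats.norm.cdf(Z), 1e-12, 1 - 1e-12)
    fit = nmf_factorize(A, k=2, n_runs=10, seed=5)
    assert purity_entropy(fit.assignments, labels).purity >= 0.99
    km = KMeans(2, n_init=10, random_state=0).fit_predict(A.T)
    assert purity_entropy(km, labels).purity >= 0.99  # independent oracle agrees


def test_nmf_input_validation(rng):
    with pytest.raises(ValueError):
        nmf_factorize(-rng.uniform(size=(5, 5)), k=2, n_runs=1)
    with pytest.raises(ValueError):
        nmf_factorize(rng.uniform(size=(5, 5)), k=0, n_runs=1)


# ---------------------------------------------------------------------------


def _planted_nonneg(rng, n_genes=60, m=24, shift=2.5):
    labels = np.array([0] * (m // 2) + [1] * (m // 2))
    X = rng.normal(size=(n_genes, m))
    X[: n_genes // 2, labels == 1] += shift
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    return np.clip(stats.norm.cdf(Z), 1e-12, 1 - 1e-12), labels


def test_consensus_stable_two_blocks(rng):
    A, _ = _planted_nonneg(rng)
    summaries = consensus_diagnostics(A, ranks=[2, 3, 4, 5], n_runs=15, seed=6,
                                      max_iter=500)
    by_rank = {s.k: s for s in summaries}
    # all runs agree at k=2: binary consensus, dispersion 1, cophenetic top
    assert set(np.round(np.unique(by_rank[2].consensus), 8).tolist()) <= {0.0, 1.0}
    assert by_rank[2].dispersion == pytest.approx(1.0, abs=1e-9)
    for k in (3, 4, 5):
        assert by_rank[2].cophenetic_correlation >= by_rank[k].cophenetic_correlation
        assert 0.0 <= by_rank[k].dispersion <= 1.0
        assert np.allclose(by_rank[k].consensus, by_rank[k].consensus.T)
    with pytest.raises(ValueError):
        consensus_diagnostics(A, ranks=[2], n_runs=1)


def test_nonnegativize_values_and_state(rng):
    values = rng.normal(size=(10, 40))
    values[0, 0], values[0, 1] = 0.0, 1.645
    matrix = ExpressionMatrix([f"g{i}" for i in range(10)], [f"s{j}" for j in range(40)],
                              values, state="fully_normalized")
    data = nonnegativize(matrix)
    assert data.matrix[0, 0] == pytest.approx(0.5, abs=1e-12)
    assert data.matrix[0, 1] == pytest.approx(0.95, abs=1e-3)
    assert data.matrix.min() > 0 and data.matrix.max() < 1
    # CDF is monotone within each gene
    for z_row, a_row in zip(values, data.matrix):
        order = np.argsort(z_row)
        assert np.all(np.diff(a_row[order]) >= 0)
    matrix.state = "raw"
    with pytest.raises(ValueError):
        nonnegativize(matrix)


# ---------------------------------------------------------------------------


def _expression_with_signal(rng, m=60, n_genes=150, n_sig=25, strength=1.2):
    responses = pd.Series(rng.normal(size=m), index=[f"s{j:02d}" for j in range(m)])
    X = rng.normal(size=(n_genes, m))
    X[:n_sig] += strength * np.sign(responses.to_numpy())[None, :]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    matrix = ExpressionMatrix([f"g{i:03d}" for i in range(n_genes)],
                              list(responses.index), Z, state="fully_normalized")
    return matrix, responses


def test_tail_selection_strong_signal_beats_random_baseline(rng):
    matrix, responses = _expression_with_signal(rng)
    sel = select_tail_subset(matrix, responses, N_grid=[20, 24, 28],
                             n_genes_preselect=80, n_runs=8, n_random_sets=6,
                             n_runs_random=4, purity_cutoff=0.9, max_iter=500, seed=7)
    assert sel.met_cutoff
    assert sel.chosen_N == 28  # largest N meeting the cutoff
    assert len(sel.high_ids) == len(sel.low_ids) == 14
    assert set(sel.high_ids).isdisjoint(sel.low_ids)
    assert np.all(sel.curve["purity_true"].to_numpy()
                  > sel.curve["purity_random"].to_numpy())
    # high tail really holds the highest responders
    assert min(responses[sel.high_ids]) > max(responses[sel.low_ids])


def test_tail_selection_null_matches_random_baseline(rng):
    # preselecting the most group-different genes overfits small subsets, so
    # under the null the true tails look exactly like the random baseline
    matrix, responses = _expression_with_signal(rng, strength=0.0)
    sel = select_tail_subset(matrix, responses, N_grid=[20, 24],
                             n_genes_preselect=80, n_runs=6, n_random_sets=8,
                             n_runs_random=4, purity_cutoff=0.9,
                             max_iter=400, seed=8)
    diff = (sel.curve["purity_true"] - sel.curve["purity_random"]).abs().mean()
    assert diff < 0.15  # exchangeable under the null, up to NMF noise at tiny N


def test_tail_selection_warns_when_cutoff_unreachable(rng):
    matrix, responses = _expression_with_signal(rng, m=40, n_genes=60, n_sig=5,
                                                strength=0.0)
    with pytest.warns(UserWarning, match="cutoff"):
        sel = select_tail_subset(matrix, responses, N_grid=[20], n_genes_preselect=30,
                                 n_runs=4, n_random_sets=2, n_runs_random=2,
                                 purity_cutoff=1.01, max_iter=300, seed=9)
    assert not sel.met_cutoff and sel.chosen_N == 20


def test_preselect_genes_largest_mean_difference(rng):
    matrix, responses = _expression_with_signal(rng, n_genes=50, n_sig=10)
    order = responses.sort_values()
    high, low = list(order.index[-10:]), list(order.index[:10])
    picked = preselect_genes(matrix, high, low, 10)
    assert len(picked) == 10
    frame = matrix.to_frame()
    diffs = (frame[high].mean(axis=1) - frame[low].mean(axis=1)).abs()
    assert set(picked) == set(diffs.nlargest(10).index)
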