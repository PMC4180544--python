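"""Relative-difference statistic, varying-s0 schedule, permutation null,
signature selection and overlap enrichment."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from statresp.signature import (
    S0Schedule,
    fit_s0_schedule,
    hypergeom_tail_exact,
    overlap_enrichment,
    permutation_pvalues,
    relative_difference,
    select_signature,
    signature_size_sweep,
)


def test_relative_difference_hand_values():
    high = np.array([[1.0, 2.0, 3.0]])
    low = np.array([[0.0, 1.0, 2.0]])
    out = relative_difference(high, low, 0.0)
    # s = sqrt((1/(3*2)) * (2 + 2)), d = 1 / s
    assert out["s"][0] == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)
    assert out["d"][0] == pytest.approx(1.0 / math.sqrt(2.0 / 3.0), abs=1e-12)
    s0 = 1.0 - math.sqrt(2.0 / 3.0)
    assert relative_difference(high, low, s0)["d"][0] == pytest.approx(1.0, abs=1e-12)
    # the rounded fudge from the worked example
    assert relative_difference(high, low, 0.18350)["d"][0] == pytest.approx(1.0, abs=1e-4)


def test_identical_groups_give_zero(rng):
    x = rng.normal(size=(20, 6))
    out = relative_difference(x, x.copy(), 0.1)
    assert np.allclose(out["d"], 0.0)


def test_antisymmetric_under_group_swap(rng):
    high, low = rng.normal(size=(30, 8)), rng.normal(size=(30, 8))
    d1 = relative_difference(high, low, 0.05)["d"].to_numpy()
    d2 = relative_difference(low, high, 0.05)["d"].to_numpy()
    assert np.array_equal(d1, -d2)


def test_equals_classical_t_statistic_at_zero_s0(rng):
    high, low = rng.normal(size=(100, 13)), rng.normal(size=(100, 13))
    d = relative_difference(high, low, 0.0)["d"].to_numpy()
    t = stats.ttest_ind(high, low, axis=1).statistic
    assert np.allclose(d, t, atol=1e-12)


def test_group_size_mismatch_rejected(rng):
    with pytest.raises(ValueError, match="equal size"):
        relative_difference(rng.normal(size=(5, 4)), rng.normal(size=(5, 3)))
    with pytest.raises(ValueError, match="N >= 2"):
        relative_difference(rng.normal(size=(5, 1)), rng.normal(size=(5, 1)))


def test_zero_scatter_zero_s0_flagged_infinite():
    high = np.array([[1.0, 1.0, 1.0]])
    low = np.array([[0.0, 0.0, 0.0]])
    with pytest.warns(UserWarning, match="infinite"):
        out = relative_difference(high, low, 0.0)
    assert np.isinf(out["d"][0])


# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_schedule_monotone_non_increasing_in_s(seed):
    rng = np.random.default_rng(seed)
    s = rng.gamma(2.0, 1.0, size=200)
    d_raw = rng.normal(size=200)
    schedule = fit_s0_schedule(s, d_raw)
    order = np.argsort(s)
    s0 = schedule.s0_of(s)
    assert np.all(np.diff(s0[order]) <= 1e-12)
    assert s0[order][-1] == pytest.approx(0.0, abs=1e-12)
    assert np.all(s0 >= 0)


def test_homoscedastic_null_prefers_little_shrinkage(rng):
    high, low = rng.normal(size=(2000, 26)), rng.normal(size=(2000, 26))
    base = relative_difference(high, low, 0.0)
    schedule = fit_s0_schedule(base["s"].to_numpy(), base["d"].to_numpy())
    cv0 = schedule.criterion_by_candidate[0]
    assert schedule.criterion_value <= cv0
    assert schedule.s0_max <= np.percentile(base["s"], 20)


def _heteroscedastic_null(rng, G=2000, N=26):
    """Null data whose d spread is inflated at low-scatter genes: per-group
    technical offsets that move the means without touching the within-group
    scatter, on genes a quarter of which have half the within-group SD."""
    sd = np.ones(G)
    sd[rng.permutation(G)[: G // 4]] = 0.5
    X = rng.normal(size=(G, 2 * N)) * sd[:, None]
    c = 0.5 * math.sqrt(2.0 / N) * math.sqrt(1.5)
    X[:, :N] += rng.normal(0, c, size=(G, 1))
    X[:, N:] += rng.normal(0, c, size=(G, 1))
    return X[:, :N], X[:, N:]


def test_varying_s0_stabilizes_heteroscedastic_null(rng):
    high, low = _heteroscedastic_null(rng)
    base = relative_difference(high, low, 0.0)
    s = base["s"].to_numpy()
    schedule = fit_s0_schedule(s, base["d"].to_numpy())
    assert schedule.s0_max > 0
    assert schedule.criterion_value < schedule.criterion_by_candidate[0]
    # spread of d in the lowest s-decile shrinks monotonically in s0_max
    low_decile = s <= np.quantile(s, 0.1)
    spreads = []
    for s0_max in np.percentile(s, [0, 5, 10, 20]):
        sched = S0Schedule(s0_max=float(s0_max), s_reference=np.sort(s))
        d = relative_difference(high, low, sched)["d"].to_numpy()
        spreads.append(np.std(d[low_decile]))
    assert np.all(np.diff(spreads) <= 1e-12)


def test_fit_s0_requires_enough_genes(rng):
    with pytest.raises(ValueError, match="100 genes"):
        fit_s0_schedule(rng.gamma(2, 1, size=50), rng.normal(size=50))


# ---------------------------------------------------------------------------


def test_tiny_groups_enumerated_exhaustively(rng):
    high, low = rng.normal(size=(50, 3)), rng.normal(size=(50, 3))
    a = permutation_pvalues(high, low, 0.0, n_perm=1000, seed=1)
    b = permutation_pvalues(high, low, 0.0, n_perm=1000, seed=99)
    # C(6,3) = 20 < 1000: the null is enumerated, so seeds are irrelevant
    assert a.attrs["n_perm_used"] == 20
    assert np.array_equal(a["p_perm"], b["p_perm"])
    # and relabeling within groups changes nothing beyond float-tie noise
    # (the identity relabeling sits in the enumerated null, so |d_obs| ties
    # with one null value exactly; column order perturbs that tie by an ulp)
    c = permutation_pvalues(high[:, [2, 0, 1]], low[:, [1, 2, 0]], 0.0,
                            n_perm=1000, seed=5)
    slack = 2.0 / (1.0 + 20 * 50)
    assert np.allclose(a["p_perm"], c["p_perm"], atol=slack)


def test_extreme_gene_attains_minimum_pooled_p(rng):
    high, low = rng.normal(size=(100, 10)), rng.normal(size=(100, 10))
    high[0] += 50.0  # dwarfs every permuted statistic
    out = permutation_pvalues(high, low, 0.0, n_perm=200, seed=2, pooling="pooled")
    n_used = out.attrs["n_perm_used"]
    assert out["p_perm"][0] == pytest.approx(1.0 / (1.0 + n_used * 100))


def test_per_gene_pooling_resolution(rng):
    high, low = rng.normal(size=(40, 10)), rng.normal(size=(40, 10))
    high[0] += 50.0
    out = permutation_pvalues(high, low, 0.0, n_perm=150, seed=3, pooling="per_gene")
    n_used = out.attrs["n_perm_used"]
    assert out["p_perm"][0] == pytest.approx(1.0 / (1.0 + n_used))
    assert (out["p_perm"] >= 1.0 / (1.0 + n_used)).all()
    with pytest.raises(ValueError):
        permutation_pvalues(high, low, 0.0, n_perm=10, pooling="bogus")


# ---------------------------------------------------------------------------


def test_select_signature_orders_by_p_then_effect(rng):
    import pandas as pd

    frame = pd.DataFrame(
        {"gene": ["a", "b", "c", "d"],
         "d": [0.5, -2.0, 1.0, -0.1],
         "p_perm": [0.01, 0.01, 0.5, 1.0]}
    )
    top, ranked = select_signature(frame, 2)
    assert top == ["b", "a"]  # same p, |d| breaks the tie
    assert list(ranked["rank"]) == [1, 2, 3, 4]
    assert list(ranked["direction"]) == ["up_in_low", "up_in_high", "up_in_high", "up_in_low"]
    full, _ = select_signature(frame, 4)
    assert sorted(full) == ["a", "b", "c", "d"]
    with pytest.raises(ValueError):
        select_signature(frame, 5)


def test_signature_size_sweep_calls_evaluator(rng):
    import pandas as pd

    frame = pd.DataFrame({"gene": list("abcdef"),
                          "d": rng.normal(size=6),
                          "p_perm": rng.uniform(size=6)})
    table = signature_size_sweep(frame, [2, 4], evaluate=len)
    assert list(table["score"]) == [2.0, 4.0]


# ---------------------------------------------------------------------------


def test_overlap_enrichment_disjoint_is_one():
    universe = {f"g{i}" for i in range(100)}
    assert overlap_enrichment(set(list(universe)[:10]), set(list(universe)[90:]),
                              universe) == pytest.approx(1.0)


def test_overlap_enrichment_matches_exact_tail_sum():
    # realistic scale: 48 of 100 vs a 3,170-gene reference
    # in a 20,000-gene universe
    for k, M, K, n in [(48, 20000, 3170, 100), (3, 50, 10, 8), (0, 30, 5, 6)]:
        exact = hypergeom_tail_exact(k, M, K, n)
        approx = float(stats.hypergeom.sf(k - 1, M, K, n))
        assert approx == pytest.approx(exact, rel=1e-12)


def test_overlap_enrichment_subset_monotonicity():
    universe = {f"g{i}" for i in range(1000)}
    reference = {f"g{i}" for i in range(500)}
    full = overlap_enrichment({f"g{i}" for i in range(10)}, reference, universe)
    partial = overlap_enrichment({f"g{i}" for i in range(495, 505)}, reference,
                                 universe)
    assert full < partial  # complete containment is the most surprising
    with pytest.raises(ValueError):
        overlap_enrichment({"g1"}, {"g2"}, set())
    with pytest.raises(ValueError):
        overlap_enrichment({"zz"}, reference, universe)
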