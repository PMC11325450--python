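import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from microagg.diversity import (accumulation_curve, compare_aggregates_vs_bulk,
                                cumulative_core_richness, rarefy, richness,
                                wilcoxon_rank_sum)
from microagg.iotables import CountTable


def ct(rows, prefix="s"):
    rows = np.atleast_2d(np.array(rows))
    return CountTable(tuple(f"{prefix}{i}" for i in range(rows.shape[0])),
                      tuple(f"a{j}" for j in range(rows.shape[1])), rows)


# ---------------------------------------------------------------- rarefy

def test_rarefy_depth_equal_total_is_identity():
    res = rarefy(ct([[8, 4, 3]]), depth=15, seed=0)
    np.testing.assert_array_equal(res.counts.counts, [[8, 4, 3]])


def test_rarefy_single_asv():
    res = rarefy(ct([[100]]), depth=10, seed=0)
    np.testing.assert_array_equal(res.counts.counts, [[10]])
    assert richness(res.counts).iloc[0] == 1


def test_rarefy_drops_shallow_samples_and_conserves_depth():
    res = rarefy(ct([[5, 5, 10], [1, 1, 0]]), depth=8, seed=0)
    assert res.dropped == ("s1",)
    assert res.counts.totals().tolist() == [8]
    orig = np.array([5, 5, 10])
    assert (np.asarray(res.counts.counts)[0] <= orig).all()


def test_rarefy_mean_richness_matches_hypergeometric_expectation():
    # E[S_d] = sum_i 1 - C(N - n_i, d) / C(N, d)
    counts = np.array([5, 5, 10])
    N, d = counts.sum(), 4
    expected = sum(1 - comb(N - n, d) / comb(N, d) for n in counts)
    vals = []
    for seed in range(10_000):
        res = rarefy(ct([counts]), depth=d, seed=seed)
        vals.append((np.asarray(res.counts.counts)[0] > 0).sum())
    assert abs(np.mean(vals) - expected) < 0.02


def test_rarefy_invalid_inputs():
    with pytest.raises(ValueError):
        rarefy(ct([[5, 5]]), depth=0)
    with pytest.raises(ValueError):
        rarefy(ct([[2, 1]]), depth=50)


# -------------------------------------------------------------- richness

def test_richness_counts_nonzero_columns():
    r = richness(ct([[0, 0, 0, 0], [1, 2, 0, 4]]))
    assert r.tolist() == [0, 3]


def test_richness_matches_brute_force():
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 5, size=(5, 20))
    r = richness(ct(mat))
    brute = [sum(1 for v in row if v > 0) for row in mat]
    assert r.tolist() == brute


# ------------------------------------------------- accumulation curves

def test_accumulation_single_and_identical_samples():
    c = accumulation_curve(ct([[3, 0, 1]]), n_perm=10, seed=0)
    assert c.mean_richness.tolist() == [2]
    c3 = accumulation_curve(ct([[3, 0, 1]] * 3), n_perm=50, seed=0)
    assert c3.mean_richness.tolist() == [2, 2, 2]
    assert (c3.upper - c3.lower).max() == 0


def test_accumulation_mean_matches_exhaustive_enumeration():
    mat = np.array([[2, 0, 0, 1],
                    [0, 3, 0, 1],
                    [1, 0, 4, 0]])
    pres = [set(np.flatnonzero(r)) for r in mat]
    exact = np.zeros(3)
    for order in itertools.permutations(range(3)):
        seen = set()
        for k, i in enumerate(order):
            seen |= pres[i]
            exact[k] += len(seen)
    exact /= 6
    curve = accumulation_curve(ct(mat), n_perm=4000, seed=1)
    np.testing.assert_allclose(curve.mean_richness, exact, atol=0.05)
    # k = n value is the pooled richness exactly, in every permutation
    assert curve.mean_richness[-1] == len(set().union(*pres))
    assert (np.diff(curve.mean_richness) >= 0).all()


def test_accumulation_monotone_every_permutation():
    rng = np.random.default_rng(2)
    mat = rng.integers(0, 3, size=(6, 30))
    from microagg.diversity import _cumulative_richness
    pres = mat > 0
    for seed in range(20):
        order = np.random.default_rng(seed).permutation(6)
        cum = _cumulative_richness(pres, order)
        assert (np.diff(cum) >= 0).all()


# ------------------------------------ per-core cumulative richness

def test_core_curconcentration_identical_and_disjoint(core_design):
    # identical aggregates: flat curve; disjoint: r * k
    ids = [f"c1-ag{i}" for i in range(1, 5)] + [f"c2-ag{i}" for i in range(1, 5)] \
        + ["c1-bulk", "c2-bulk"]
    same = np.tile([1, 1, 0, 0, 0, 0, 0, 0], (4, 1))
    disjoint = np.eye(8, dtype=int)[:4] * 3
    mat = np.vstack([same, disjoint, np.ones((2, 8), dtype=int)])
    counts = CountTable(tuple(ids), tuple(f"a{j}" for j in range(8)), mat)
    curves = cumulative_core_richness(counts, core_design, n_perm=10,
                                      min_aggregates=3, seed=0)
    c1 = curves[curves.core_id == "c1"].sort_values("k")
    assert c1.mean_richness.tolist() == [2, 2, 2, 2]
    c2 = curves[curves.core_id == "c2"].sort_values("k")
    assert c2.mean_richness.tolist() == [1, 2, 3, 4]


def test_core_curves_match_exhaustive_enumeration(core_design):
    rng = np.random.default_rng(3)
    mat = rng.integers(0, 3, size=(4, 12))
    ids = [f"c1-ag{i}" for i in range(1, 5)]
    full = np.vstack([mat, np.zeros((6, 12), dtype=int)])
    all_ids = ids + [f"c2-ag{i}" for i in range(1, 5)] + ["c1-bulk", "c2-bulk"]
    counts = CountTable(tuple(all_ids), tuple(f"a{j}" for j in range(12)), full)
    curves = cumulative_core_richness(counts, core_design, n_perm=5000,
                                      min_aggregates=4, seed=1)
    pres = [set(np.flatnonzero(r)) for r in mat]
    exact = np.zeros(4)
    for order in itertools.permutations(range(4)):
        seen = set()
        for k, i in enumerate(order):
            seen |= pres[i]
            exact[k] += len(seen)
    exact /= 24
    got = curves[curves.core_id == "c1"].sort_values("k").mean_richness
    np.testing.assert_allclose(got, exact, atol=0.1)


def test_compare_identical_groups_is_null():
    curves = pd.DataFrame({
        "core_id": list("abcd"), "depth_layer": "top", "k": 1,
        "mean_richness": [10.0, 11.0, 12.0, 13.0]})
    bulk = pd.Series([10.0, 11.0, 12.0, 13.0])
    res = compare_aggregates_vs_bulk(curves, bulk, "top")
    assert res.U.iloc[0] == 8  # n1 * n2 / 2
    assert res.p_value.iloc[0] > 0.99


# ------------------------------------------------------------ rank sum

def test_rank_sum_identical_multisets():
    r = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert r.U == 4.5
    assert r.p_value > 0.99


def test_rank_sum_exact_small_samples():
    r = wilcoxon_rank_sum([1, 2], [3, 4])
    assert r.U in (0, 4)
    assert r.p_value == pytest.approx(2 / 6)
    # full separation, n1 = n2 = 4: two-sided p = 2 / C(8, 4)
    r = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
    assert r.p_value == pytest.approx(2 / comb(8, 4))
    assert not r.tie_correction_applied


def test_rank_sum_exact_matches_enumeration_oracle():
    # enumerate the exact two-sided null for a 5 vs 4 untied comparison
    x = [1.0, 4.0, 6.0, 9.0, 11.0]
    y = [2.0, 3.0, 8.0, 10.0]
    res = wilcoxon_rank_sum(x, y)
    n1, n2 = len(x), len(y)
    pooled = sorted(x + y)
    u_obs = sum(1 for a in x for b in y if a > b) + \
        0.5 * sum(1 for a in x for b in y if a == b)
    null = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n1 + n2) if i not in combo]
        null.append(sum(1 for a in xs for b in ys if a > b))
    null = np.array(null)
    mean_u = n1 * n2 / 2
    p_exact = np.mean(np.abs(null - mean_u) >= abs(u_obs - mean_u) - 1e-9)
    assert res.p_value == pytest.approx(p_exact, abs=1e-12)


def test_rank_sum_tie_corrected_normal_for_large_samples():
    # tie-corrected two-sided normal approximation, computed from the formula
    rng = np.random.default_rng(1)
    x = np.round(rng.normal(0, 1, 30), 1)
    y = np.round(rng.normal(0.5, 1, 25), 1)
    res = wilcoxon_rank_sum(x, y)
    from scipy import stats
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2, n = len(x), len(y), len(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    _, t = np.unique(pooled, return_counts=True)
    var = n1 * n2 / 12 * (n + 1 - (t ** 3 - t).sum() / (n * (n - 1)))
    z = (abs(u - n1 * n2 / 2) - 0.5) / np.sqrt(var)
    p_manual = 2 * stats.norm.sf(z)
    assert res.tie_correction_applied
    assert res.p_value == pytest.approx(p_manual, abs=1e-6)


def test_rank_sum_rejects_empty():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])
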