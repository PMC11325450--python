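import itertools

import numpy as np
import pandas as pd
import pytest

from microagg.iotables import CountTable
from microagg.ordination import (DistanceMatrix, aitchison_distance,
                                 clr_transform, distance_decay, pcoa,
                                 spatial_distance_categories)
from tests.conftest import make_sample_frame


def ct(rows):
    rows = np.atleast_2d(np.array(rows))
    return CountTable(tuple(f"s{i}" for i in range(rows.shape[0])),
                      tuple(f"a{j}" for j in range(rows.shape[1])), rows)


# ------------------------------------------------------------------ CLR

def test_clr_equal_counts_is_zero():
    np.testing.assert_allclose(clr_transform(ct([[5, 5, 5]])).to_numpy(),
                               0, atol=1e-12)


def test_clr_rows_sum_to_zero_and_scale_invariance():
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 50, size=(8, 30))
    clr = clr_transform(ct(mat)).to_numpy()
    assert np.abs(clr.sum(axis=1)).max() < 1e-9
    # x and 2x give identical CLR rows (composition, not absolute counts)
    x = np.array([[10, 20, 70]])
    a = clr_transform(ct(x), pseudocount=1e-9).to_numpy()
    b = clr_transform(ct(2 * x), pseudocount=1e-9).to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_clr_matches_hand_computation():
    vals = np.log(np.array([11.0, 11.0, 81.0]))
    expected = vals - vals.mean()
    got = clr_transform(ct([[10, 10, 80]]), pseudocount=1).to_numpy()[0]
    np.testing.assert_allclose(got, expected, atol=1e-12)


# ----------------------------------------------------------- Aitchison

def test_aitchison_identical_and_scale_invariance():
    d = aitchison_distance(ct([[3, 5, 9], [3, 5, 9], [6, 10, 18]]),
                           pseudocount=1e-9)
    m = np.asarray(d.matrix)
    assert m[0, 1] < 1e-6
    assert m[0, 2] < 1e-6  # D(x, 2x) = 0 up to the vanishing pseudocount


def test_aitchison_matches_brute_force_and_triangle():
    rng = np.random.default_rng(1)
    mat = rng.integers(0, 40, size=(5, 12))
    D = np.asarray(aitchison_distance(ct(mat)).matrix)
    logs = np.log(mat + 1.0)
    clr = logs - logs.mean(axis=1, keepdims=True)
    # closure factor cancels in CLR, so brute-force from logs directly
    for i in range(5):
        for j in range(5):
            assert D[i, j] == pytest.approx(np.linalg.norm(clr[i] - clr[j]),
                                            abs=1e-9)
    for i, j, k in itertools.permutations(range(5), 3):
        assert D[i, k] <= D[i, j] + D[j, k] + 1e-9


# ----------------------------------------------------------------- PCoA

def test_pcoa_two_samples():
    D = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
    res = pcoa(D)
    assert res.coordinates.shape == (2, 1)
    np.testing.assert_allclose(np.abs(res.coordinates[:, 0]), 1.5, atol=1e-10)
    assert res.coordinates[:, 0].sum() == pytest.approx(0, abs=1e-10)


def test_pcoa_reconstructs_planar_configuration():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 2))
    from scipy.spatial.distance import pdist, squareform
    D = DistanceMatrix(tuple(map(str, range(12))), squareform(pdist(pts)))
    res = pcoa(D)
    rec = squareform(pdist(res.coordinates[:, :2]))
    np.testing.assert_allclose(rec, np.asarray(D.matrix), atol=1e-8)
    assert (np.diff(res.proportion_explained) <= 1e-12).all()


def test_pcoa_on_aitchison_equals_pca_on_clr():
    rng = np.random.default_rng(3)
    mat = rng.integers(0, 60, size=(30, 50))
    table = ct(mat)
    res = pcoa(aitchison_distance(table))
    clr = clr_transform(table).to_numpy()
    clr_c = clr - clr.mean(axis=0)
    # PCA eigenvalues of the CLR matrix = PCoA eigenvalues of Aitchison D
    sing = np.linalg.svd(clr_c, compute_uv=False)
    pca_eig = sing ** 2
    n_pos = min(len(res.eigenvalues), len(pca_eig))
    pos = res.eigenvalues[res.eigenvalues > 1e-8]
    np.testing.assert_allclose(pos, pca_eig[:len(pos)], rtol=1e-8)


def test_pcoa_axis_sign_deterministic():
    rng = np.random.default_rng(4)
    mat = rng.integers(0, 30, size=(10, 20))
    r1 = pcoa(aitchison_distance(ct(mat)))
    r2 = pcoa(aitchison_distance(ct(mat)))
    np.testing.assert_array_equal(r1.coordinates, r2.coordinates)
    for j in range(r1.coordinates.shape[1]):
        i = np.argmax(np.abs(r1.coordinates[:, j]))
        assert r1.coordinates[i, j] > 0


# --------------------------------------------- spatial categories/decay

def _decay_design():
    rows = []
    # two cores at one point, a second point 1 m away, a plot 15 m away
    layout = [
        ("c1", "P1a", "P1", 0.00), ("c1", "P1a", "P1", 0.001),
        ("c2", "P1a", "P1", 0.05),
        ("c3", "P1b", "P1", 1.0),
        ("c4", "P2a", "P2", 15.0),
    ]
    for i, (core, point, plot, x) in enumerate(layout):
        rows.append(dict(sample_id=f"g{i}", sample_type="aggregate",
                         depth_layer="top", plot_id=plot, point_id=point,
                         core_id=core, x=x, y=0.0))
    return make_sample_frame(rows)


def test_spatial_categories_assignments():
    cats = spatial_distance_categories(_decay_design())
    lookup = {(r.id1, r.id2): r.category for r in cats.itertuples()}
    assert lookup[("g0", "g1")] == "spsc"     # same parent core
    assert lookup[("g0", "g2")] == "apsc"     # adjacent cores, same point
    assert lookup[("g0", "g3")] == "1m"       # other point of the plot
    assert lookup[("g0", "g4")] == "10-20m"   # 15 m away


def test_spatial_categories_exclude_cross_depth_and_beyond_edges():
    rows = [
        dict(sample_id="t1", sample_type="aggregate", depth_layer="top",
             plot_id="P1", point_id="P1a", core_id="c1", x=0.0, y=0.0),
        dict(sample_id="d1", sample_type="aggregate", depth_layer="deep",
             plot_id="P1", point_id="P1a", core_id="c9", x=0.0, y=0.0),
        dict(sample_id="t2", sample_type="aggregate", depth_layer="top",
             plot_id="P2", point_id="P2a", core_id="c2", x=100.0, y=0.0),
    ]
    cats = spatial_distance_categories(make_sample_frame(rows))
    assert len(cats) == 0  # cross-depth pair and >60 m pair both excluded


def test_distance_decay_matches_brute_force_grouping():
    design = _decay_design()
    rng = np.random.default_rng(5)
    mat = rng.integers(0, 50, size=(5, 40))
    counts = CountTable(tuple(design.sample_ids),
                        tuple(f"a{j}" for j in range(40)), mat)
    D = aitchison_distance(counts)
    cats = spatial_distance_categories(design)
    decay = distance_decay(D, cats)
    pos = {s: k for k, s in enumerate(D.ids)}
    m = np.asarray(D.matrix)
    for r in decay.itertuples():
        sub = cats[(cats.category == r.category)]
        vals = [m[pos[a], pos[b]] for a, b in zip(sub.id1, sub.id2)]
        assert r.median == pytest.approx(np.median(vals))
        assert r.n_pairs == len(vals)


def test_distance_decay_identical_communities_zero():
    design = _decay_design()
    counts = CountTable(tuple(design.sample_ids), ("a0", "a1"),
                        np.tile([4, 7], (5, 1)))
    decay = distance_decay(aitchison_distance(counts),
                           spatial_distance_categories(design))
    assert (decay["median"].abs() < 1e-10).all()


def test_distance_decay_invariant_to_sample_order():
    design = _decay_design()
    rng = np.random.default_rng(6)
    mat = rng.integers(0, 50, size=(5, 30))
    ids = list(design.sample_ids)
    counts = CountTable(tuple(ids), tuple(f"a{j}" for j in range(30)), mat)
    d1 = distance_decay(aitchison_distance(counts),
                        spatial_distance_categories(design))
    perm = [3, 1, 4, 0, 2]
    counts2 = CountTable(tuple(ids[i] for i in perm),
                         tuple(f"a{j}" for j in range(30)), mat[perm])
    design2 = make_sample_frame([
        dict(sample_id=s, **design.data.loc[s,
             ["sample_type", "depth_layer", "plot_id", "point_id",
              "core_id", "x", "y"]].to_dict())
        for s in counts2.sample_ids])
    d2 = distance_decay(aitchison_distance(counts2),
                        spatial_distance_categories(design2))
    a = d1.sort_values(["category", "sample_type"]).reset_index(drop=True)
    b = d2.sort_values(["category", "sample_type"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a[["category", "median", "n_pairs"]],
                                  b[["category", "median", "n_pairs"]])
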