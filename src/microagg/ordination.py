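"""Compositional ordination and distance decay.

Community dissimilarity is the Aitchison distance: Euclidean distance
between centred-log-ratio (CLR) transformed samples.  Zeros are handled by
a unit pseudocount added to the raw counts before closure; composition
analyses consume the non-rarefied table, so the pseudocount operates on
raw counts.  PCoA embeds the distance matrix by eigendecomposition of the
Gower-centred matrix; distance decay groups pairwise dissimilarities into
ordered spatial categories, from pairs within one parent soil core (spsc)
through pairs tens of metres apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from microagg.diversity import wilcoxon_rank_sum
from microagg.iotables import CountTable, SampleFrame

__all__ = [
    "DistanceMatrix", "OrdinationResult", "DEFAULT_CATEGORY_EDGES",
    "CATEGORY_ORDER", "clr_transform", "aitchison_distance", "pcoa",
    "spatial_distance_categories", "distance_decay",
]

#: upper edges (m) of the metric distance bins, with their labels
DEFAULT_CATEGORY_EDGES = ((5.0, "1m"), (20.0, "10-20m"), (30.0, "20-30m"),
                          (40.0, "30-40m"), (50.0, "40-50m"), (60.0, "50-60m"))

CATEGORY_ORDER = ("spsc", "apsc", "1m", "10-20m", "20-30m", "30-40m",
                  "40-50m", "50-60m")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise dissimilarities with zero diagonal."""

    ids: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        ids = tuple(str(i) for i in self.ids)
        if m.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (m < -1e-12).any():
            raise ValueError("negative distances")
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "ids", ids)

    def subset(self, ids) -> "DistanceMatrix":
        pos = {s: k for k, s in enumerate(self.ids)}
        idx = [pos[str(i)] for i in ids]
        return DistanceMatrix(tuple(str(i) for i in ids),
                              np.asarray(self.matrix)[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.asarray(self.matrix), index=list(self.ids),
                            columns=list(self.ids))


@dataclass(frozen=True)
class OrdinationResult:
    ids: tuple
    coordinates: np.ndarray          # samples x positive axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def clr_transform(counts: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform of counts + pseudocount.

    Each sample is closed to proportions, logged, and centred by its mean
    log; rows of the result sum to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mat = np.asarray(counts.counts, dtype=float) + pseudocount
    logp = np.log(mat / mat.sum(axis=1, keepdims=True))
    clr = logp - logp.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=list(counts.sample_ids),
                        columns=list(counts.asv_ids))


def aitchison_distance(counts: CountTable,
                       pseudocount: float = 1.0) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    clr = clr_transform(counts, pseudocount)
    d = squareform(pdist(clr.to_numpy(), metric="euclidean"))
    return DistanceMatrix(tuple(clr.index), d)


def pcoa(D: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS).

    Gower double-centering of -D^2/2, eigendecomposition; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues are reported but excluded from the embedding.
    Axis sign is fixed by making the largest-magnitude loading positive.
    """
    d = np.asarray(D.matrix)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    a = -0.5 * d ** 2
    centre = np.eye(n) - np.ones((n, n)) / n
    g = centre @ a @ centre
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, abs(eigval[0]) * 1e-12)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    prop = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(D.ids, coords, eigval, prop)


def spatial_distance_categories(samples: SampleFrame, edges=DEFAULT_CATEGORY_EDGES,
                                sample_ids=None) -> pd.DataFrame:
    """Categorize same-depth, same-type sample pairs by spatial separation.

    Pairs from the same parent soil core are "spsc"; pairs from different
    cores of the same sampling point are "apsc"; all other pairs are binned
    by Euclidean distance using ``edges``.  Pairs spanning depth layers or
    sample types, and pairs beyond the last edge, are excluded.
    Returns a long DataFrame (id1, id2, sample_type, depth_layer, category,
    distance_m).
    """
    df = samples.data if sample_ids is None else samples.data.loc[list(sample_ids)]
    ids = df.index.to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)
    stype = df["sample_type"].to_numpy()
    depth = df["depth_layer"].to_numpy()
    core = df["core_id"].to_numpy()
    point = df["point_id"].to_numpy()
    rows = []
    n = len(df)
    for i in range(n):
        for j in range(i + 1, n):
            if stype[i] != stype[j] or depth[i] != depth[j]:
                continue
            dist = float(np.hypot(*(xy[i] - xy[j])))
            if core[i] == core[j]:
                cat = "spsc"
            elif point[i] == point[j]:
                cat = "apsc"
            else:
                cat = None
                for edge, label in edges:
                    if dist <= edge:
                        cat = label
                        break
                if cat is None:
                    continue  # beyond last edge: excluded
            rows.append((ids[i], ids[j], stype[i], depth[i], cat, dist))
    return pd.DataFrame(rows, columns=["id1", "id2", "sample_type",
                                       "depth_layer", "category",
                                       "distance_m"])


def distance_decay(D: DistanceMatrix, categories: pd.DataFrame) -> pd.DataFrame:
    """Median community dissimilarity per spatial category.

    Returns one row per (depth_layer, category, sample_type) with the
    median and standard deviation of pairwise dissimilarities and the pair
    count, plus an aggregate-vs-bulk rank-sum p-value where both types
    have pairs in the category.
    """
    if categories.empty:
        raise ValueError("no categorized pairs")
    pos = {s: k for k, s in enumerate(D.ids)}
    m = np.asarray(D.matrix)
    cat = categories.copy()
    cat["dissimilarity"] = [
        m[pos[a], pos[b]] for a, b in zip(cat["id1"], cat["id2"])
    ]
    rows = []
    for (depth, label), sub in cat.groupby(["depth_layer", "category"],
                                           sort=False):
        groups = {t: g["dissimilarity"].to_numpy()
                  for t, g in sub.groupby("sample_type")}
        p = np.nan
        if "aggregate" in groups and "bulk" in groups:
            p = wilcoxon_rank_sum(groups["aggregate"], groups["bulk"]).p_value
        for t, vals in sorted(groups.items()):
            rows.append({"depth_layer": depth, "category": label,
                         "sample_type": t,
                         "median": float(np.median(vals)),
                         "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "n_pairs": int(len(vals)),
                         "p_agg_vs_bulk": p})
    out = pd.DataFrame(rows)
    rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    out["_r"] = out["category"].map(rank)
    out = out.sort_values(["depth_layer", "_r", "sample_type"],
                          kind="mergesort").drop(columns="_r")
    return out.reset_index(drop=True)
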