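"""Phylum composition of cumulative abundance categories.

Within each sample, ASVs are ranked by decreasing relative abundance
(dense ranks, ties broken by ASV identifier).  Abundance category k pools,
from every sample in a group (aggregates or bulk samples of one depth
layer), the ASVs ranked <= k.  The composition of category k is the
per-phylum share of pooled sample-ASV incidences — an ASV in ten samples'
top-k contributes ten incidences (a union-of-unique-ASVs variant is
available behind a flag).  Phyla below ``min_frac`` of a category are
collapsed into a "<5%" class.  Based on non-rarefied counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from microagg.iotables import CountTable, SampleFrame, TaxonomyTable

__all__ = ["rank_asvs", "abundance_category_composition", "OTHER_LABEL"]

OTHER_LABEL = "<5%"


def rank_asvs(counts: CountTable, sample_id: str) -> pd.Series:
    """Dense ranks 1..r of the ASVs present in one sample.

    Rank 1 is the most abundant; ties share relative abundance and are
    broken lexicographically by ASV identifier.  Absent ASVs are unranked.
    """
    pos = {s: k for k, s in enumerate(counts.sample_ids)}
    if sample_id not in pos:
        raise KeyError(sample_id)
    row = np.asarray(counts.counts)[pos[sample_id]]
    present = row > 0
    if not present.any():
        raise ValueError(f"sample {sample_id!r} has no reads")
    ids = np.asarray(counts.asv_ids, dtype=object)[present]
    vals = row[present]
    order = np.lexsort((ids, -vals))  # by decreasing count, then id
    ranks = np.empty(len(ids), dtype=np.int64)
    ranks[order] = np.arange(1, len(ids) + 1)
    return pd.Series(ranks, index=ids, name="rank").sort_index()


def _rank_matrix(mat: np.ndarray, asv_ids) -> np.ndarray:
    """Per-sample ranks (0 where absent), vectorized over samples."""
    n, S = mat.shape
    ids = np.asarray(asv_ids, dtype=object)
    ranks = np.zeros((n, S), dtype=np.int64)
    for i in range(n):
        row = mat[i]
        present = np.flatnonzero(row > 0)
        sub = present[np.argsort(ids[present])]
        sub = sub[np.argsort(-row[sub], kind="stable")]
        ranks[i, sub] = np.arange(1, len(sub) + 1)
    return ranks


def abundance_category_composition(counts: CountTable, taxonomy: TaxonomyTable,
                                   samples: SampleFrame,
                                   sample_type: str, depth_layer: str,
                                   K: int = 100, min_frac: float = 0.05,
                                   pooling: str = "multiplicity") -> pd.DataFrame:
    """Per-category phylum proportions for one sample-type x depth group.

    Returns a long DataFrame (k, phylum, proportion); per k the proportions
    sum to 1 and phyla under ``min_frac`` are merged into ``"<5%"``.
    """
    if pooling not in ("multiplicity", "union"):
        raise ValueError(f"unknown pooling {pooling!r}")
    meta = samples.data.loc[list(counts.sample_ids)]
    mask = ((meta["sample_type"] == sample_type)
            & (meta["depth_layer"] == depth_layer)).to_numpy()
    if not mask.any():
        raise ValueError(f"no {sample_type!r} samples in {depth_layer!r}")
    mat = np.asarray(counts.counts)[mask]
    ranks = _rank_matrix(mat, counts.asv_ids)
    phyla = taxonomy.phylum_of(counts.asv_ids)
    uniq_phyla, phy_idx = np.unique(phyla, return_inverse=True)

    # counts[p, k] = incidences of phylum p with rank <= k+1
    P = len(uniq_phyla)
    hist = np.zeros((P, K), dtype=np.int64)
    if pooling == "multiplicity":
        r = ranks[(ranks > 0) & (ranks <= K)]
        p = np.broadcast_to(phy_idx, ranks.shape)[(ranks > 0) & (ranks <= K)]
        np.add.at(hist, (p, r - 1), 1)
        cum = hist.cumsum(axis=1)
    else:  # union: each ASV counted once, at its best rank in the group
        best = np.where(ranks > 0, ranks, np.iinfo(np.int64).max).min(axis=0)
        sel = (best <= K)
        np.add.at(hist, (phy_idx[sel], best[sel] - 1), 1)
        cum = hist.cumsum(axis=1)
    totals = cum.sum(axis=0)
    rows = []
    for k in range(1, K + 1):
        tot = totals[k - 1]
        if tot == 0:
            continue
        props = cum[:, k - 1] / tot
        small = props < min_frac
        for p in np.flatnonzero(~small):
            rows.append({"k": k, "phylum": uniq_phyla[p],
                         "proportion": float(props[p])})
        if small.any() and props[small].sum() > 0:
            rows.append({"k": k, "phylum": OTHER_LABEL,
                         "proportion": float(props[small].sum())})
    return pd.DataFrame(rows)
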