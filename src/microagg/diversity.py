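"""Rarefaction, richness, and permutation species-accumulation curves.

Richness comparisons between sample types are standardized by rarefying
every sample to a common read depth (a single seeded draw per sample,
without replacement); samples below the depth are dropped and reported.
Accumulation curves add samples in random order and average the cumulative
unique-ASV count over permutations; the per-core variant compares the
cumulative richness of k aggregates from one parent soil core against the
richness of single bulk samples via two-sided rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from microagg.iotables import CountTable, SampleFrame

__all__ = [
    "RarefactionResult",
    "AccumulationCurve",
    "RankSumResult",
    "rarefy",
    "richness",
    "accumulation_curve",
    "cumulative_core_richness",
    "compare_aggregates_vs_bulk",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class RarefactionResult:
    counts: CountTable
    depth: int
    dropped: tuple


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean cumulative richness vs number of samples, with a 95 % band.

    The band is the empirical 2.5 %/97.5 % quantile across permutations
    (no normality assumption).
    """

    k: np.ndarray
    mean_richness: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Mann-Whitney U test result with group medians."""

    U: float
    p_value: float
    n1: int
    n2: int
    tie_correction_applied: bool
    median1: float = np.nan
    median2: float = np.nan


def rarefy(counts: CountTable, depth: int, seed: int = 0) -> RarefactionResult:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and listed in
    the result.  One draw per sample; deterministic given the seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.totals()
    keep = totals >= depth
    dropped = tuple(np.asarray(counts.sample_ids)[~keep])
    if not keep.any():
        raise ValueError("all samples fall below the rarefaction depth")
    mat = np.asarray(counts.counts)[keep]
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = rng.multivariate_hypergeometric(mat[i], depth)
    kept_ids = tuple(np.asarray(counts.sample_ids)[keep])
    return RarefactionResult(CountTable(kept_ids, counts.asv_ids, out),
                             depth, dropped)


def richness(counts: CountTable) -> pd.Series:
    """Observed ASV count (nonzero columns) per sample."""
    r = (np.asarray(counts.counts) > 0).sum(axis=1)
    return pd.Series(r, index=list(counts.sample_ids), name="richness")


def _cumulative_richness(presence: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Cumulative unique-ASV count after adding samples in ``order``."""
    perm = presence[order]
    seen = np.cumsum(perm, axis=0) > 0
    return seen.sum(axis=1)


def accumulation_curve(counts: CountTable, sample_subset=None,
                       n_perm: int = 1000, seed: int = 0) -> AccumulationCurve:
    """Mean species accumulation curve over random sample orderings."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    table = counts if sample_subset is None else counts.subset_samples(sample_subset)
    n = table.n_samples
    if n == 0:
        raise ValueError("empty sample subset")
    presence = table.presence()
    rng = np.random.default_rng(seed)
    curves = np.empty((n_perm, n), dtype=np.int64)
    for b in range(n_perm):
        curves[b] = _cumulative_richness(presence, rng.permutation(n))
    mean = curves.mean(axis=0)
    lower = np.quantile(curves, 0.025, axis=0)
    upper = np.quantile(curves, 0.975, axis=0)
    return AccumulationCurve(np.arange(1, n + 1), mean, lower, upper,
                             n_perm, seed)


def cumulative_core_richness(counts: CountTable, samples: SampleFrame,
                             n_perm: int = 100, min_aggregates: int = 3,
                             seed: int = 0) -> pd.DataFrame:
    """Per-core mean cumulative aggregate richness at each k.

    Only parent soil cores with at least ``min_aggregates`` aggregates
    present in the (rarefied) count table are considered.  Returns a long
    DataFrame (core_id, depth_layer, k, mean_richness).
    """
    meta = samples.data.loc[list(counts.sample_ids)]
    agg = meta[meta["sample_type"] == "aggregate"]
    rows = []
    rng = np.random.default_rng(seed)
    for core_id, sub in agg.groupby("core_id", observed=True, sort=True):
        ids = sorted(sub.index)
        if len(ids) < min_aggregates:
            continue
        curve = accumulation_curve(counts, ids, n_perm=n_perm,
                                   seed=int(rng.integers(2 ** 31)))
        for k, m in zip(curve.k, curve.mean_richness):
            rows.append({"core_id": core_id,
                         "depth_layer": sub["depth_layer"].iloc[0],
                         "k": int(k), "mean_richness": float(m)})
    if not rows:
        raise ValueError("no core passes the min_aggregates filter")
    return pd.DataFrame(rows)


def compare_aggregates_vs_bulk(core_curves: pd.DataFrame,
                               bulk_richness: pd.Series,
                               depth_layer: str) -> pd.DataFrame:
    """Rank-sum test of cumulative aggregate richness vs bulk richness per k.

    ``core_curves`` is the output of :func:`cumulative_core_richness`;
    ``bulk_richness`` must be indexed by bulk sample id with a matching
    SampleFrame-derived depth restriction applied by the caller.
    """
    sub = core_curves[core_curves["depth_layer"] == depth_layer]
    if sub.empty or len(bulk_richness) == 0:
        raise ValueError(f"empty group in depth layer {depth_layer!r}")
    out = []
    bulk_vals = bulk_richness.to_numpy(dtype=float)
    for k, grp in sub.groupby("k", sort=True):
        agg_vals = grp["mean_richness"].to_numpy(dtype=float)
        if len(agg_vals) < 2 or len(bulk_vals) < 2:
            raise ValueError("a group has fewer than 2 values")
        res = wilcoxon_rank_sum(agg_vals, bulk_vals)
        out.append({"depth_layer": depth_layer, "k": int(k),
                    "n_cores": len(agg_vals), "n_bulk": len(bulk_vals),
                    "median_aggregates": float(np.median(agg_vals)),
                    "median_bulk": float(np.median(bulk_vals)),
                    "U": res.U, "p_value": res.p_value})
    return pd.DataFrame(out)


def wilcoxon_rank_sum(x, y) -> RankSumResult:
    """Two-sided Mann-Whitney U (a.k.a. Wilcoxon rank-sum) test.

    Exact null distribution for small untied samples (n1, n2 <= 8),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input to rank-sum test")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (not has_ties) and x.size <= 8 and y.size <= 8
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=not exact)
    return RankSumResult(U=float(res.statistic),
                         p_value=float(min(res.pvalue, 1.0)),
                         n1=int(x.size), n2=int(y.size),
                         tie_correction_applied=bool(has_ties and not exact),
                         median1=float(np.median(x)),
                         median2=float(np.median(y)))
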