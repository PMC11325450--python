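"""Shared/unique ASV partitioning within parent soil cores and
aggregate-vs-bulk overlap.

For four aggregates of one parent soil core, an ASV is "unique" if it is
present (count > 0 on the rarefied table) in exactly one of the four
communities and "shared" if present in all four.  Fractions are computed
per aggregate — which share of *that* community's ASVs, and of its reads,
falls in each class — then averaged over the four aggregates.  Taxa
present in 2-3 of the 4 aggregates form the intermediate class, reported
so the three classes audit to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from microagg.iotables import CountTable, SampleFrame

__all__ = ["CorePartition", "VennResult", "core_partition",
           "partition_summary", "sample_type_overlap"]


@dataclass(frozen=True)
class CorePartition:
    core_id: str
    depth_layer: str
    n_aggregates: int
    frac_unique_asvs: float
    frac_shared_asvs: float
    frac_intermediate_asvs: float
    abund_frac_unique: float
    abund_frac_shared: float
    abund_frac_intermediate: float


@dataclass(frozen=True)
class VennResult:
    """Two-set overlap of pooled ASV presence between sample types."""

    n_both: int
    n_only_a: int
    n_only_b: int

    @property
    def n_union(self) -> int:
        return self.n_both + self.n_only_a + self.n_only_b

    @property
    def frac_both(self) -> float:
        return self.n_both / self.n_union

    @property
    def frac_only_a(self) -> float:
        return self.n_only_a / self.n_union

    @property
    def frac_only_b(self) -> float:
        return self.n_only_b / self.n_union


def core_partition(counts: CountTable, samples: SampleFrame, core_id: str,
                   n_required: int = 4, seed: int = 0) -> CorePartition:
    """Unique/shared ASV fractions for ``n_required`` aggregates of a core.

    If the core has more aggregates than required, a seeded random subset
    is used.  Fractions and relative-abundance fractions are per-aggregate
    shares averaged over the chosen aggregates.
    """
    if n_required < 2:
        raise ValueError("n_required must be >= 2")
    meta = samples.data.loc[list(counts.sample_ids)]
    agg = meta[(meta["sample_type"] == "aggregate")
               & (meta["core_id"] == core_id)]
    ids = sorted(agg.index)
    if len(ids) < n_required:
        raise ValueError(
            f"core {core_id!r} has {len(ids)} aggregates; "
            f"{n_required} required")
    if len(ids) > n_required:
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in np.sort(
            rng.choice(len(ids), size=n_required, replace=False))]
    sub = counts.subset_samples(ids)
    mat = np.asarray(sub.counts, dtype=float)
    pres = mat > 0
    occ = pres.sum(axis=0)  # in how many of the n aggregates each ASV occurs
    unique = occ == 1
    shared = occ == n_required

    fr_u, fr_s, fr_i, ab_u, ab_s, ab_i = [], [], [], [], [], []
    for i in range(n_required):
        p = pres[i]
        n_present = p.sum()
        total = mat[i].sum()
        fr_u.append((p & unique).sum() / n_present)
        fr_s.append((p & shared).sum() / n_present)
        fr_i.append((p & ~unique & ~shared).sum() / n_present)
        ab_u.append(mat[i, p & unique].sum() / total)
        ab_s.append(mat[i, p & shared].sum() / total)
        ab_i.append(mat[i, p & ~unique & ~shared].sum() / total)
    return CorePartition(
        core_id=core_id,
        depth_layer=str(agg["depth_layer"].iloc[0]),
        n_aggregates=n_required,
        frac_unique_asvs=float(np.mean(fr_u)),
        frac_shared_asvs=float(np.mean(fr_s)),
        frac_intermediate_asvs=float(np.mean(fr_i)),
        abund_frac_unique=float(np.mean(ab_u)),
        abund_frac_shared=float(np.mean(ab_s)),
        abund_frac_intermediate=float(np.mean(ab_i)),
    )


def partition_all_cores(counts: CountTable, samples: SampleFrame,
                        n_required: int = 4, seed: int = 0) -> list:
    """core_partition for every core with enough aggregates in the table."""
    meta = samples.data.loc[list(counts.sample_ids)]
    agg = meta[meta["sample_type"] == "aggregate"]
    sizes = agg.groupby("core_id", observed=True).size()
    out = []
    rng = np.random.default_rng(seed)
    for core_id in sorted(sizes.index[sizes >= n_required]):
        out.append(core_partition(counts, samples, core_id, n_required,
                                  seed=int(rng.integers(2 ** 31))))
    return out


def partition_summary(partitions) -> pd.DataFrame:
    """Median and IQR of the partition fractions across cores, per depth."""
    if not partitions:
        raise ValueError("no core partitions to summarize")
    df = pd.DataFrame([p.__dict__ for p in partitions])
    metrics = ["frac_unique_asvs", "frac_shared_asvs",
               "abund_frac_unique", "abund_frac_shared"]
    rows = []
    for depth, sub in df.groupby("depth_layer", sort=True):
        for m in metrics:
            v = sub[m].to_numpy()
            rows.append({"depth_layer": depth, "metric": m,
                         "median": float(np.median(v)),
                         "q25": float(np.quantile(v, 0.25)),
                         "q75": float(np.quantile(v, 0.75)),
                         "n_cores": len(sub)})
    return pd.DataFrame(rows)


def sample_type_overlap(counts: CountTable, samples: SampleFrame) -> VennResult:
    """Pooled ASV overlap between aggregates (set a) and bulk samples (set b)."""
    meta = samples.data.loc[list(counts.sample_ids)]
    pres = counts.presence()
    is_agg = (meta["sample_type"] == "aggregate").to_numpy()
    is_bulk = (meta["sample_type"] == "bulk").to_numpy()
    if not is_agg.any() or not is_bulk.any():
        raise ValueError("both sample types must be present")
    in_agg = pres[is_agg].any(axis=0)
    in_bulk = pres[is_bulk].any(axis=0)
    return VennResult(n_both=int((in_agg & in_bulk).sum()),
                      n_only_a=int((in_agg & ~in_bulk).sum()),
                      n_only_b=int((~in_agg & in_bulk).sum()))
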