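"""Hierarchical metacommunity simulator with the field study's sampling design.

The generator reproduces a nested design: 5 plots on an 11 x 65 m slope,
two sampling points ~1 m apart per plot, two parent soil cores a few
centimetres apart per point and depth layer (top 0-5 cm, deep 15-20 cm),
five ~2-mm aggregates plus one homogenized bulk sample per core.  With the
default 5 % aggregate dropout this yields 190 aggregate and 40 bulk
samples, the sample sizes of the motivating field campaign.

Community structure is built multiplicatively on the log-abundance scale:
a regional lognormal species-abundance distribution perturbed by
independent Gaussian effects at each hierarchy level (depth, plot, point,
core, aggregate) plus a Gaussian-niche shift along a latent organic-matter
(OM) axis.  This produces nested beta-diversity (within-core pairs more
similar than between-plot pairs), a long tail of rare taxa heterogeneous
at the aggregate scale, and environment-composition coupling.  Richness
responds to OM through an evenness tilt: the spread of log abundances is
compressed where the tilt is high, so more taxa clear the detection limit
at a fixed read depth; the tilt's shape (unimodal or monotone in OM) is
configurable per depth layer.

Bulk community = mean of the core's aggregate compositions plus a small
bulk-only habitat component (taxa occupying inter-aggregate habitats that
2-mm aggregates never sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from microagg.iotables import CountTable, SampleFrame

__all__ = [
    "DesignParams",
    "CommunityParams",
    "SeqParams",
    "generate_design",
    "generate_environment",
    "generate_communities",
    "simulate_reads",
    "generate_dataset",
]


@dataclass(frozen=True)
class DesignParams:
    """Sampling-design geometry and sample counts."""

    n_plots: int = 5
    points_per_plot: int = 2
    cores_per_point_per_depth: int = 2
    aggregates_per_core: int = 5
    depths: tuple = ("top", "deep")
    slope_extent_m: tuple = (65.0, 11.0)
    point_separation_m: float = 1.0
    aggregate_dropout: float = 10 / 200

    def __post_init__(self):
        for name in ("n_plots", "points_per_plot", "cores_per_point_per_depth",
                     "aggregates_per_core"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.aggregate_dropout < 1:
            raise ValueError("aggregate_dropout must be in [0, 1)")


@dataclass(frozen=True)
class CommunityParams:
    """Regional pool and hierarchy/environment effect sizes.

    effect_sd values are standard deviations of multiplicative
    (log-abundance) effects; env_niche_strength is the curvature of the
    Gaussian niche along the latent OM axis.
    """

    regional_richness: int = 2000
    sad_meanlog: float = 0.0
    sad_sdlog: float = 1.6
    effect_sd: Mapping[str, float] = field(default_factory=lambda: {
        "depth": 1.0, "plot": 0.45, "point": 0.25,
        "core": 0.5, "aggregate": 0.7,
    })
    env_niche_strength: float = 0.35
    richness_env_mode: Mapping[str, str] | str = field(
        default_factory=lambda: {"top": "unimodal", "deep": "monotone"})
    richness_env_amp: float = 0.5
    richness_niche_width: float = 0.8
    richness_protected_quantile: float = 0.75
    richness_avail_jitter: float = 0.12
    unimodal_optimum_offset: float = 0.0
    env_noise_scale: float = 1.0
    frac_bulk_exclusive: float = 0.03
    bulk_habitat_weight: float = 0.05
    swc_missing_rate: float = 0.0

    def __post_init__(self):
        if self.regional_richness < 2:
            raise ValueError("regional_richness must be >= 2")
        if any(v < 0 for v in self.effect_sd.values()):
            raise ValueError("effect_sd values must be >= 0")

    def mode_for(self, depth: str) -> str:
        if isinstance(self.richness_env_mode, str):
            return self.richness_env_mode
        return self.richness_env_mode[depth]


@dataclass(frozen=True)
class SeqParams:
    """Read-depth law: negative-binomial depth with a hard floor.

    Defaults put roughly 2 % of samples below a rarefaction depth of
    ~8200 reads, so the sample-dropping path of rarefaction is exercised.
    """

    mean_depth: int = 20000
    depth_dispersion: float = 12.0
    min_depth_floor: int = 500

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


# latent-OM -> measurement maps (depth contrasts and noise scales)
_OM_DEPTH_MEAN = {"top": 0.55, "deep": -0.55}
_OM_CORE_SD = {"top": 0.55, "deep": 0.30}
_OM_AGG_SD = {"top": 0.30, "deep": 0.18}


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def generate_design(params: DesignParams, seed: int) -> SampleFrame:
    """Lay out plots, points, cores, and aggregate/bulk samples on the slope."""
    rng = _child_rng(seed, 0)
    sx, sy = params.slope_extent_m
    rows = []
    plot_step = sx / params.n_plots
    for ip in range(params.n_plots):
        plot_id = f"P{ip + 1}"
        px = (ip + 0.5) * plot_step + rng.uniform(-0.08, 0.08) * plot_step
        py = sy / 2 + rng.uniform(-0.25, 0.25) * sy
        theta = rng.uniform(0, 2 * np.pi)  # axis joining the plot's two points
        for jp in range(params.points_per_plot):
            point_id = f"{plot_id}{chr(ord('a') + jp)}"
            r = params.point_separation_m / 2
            qx = px + np.cos(theta) * r * (1 if jp % 2 == 0 else -1)
            qy = py + np.sin(theta) * r * (1 if jp % 2 == 0 else -1)
            for depth in params.depths:
                for kc in range(params.cores_per_point_per_depth):
                    core_id = f"{point_id}-{depth}-c{kc + 1}"
                    cx = qx + rng.uniform(-0.02, 0.02)
                    cy = qy + rng.uniform(-0.02, 0.02)
                    for ia in range(params.aggregates_per_core):
                        rows.append({
                            "sample_id": f"{core_id}-ag{ia + 1}",
                            "sample_type": "aggregate",
                            "depth_layer": depth,
                            "plot_id": plot_id, "point_id": point_id,
                            "core_id": core_id,
                            "x": cx + rng.uniform(-0.002, 0.002),
                            "y": cy + rng.uniform(-0.002, 0.002),
                        })
                    rows.append({
                        "sample_id": f"{core_id}-bulk",
                        "sample_type": "bulk",
                        "depth_layer": depth,
                        "plot_id": plot_id, "point_id": point_id,
                        "core_id": core_id, "x": cx, "y": cy,
                    })
    df = pd.DataFrame(rows).set_index("sample_id")
    agg_ids = df.index[df["sample_type"] == "aggregate"]
    n_drop = int(round(params.aggregate_dropout * len(agg_ids)))
    if n_drop:
        drop = rng.choice(len(agg_ids), size=n_drop, replace=False)
        df = df.drop(agg_ids[np.sort(drop)])
    return SampleFrame(df)


def generate_environment(design: SampleFrame, params: CommunityParams,
                         seed: int) -> tuple[SampleFrame, pd.Series]:
    """Fill the environment columns from a latent organic-matter (OM) axis.

    Returns the augmented SampleFrame and the per-sample latent OM values
    (ground truth for recovery tests).  Carbon and nitrogen both increase
    with OM (with correlated noise), recycled OM is more 13C-enriched and
    15N-enriched at low OM, water content and microbial density increase
    with OM; the top layer has a higher mean and variance of C.
    """
    rng = _child_rng(seed, 1)
    df = design.data.copy()
    ns = params.env_noise_scale

    core_om: dict[str, float] = {}
    for core_id, sub in df.groupby("core_id", observed=True):
        depth = sub["depth_layer"].iloc[0]
        core_om[core_id] = (_OM_DEPTH_MEAN[depth]
                            + rng.normal(0, _OM_CORE_SD[depth]))
    om = np.empty(len(df))
    order = np.argsort(df.index.to_numpy())  # draw noise in id order: deterministic
    for pos in order:
        row = df.iloc[pos]
        base = core_om[row["core_id"]]
        if row["sample_type"] == "aggregate":
            om[pos] = base + rng.normal(0, _OM_AGG_SD[row["depth_layer"]])
        else:
            om[pos] = base
    # bulk OM = mean of its aggregates' OM (homogenized core)
    is_bulk = (df["sample_type"] == "bulk").to_numpy()
    agg_mean = pd.Series(om[~is_bulk], index=df.index[~is_bulk]).groupby(
        df.loc[~is_bulk, "core_id"], observed=True).mean()
    for pos in np.flatnonzero(is_bulk):
        cid = df.iloc[pos]["core_id"]
        if cid in agg_mean.index:
            om[pos] = agg_mean[cid]

    n = len(df)
    c = np.exp(np.log(2.5) + 0.5 * om + ns * rng.normal(0, 0.05, n))
    cn = 15.0 - 1.0 * om + ns * rng.normal(0, 0.6, n)
    cn = np.clip(cn, 5.0, None)
    nitrogen = c / cn
    df["C_pct"] = c
    df["N_pct"] = nitrogen
    df["CN_ratio"] = c / nitrogen
    df["d13C_permil"] = -27.0 - 1.2 * om + ns * rng.normal(0, 0.3, n)
    df["d15N_permil"] = 3.0 - 1.0 * om + ns * rng.normal(0, 0.4, n)
    df["SWC"] = np.exp(np.log(0.35) + 0.3 * om + ns * rng.normal(0, 0.08, n))
    df["gene_copies"] = np.exp(np.log(1e9) + 0.8 * om + ns * rng.normal(0, 0.3, n))
    if params.swc_missing_rate > 0:
        is_agg = (df["sample_type"] == "aggregate").to_numpy()
        miss = rng.random(n) < params.swc_missing_rate
        df.loc[miss & is_agg, "SWC"] = np.nan
    return SampleFrame(df), pd.Series(om, index=df.index, name="latent_om")


def _availability(om: np.ndarray, mode: str, params: CommunityParams,
                  depth: str) -> np.ndarray:
    """Fraction of the filterable taxon pool available per aggregate.

    Models environmental filtering: richer organic matter supports more
    niches.  The layer's latent-OM mean and spread anchor the response so
    that a unimodal availability peaks inside the layer's OM range, while
    a monotone availability is linear in the noise-free carbon proxy
    exp(OM/2) across it — so expected richness is close to linear in
    measured carbon.  Values lie in [1 - richness_env_amp, 1].
    """
    mu = _OM_DEPTH_MEAN[depth]
    sigma = float(np.hypot(_OM_CORE_SD[depth], _OM_AGG_SD[depth]))
    amp = params.richness_env_amp
    if mode == "unimodal":
        w = params.richness_niche_width * sigma
        shape = np.exp(-((om - mu - params.unimodal_optimum_offset * sigma)
                         ** 2) / (2 * w ** 2))
    elif mode == "monotone":
        cproxy = np.exp(0.5 * om)
        c0 = np.exp(0.5 * mu)
        half_range = 4.5 * c0 * 0.5 * sigma
        shape = 0.5 + 0.5 * np.clip((cproxy - c0) / half_range, -1.0, 1.0)
    else:
        raise ValueError(f"unknown richness_env_mode {mode!r}")
    return 1.0 - amp * (1.0 - shape)


def generate_communities(design: SampleFrame, env: SampleFrame,
                         latent_om: pd.Series, params: CommunityParams,
                         seed: int) -> pd.DataFrame:
    """Latent relative-abundance matrix (samples x ASVs, rows sum to 1)."""
    rng = _child_rng(seed, 2)
    df = env.data
    S = params.regional_richness
    asv_ids = [f"ASV{str(i + 1).zfill(len(str(S)))}" for i in range(S)]

    log_sad = rng.normal(params.sad_meanlog, params.sad_sdlog, S)
    niche_opt = rng.normal(0.0, 1.0, S)
    n_excl = int(round(params.frac_bulk_exclusive * S))
    bulk_only = np.zeros(S, dtype=bool)
    if n_excl:
        bulk_only[rng.choice(S, size=n_excl, replace=False)] = True

    levels = {
        "depth": "depth_layer", "plot": "plot_id", "point": "point_id",
        "core": "core_id",
    }
    effects: dict[str, tuple[pd.Index, np.ndarray]] = {}
    for level, col in levels.items():
        units = pd.Index(sorted(df[col].unique()))
        effects[level] = (units, rng.normal(0, params.effect_sd[level],
                                            (len(units), S)))

    agg = df[df["sample_type"] == "aggregate"]
    om = latent_om
    beta = params.env_niche_strength

    eta = np.zeros((len(agg), S))
    for level, col in levels.items():
        units, mat = effects[level]
        idx = units.get_indexer(agg[col])
        eta += mat[idx]
    avail = np.empty(len(agg))
    for depth in dict.fromkeys(agg["depth_layer"]):
        m = (agg["depth_layer"] == depth).to_numpy()
        avail[m] = _availability(om[agg.index].to_numpy()[m],
                                 params.mode_for(depth), params, depth)
    if params.richness_avail_jitter > 0:
        avail = np.clip(avail + rng.normal(0, params.richness_avail_jitter,
                                           len(agg)), 0.05, 1.0)
    eta += log_sad[None, :]
    eta += rng.normal(0, params.effect_sd["aggregate"], (len(agg), S))
    eta -= beta * (om[agg.index].to_numpy()[:, None] - niche_opt[None, :]) ** 2 / 2
    # environmental filtering of the rarer taxa: each aggregate hosts a
    # fraction avail of the filterable pool (dominants are never filtered)
    protected = log_sad >= np.quantile(log_sad,
                                       params.richness_protected_quantile)
    filterable = ~protected & ~bulk_only
    absent = (rng.random((len(agg), S)) >= avail[:, None]) & filterable[None, :]
    eta[absent] = -np.inf
    eta[:, bulk_only] = -np.inf

    eta -= eta.max(axis=1, keepdims=True)
    p_agg = np.exp(eta)
    p_agg /= p_agg.sum(axis=1, keepdims=True)
    latent = pd.DataFrame(p_agg, index=agg.index, columns=asv_ids)

    # bulk = mean of member aggregates + exclusive inter-aggregate habitat taxa
    bulks = df[df["sample_type"] == "bulk"]
    if n_excl:
        excl_comp = np.zeros(S)
        excl_comp[bulk_only] = np.exp(
            rng.normal(params.sad_meanlog, params.sad_sdlog, n_excl))
        excl_comp /= excl_comp.sum()
    bulk_rows = {}
    core_groups = agg.groupby("core_id", observed=True).groups
    for sid, row in bulks.iterrows():
        members = core_groups.get(row["core_id"])
        if members is None or len(members) == 0:
            base = np.full(S, 1.0 / S)
        else:
            base = latent.loc[members].to_numpy().mean(axis=0)
        if n_excl and params.bulk_habitat_weight > 0:
            base = ((1 - params.bulk_habitat_weight) * base
                    + params.bulk_habitat_weight * excl_comp)
        bulk_rows[sid] = base / base.sum()
    if bulk_rows:
        latent = pd.concat([
            latent,
            pd.DataFrame.from_dict(bulk_rows, orient="index", columns=asv_ids),
        ])
    return latent.loc[df.index]


def simulate_reads(latent: pd.DataFrame, seq: SeqParams, seed: int) -> CountTable:
    """Multinomial read sampling at negative-binomial per-sample depths."""
    p = latent.to_numpy(dtype=float)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("latent rows must sum to 1")
    rng = _child_rng(seed, 3)
    k = seq.depth_dispersion
    prob = k / (k + seq.mean_depth)
    depths = rng.negative_binomial(k, prob, size=len(latent))
    depths = np.maximum(depths, seq.min_depth_floor)
    counts = np.empty_like(p, dtype=np.int64)
    for i in range(len(latent)):
        row = p[i] / p[i].sum()
        counts[i] = rng.multinomial(depths[i], row)
    return CountTable(tuple(latent.index), tuple(latent.columns), counts)


def generate_dataset(design_params: DesignParams | None = None,
                     community_params: CommunityParams | None = None,
                     seq_params: SeqParams | None = None,
                     seed: int = 0):
    """Run the full generator chain; returns (counts, samples, latent_om, latent).

    Convenience wrapper used by the pipeline and by tests: design ->
    environment -> latent communities -> read simulation, all derived from
    one seed.
    """
    design_params = design_params or DesignParams()
    community_params = community_params or CommunityParams()
    seq_params = seq_params or SeqParams()
    design = generate_design(design_params, seed)
    env, om = generate_environment(design, community_params, seed)
    latent = generate_communities(design, env, om, community_params, seed)
    counts = simulate_reads(latent, seq_params, seed)
    return counts, env, om, latent


def default_taxonomy(asv_ids, n_phyla: int = 12, seed: int = 0):
    """Assign ASVs to a lognormally-sized set of phyla (for top-taxa tests)."""
    from microagg.iotables import TaxonomyTable

    rng = _child_rng(seed, 4)
    weights = np.exp(rng.normal(0, 1.0, n_phyla))
    weights /= weights.sum()
    names = [f"Phylum{chr(ord('A') + i)}" for i in range(n_phyla)]
    assign = rng.choice(names, size=len(asv_ids), p=weights)
    df = pd.DataFrame({"phylum": assign},
                      index=pd.Index(list(asv_ids), name="asv_id"))
    df.insert(0, "domain", "Bacteria")
    return TaxonomyTable(df)
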