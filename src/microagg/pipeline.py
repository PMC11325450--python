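"""End-to-end orchestration: synthetic generation (or user tables) through
every analysis stage, with deterministic seeded outputs.

Two marker channels (a 16S-like and an ITS-like community, each with its
own rarefaction depth and seed) run independently, mirroring parallel
bacterial/archaeal and fungal analyses.  Every stage writes its result as
TSV under the output directory and the run ends with a machine-readable
``summary.json`` assembled only from those stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from microagg import __version__, iotables
from microagg.constrained import core_dummies, forward_select, pcnm, \
    variation_partition3
from microagg.diversity import accumulation_curve, compare_aggregates_vs_bulk, \
    cumulative_core_richness, rarefy, richness
from microagg.envlink import dissimilarity_regression, richness_env_model, \
    within_core_pair_table, zscore
from microagg.iotables import DEPTH_LAYERS, CountTable, SampleFrame, \
    TaxonomyTable, validate_dataset
from microagg.membership import partition_all_cores, partition_summary, \
    sample_type_overlap
from microagg.ordination import aitchison_distance, clr_transform, \
    distance_decay, pcoa, spatial_distance_categories
from microagg.synthdata import CommunityParams, DesignParams, SeqParams, \
    default_taxonomy, generate_dataset
from microagg.toptaxa import abundance_category_composition

log = logging.getLogger("microagg")

ELEMENTAL_VARS = ("C_pct", "N_pct", "CN_ratio", "d13C_permil", "d15N_permil")
DISSIM_VARS = ELEMENTAL_VARS + ("SWC",)
RICHNESS_VARS = DISSIM_VARS + ("gene_copies",)


@dataclass
class MarkerConfig:
    name: str = "markerA"
    rarefaction_depth: int = 8185
    seed: int = 0


@dataclass
class PipelineConfig:
    """All tunables of a run; every stochastic stage has an explicit seed."""

    markers: list = field(default_factory=lambda: [
        MarkerConfig("markerA", 8185, 11),
        MarkerConfig("markerB", 8195, 12),
    ])
    synth: dict | None = field(default_factory=dict)   # generator overrides
    inputs: dict | None = None     # marker name -> table paths
    n_perm_curves: int = 1000
    n_perm_core: int = 100
    n_perm_tests: int = 999
    pseudocount: float = 1.0
    K: int = 100
    min_frac: float = 0.05
    alpha: float = 0.05
    min_aggregates_core: int = 3
    n_required_partition: int = 4
    seed: int = 0

    def __post_init__(self):
        self.markers = [m if isinstance(m, MarkerConfig) else MarkerConfig(**m)
                        for m in self.markers]
        if self.inputs is None and self.synth is None:
            raise ValueError("config needs an input block or a synth block")
        for name, lo in (("n_perm_curves", 1), ("n_perm_core", 1),
                         ("n_perm_tests", 1), ("K", 1)):
            if getattr(self, name) < lo:
                raise ValueError(f"{name} must be >= {lo}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _synth_params(cfg: PipelineConfig):
    synth = cfg.synth or {}
    return (DesignParams(**synth.get("design", {})),
            CommunityParams(**synth.get("community", {})),
            SeqParams(**synth.get("seq", {})))


def _load_marker(cfg: PipelineConfig, marker: MarkerConfig):
    """Dataset for one marker: synthetic or read from configured paths."""
    if cfg.inputs and marker.name in cfg.inputs:
        paths = cfg.inputs[marker.name]
        counts = iotables.read_count_table(
            paths["counts"], paths.get("orientation", "asvs-as-rows"))
        samples = iotables.read_sample_frame(paths["samples"])
        taxonomy = iotables.read_taxonomy_table(paths["taxonomy"])
    else:
        dp, cp, sp = _synth_params(cfg)
        counts, samples, _, _ = generate_dataset(dp, cp, sp,
                                                 seed=cfg.seed + marker.seed)
        taxonomy = default_taxonomy(counts.asv_ids,
                                    seed=cfg.seed + marker.seed)
    return validate_dataset(counts, samples, taxonomy)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_marker(cfg: PipelineConfig, marker: MarkerConfig, outdir: Path) -> dict:
    """All analysis stages for one marker channel; returns its summary."""
    out = outdir / marker.name
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"rarefaction_depth": marker.rarefaction_depth}
    ds = _load_marker(cfg, marker)
    counts, samples, taxonomy = ds.counts, ds.samples, ds.taxonomy
    meta = samples.data.loc[list(counts.sample_ids)]
    log.info("[%s] %d samples x %d ASVs", marker.name, counts.n_samples,
             counts.n_asvs)

    # --- rarefaction -----------------------------------------------------
    rar = rarefy(counts, marker.rarefaction_depth, seed=cfg.seed + 100)
    summary["n_samples_total"] = counts.n_samples
    summary["n_samples_rarefied"] = rar.counts.n_samples
    summary["n_dropped_rarefaction"] = len(rar.dropped)
    rich = richness(rar.counts)
    rmeta = samples.data.loc[list(rar.counts.sample_ids)]
    _write(rich.rename("richness").rename_axis("sample_id").reset_index(),
           out / "richness.tsv")

    # --- accumulation curves + venn overlap ------------------------------
    acc_rows = []
    for stype in ("aggregate", "bulk"):
        ids = sorted(rmeta.index[rmeta["sample_type"] == stype])
        curve = accumulation_curve(rar.counts, ids,
                                   n_perm=cfg.n_perm_curves,
                                   seed=cfg.seed + 200)
        summary[f"pooled_richness_{stype}"] = int(curve.mean_richness[-1])
        for k, m, lo, hi in zip(curve.k, curve.mean_richness, curve.lower,
                                curve.upper):
            acc_rows.append({"sample_type": stype, "k": int(k),
                             "mean_richness": m, "lower": lo, "upper": hi})
    _write(pd.DataFrame(acc_rows), out / "accumulation_curves.tsv")
    venn = sample_type_overlap(rar.counts, samples)
    summary["venn"] = {"frac_both": venn.frac_both,
                       "frac_only_aggregates": venn.frac_only_a,
                       "frac_only_bulk": venn.frac_only_b,
                       "n_union": venn.n_union}

    # --- per-core cumulative richness vs bulk ----------------------------
    core_curves = cumulative_core_richness(
        rar.counts, samples, n_perm=cfg.n_perm_core,
        min_aggregates=cfg.min_aggregates_core, seed=cfg.seed + 300)
    _write(core_curves, out / "core_accumulation.tsv")
    cmp_rows = []
    for depth in DEPTH_LAYERS:
        bulk_ids = rmeta.index[(rmeta["sample_type"] == "bulk")
                               & (rmeta["depth_layer"] == depth)]
        res = compare_aggregates_vs_bulk(core_curves, rich[bulk_ids], depth)
        cmp_rows.append(res)
        at3 = res[res["k"] == 3]
        if len(at3):
            summary[f"median_cumrichness_3agg_{depth}"] = float(
                at3["median_aggregates"].iloc[0])
            summary[f"median_bulk_richness_{depth}"] = float(
                at3["median_bulk"].iloc[0])
    _write(pd.concat(cmp_rows, ignore_index=True),
           out / "aggregates_vs_bulk.tsv")

    # --- shared/unique partitioning --------------------------------------
    parts = partition_all_cores(rar.counts, samples,
                                n_required=cfg.n_required_partition,
                                seed=cfg.seed + 400)
    psum = partition_summary(parts)
    _write(pd.DataFrame([p.__dict__ for p in parts]),
           out / "core_partitions.tsv")
    _write(psum, out / "partition_summary.tsv")
    summary["partition"] = {
        f"{row.metric}_{row.depth_layer}": row.median
        for row in psum.itertuples()
    }

    # --- ordination & distance decay (non-rarefied) ----------------------
    D = aitchison_distance(counts, cfg.pseudocount)
    ord_res = pcoa(D)
    summary["pcoa_prop_axis1"] = float(ord_res.proportion_explained[0])
    summary["pcoa_prop_axis2"] = float(ord_res.proportion_explained[1])
    coords = pd.DataFrame(ord_res.coordinates[:, :2], index=list(ord_res.ids),
                          columns=["PCo1", "PCo2"])
    coords.index.name = "sample_id"
    coords.reset_index().pipe(_write, out / "pcoa_coordinates.tsv")
    cats = spatial_distance_categories(samples,
                                       sample_ids=list(counts.sample_ids))
    decay = distance_decay(D, cats)
    _write(decay, out / "distance_decay.tsv")
    summary["decay_medians"] = {
        f"{r.depth_layer}_{r.category}_{r.sample_type}": r.median
        for r in decay.itertuples()
    }

    # --- abundance-category composition (non-rarefied) -------------------
    top_rows = []
    for stype in ("aggregate", "bulk"):
        for depth in DEPTH_LAYERS:
            comp = abundance_category_composition(
                counts, taxonomy, samples, stype, depth,
                K=cfg.K, min_frac=cfg.min_frac)
            comp.insert(0, "depth_layer", depth)
            comp.insert(0, "sample_type", stype)
            top_rows.append(comp)
    _write(pd.concat(top_rows, ignore_index=True),
           out / "abundance_categories.tsv")

    # --- variation partitioning (rarefied) -------------------------------
    summary["varpart"] = {}
    vp_rows = []
    for depth in DEPTH_LAYERS:
        agg_ids = sorted(rmeta.index[(rmeta["sample_type"] == "aggregate")
                                     & (rmeta["depth_layer"] == depth)])
        sub = rar.counts.subset_samples(agg_ids)
        smeta = samples.data.loc[agg_ids]
        ok = smeta[list(ELEMENTAL_VARS)].notna().all(axis=1)
        agg_ids = [i for i, o in zip(agg_ids, ok) if o]
        sub = rar.counts.subset_samples(agg_ids)
        smeta = samples.data.loc[agg_ids]
        clr = clr_transform(sub, cfg.pseudocount).to_numpy()
        basis = pcnm(smeta[["x", "y"]].to_numpy(float), ids=agg_ids)
        space = pd.DataFrame(
            basis.eigenvectors, index=agg_ids,
            columns=[f"PCNM{j + 1}" for j in range(basis.eigenvectors.shape[1])])
        space = space.apply(lambda c: zscore(c.to_numpy()))
        elem = pd.DataFrame(
            {v: zscore(smeta[v].to_numpy(float)) for v in ELEMENTAL_VARS},
            index=agg_ids)
        core = core_dummies(smeta["core_id"])
        for resp_name, Y in (("composition", clr),
                             ("richness", rich[agg_ids].to_numpy(float))):
            sel_space = forward_select(Y, space, alpha=cfg.alpha,
                                       n_perm=cfg.n_perm_tests,
                                       seed=cfg.seed + 500)
            sel_elem = forward_select(Y, elem, alpha=cfg.alpha,
                                      n_perm=cfg.n_perm_tests,
                                      seed=cfg.seed + 501)
            vp = variation_partition3(Y, {
                "core": core.to_numpy(),
                "space": space[sel_space].to_numpy() if sel_space else
                    np.empty((len(agg_ids), 0)),
                "elemental": elem[sel_elem].to_numpy() if sel_elem else
                    np.empty((len(agg_ids), 0)),
            })
            key = f"{resp_name}_{depth}"
            summary["varpart"][key] = {
                **{f"individual_{k}": v for k, v in vp.individual.items()},
                "triple": vp.triple, "residual": vp.residual,
                "largest_individual": vp.largest_individual(),
                "selected_space": sel_space, "selected_elemental": sel_elem,
            }
            for k, v in vp.individual.items():
                vp_rows.append({"response": resp_name, "depth_layer": depth,
                                "fraction": f"individual_{k}", "value": v})
            for pair, v in vp.pairwise.items():
                vp_rows.append({"response": resp_name, "depth_layer": depth,
                                "fraction": "joint_" + "_".join(sorted(pair)),
                                "value": v})
            vp_rows.append({"response": resp_name, "depth_layer": depth,
                            "fraction": "triple", "value": vp.triple})
            vp_rows.append({"response": resp_name, "depth_layer": depth,
                            "fraction": "residual", "value": vp.residual})
    _write(pd.DataFrame(vp_rows), out / "variation_partitioning.tsv")

    # --- environment-community regressions -------------------------------
    dis_rows, rich_rows = [], []
    summary["dissim_regressions"] = {}
    summary["richness_models"] = {}
    for depth in DEPTH_LAYERS:
        for var in DISSIM_VARS:
            try:
                pairs = within_core_pair_table(
                    D, samples, var, depth,
                    min_aggregates=cfg.min_aggregates_core)
                reg = dissimilarity_regression(pairs, var, depth)
            except ValueError as e:
                log.warning("dissim %s/%s skipped: %s", depth, var, e)
                continue
            dis_rows.append(reg.__dict__ | {"highlighted": reg.highlighted})
            summary["dissim_regressions"][f"{var}_{depth}"] = {
                "R2": reg.R2, "p": reg.p_value, "n_pairs": reg.n_pairs}
        dmeta = rmeta[(rmeta["sample_type"] == "aggregate")
                      & (rmeta["depth_layer"] == depth)]
        for var in RICHNESS_VARS:
            x = dmeta[var]
            if x.notna().sum() < 5:
                continue
            model = richness_env_model(rich[dmeta.index], x, var, depth,
                                       alpha=cfg.alpha)
            rich_rows.append({
                "predictor": var, "depth_layer": depth,
                "chosen_form": model.chosen_form, "R2": model.R2,
                "AIC_linear": model.AIC_linear,
                "AIC_quadratic": model.AIC_quadratic,
                "F_p": model.F_p, "n": model.n})
            summary["richness_models"][f"{var}_{depth}"] = {
                "form": model.chosen_form, "R2": model.R2}
    _write(pd.DataFrame(dis_rows), out / "dissimilarity_regressions.tsv")
    _write(pd.DataFrame(rich_rows), out / "richness_models.tsv")
    return summary


def run_all(cfg: PipelineConfig, outdir) -> Path:
    """Run every stage for every marker; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    try:
        log.info("microagg %s, seed %d", __version__, cfg.seed)
        settings = dataclasses.asdict(cfg)
        settings["markers"] = [dataclasses.asdict(m) for m in cfg.markers]
        summary = {"version": __version__, "config": settings, "markers": {}}
        for marker in cfg.markers:
            log.info("running marker %s", marker.name)
            summary["markers"][marker.name] = run_marker(cfg, marker, outdir)
        with open(outdir / "summary.json", "w") as out:
            json.dump(summary, out, indent=1, sort_keys=True,
                      default=_jsonable)
            out.write("\n")
    except Exception as e:
        log.error("pipeline failed: %s", e)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir


def _jsonable(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
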