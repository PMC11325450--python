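# microagg

Millimetre-scale soil microbiome analysis: do individual ~2-mm soil
aggregates host microbial communities that differ from what a homogenized
bulk soil sample shows?

Soil microbial ecology conventionally sequences grams of sieved soil, which
averages over thousands of microhabitats. `microagg` implements the
complete statistical workflow for studies that instead sequence individual
soil aggregates alongside the bulk samples of their parent soil cores:

- **Diversity** — rarefaction to a common read depth, permutation species
  accumulation curves, cumulative per-core aggregate richness vs bulk
  richness with rank-sum tests.
- **Membership** — shared/unique ASV partitioning among the four
  aggregates of a parent core, and the aggregate-vs-bulk detection Venn.
- **Ordination** — centred-log-ratio (CLR) transform, Aitchison distances,
  PCoA, and distance decay of community similarity over ordered spatial
  categories (same core → adjacent cores → 1 m → … → 50–60 m).
- **Top taxa** — phylum composition of cumulative abundance categories
  (the k most abundant ASVs per sample, k = 1…100).
- **Constrained analysis** — PCNM spatial eigenfunctions, (partial) RDA
  with Ezekiel-adjusted R², permutation forward selection, and three-set
  variation partitioning (parent-core membership / space / elemental
  composition).
- **Environment links** — within-core dissimilarity–environment
  regressions and linear-vs-quadratic richness–environment model selection
  (nested ANOVA + AIC).
- **Synthetic data** — a hierarchical metacommunity generator with the
  field sampling design (5 plots on an 11 × 65 m slope, 2 points/plot,
  2 cores/point per depth, 5 aggregates + 1 bulk per core → 190 + 40
  samples), nested beta-diversity, a long tail of rare taxa, and
  organic-matter coupling to composition and richness, so every stage runs
  with known ground truth.

The statistical core in brief: community dissimilarity is the Aitchison
distance ‖clr(x) − clr(y)‖₂ with clr(x)ᵢ = log xᵢ − (1/D)Σⱼ log xⱼ on
pseudocounted counts; explained variation is R²adj = 1 − (1 − R²)(n − 1)/
(n − p − 1) decomposed over predictor sets by inclusion–exclusion; and the
richness–environment response is chosen between y = a + bx and
y = a + bx + cx² by the nested F-test and AIC jointly.

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.

## Worked example

```python
from microagg.synthdata import generate_dataset
from microagg.diversity import (rarefy, richness, cumulative_core_richness,
                                compare_aggregates_vs_bulk)
from microagg.membership import partition_all_cores, partition_summary

counts, samples, om, latent = generate_dataset(seed=42)
rar = rarefy(counts, depth=8185, seed=42)
rich = richness(rar.counts)

curves = cumulative_core_richness(rar.counts, samples, n_perm=100, seed=42)
meta = samples.data.loc[list(rar.counts.sample_ids)]
bulk_top = rich[meta.index[(meta.sample_type == "bulk")
                           & (meta.depth_layer == "top")]]
cmp = compare_aggregates_vs_bulk(curves, bulk_top, "top")
row = cmp[cmp.k == 3].iloc[0]
print(f"k=3 aggregates: median cumulative richness {row.median_aggregates:.0f} "
      f"vs bulk {row.median_bulk:.0f} (rank-sum p = {row.p_value:.2e})")

parts = partition_all_cores(rar.counts, samples, n_required=4, seed=42)
s = partition_summary(parts).set_index(["depth_layer", "metric"])["median"]
print(f"shared among 4 aggregates: {100*s['top','frac_shared_asvs']:.0f}% of "
      f"ASVs, {100*s['top','abund_frac_shared']:.0f}% of reads")
```

prints

```
k=3 aggregates: median cumulative richness 1178 vs bulk 898 (rank-sum p = 6.80e-08)
shared among 4 aggregates: 44% of ASVs, 85% of reads
```

Three aggregates of one core already reveal more ASVs than the whole
homogenized core's bulk sample — pooling small communities beats averaging
them — while the taxa shared by all four aggregates of a core carry 85 %
of each community's reads: aggregates agree on the dominant taxa and
differ in the rare ones.

## Command line

```bash
microagg simulate --outdir sim/            # write synthetic TSV tables
microagg run --outdir out/ --seed 1        # full pipeline, both markers
microagg stage markerA --outdir out/       # one marker channel only
```

`--config pipeline.yaml` overrides any default (rarefaction depths,
permutation counts, generator parameters, spatial bin edges); every stage
writes its result as TSV under the output directory and the run ends with
a machine-readable `summary.json`.

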