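# Methods

`microagg` re-implements, as a tested pipeline, the statistical workflow
used to compare microbial communities of individual ~2-mm soil aggregates
with homogenized bulk soil samples, together with a hierarchical
metacommunity simulator so that every stage can be exercised and verified
without sequencing data.

## The analyses

**Rarefaction and richness.** Richness analyses run on a rarefied count
table: every sample is subsampled without replacement to a common depth
(defaults 8185 reads for the 16S-like channel, 8195 for the ITS-like
channel), samples below the depth are dropped and reported. Rarefaction is
a single seeded draw per sample — one rarefied dataset per run, as in
standard practice — while tests validate the subsampler against the exact
hypergeometric expectation E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d)).

**Species accumulation.** Curves add samples in random order and average
the cumulative unique-ASV count over permutations (1000 for whole-group
curves, 100 for per-core curves). The uncertainty band is the empirical
2.5 %/97.5 % quantile across permutations; a quantile band was chosen over
±1.96·sd because permutation curves are bounded and skewed near
saturation. Per-core cumulative richness at k aggregates is compared
against single-bulk richness with a two-sided Mann–Whitney U test (exact
null for untied samples with n₁, n₂ ≤ 8, tie-corrected normal
approximation otherwise).

**Shared/unique partitioning.** For four aggregates of one parent core
(a seeded random four if five are available), an ASV is *unique* if
present in exactly one aggregate and *shared* if present in all four;
fractions are per-aggregate shares (of that community's ASVs, and of its
reads) averaged over the four. The intermediate class (present in 2–3) is
reported so the three classes sum to one exactly — an audit the tests
enforce.

**Compositional ordination.** Community dissimilarity is the Aitchison
distance: Euclidean distance between centred-log-ratio rows of counts + 1
pseudocount. A unit pseudocount on raw counts was chosen for zero
replacement because it is simple, reproducible, and leaves the transform
exactly invertible in tests; composition analyses consume the non-rarefied
table, so the pseudocount acts on raw counts. PCoA is the eigendecomposition
of the Gower-centred −D²/2; on an Aitchison matrix it is exactly PCA of
the CLR matrix, and the tests assert eigenvalue agreement to 1e-8. Axis
signs are fixed by making the largest-magnitude loading positive.

**Distance decay.** Same-depth, same-type sample pairs are grouped into
ordered spatial categories: same parent core (spsc), adjacent cores of one
sampling point (apsc), then metric bins (≤5 m labelled "1m", 5–20 m
"10-20m", then 10-m bins to 60 m). The unlabelled 5–10 m gap in the field
design is closed by extending the 10–20 m bin down to >5 m; edges are
configurable. Per category the median and the standard deviation of the
pairwise dissimilarities are reported (the sd of pairwise values, not a
bootstrap sd of the median), plus an aggregate-vs-bulk rank-sum test.

**Abundance-category composition.** Within each sample ASVs get dense
ranks by decreasing relative abundance (ties broken by identifier);
category k pools every sample's ASVs of rank ≤ k and reports the
per-phylum share of pooled sample-ASV *incidences* — an ASV in ten
samples' top-k counts ten times. Multiplicity pooling is the default
because the statistic describes "the k most abundant ASVs of all samples";
a union-of-unique-ASVs variant is available via `pooling="union"` for
sensitivity analysis. Phyla under 5 % of a category are collapsed into a
"<5%" class, independently per category.

**Variation partitioning.** The variability of aggregate communities is
decomposed over three predictor sets: parent-core membership
(reference-cell dummy coding), space (PCNM eigenfunctions of the aggregate
coordinates, truncation at the longest minimum-spanning-tree edge,
distances beyond it replaced by 4× truncation, positive-eigenvalue axes
only — verified against vegan's construction), and elemental composition
(z-scored C, N, C:N, δ¹³C, δ¹⁵N). PCNM axes and elemental variables are
forward-selected with the double stopping rule: a candidate enters only if
its Freedman–Lane permutation p ≤ α and the cumulative adjusted R² stays
at or below the full candidate model's. Adjusted R² (Ezekiel) is computed
for all seven set unions and decomposed by inclusion–exclusion into
individual, pairwise-joint and triple-joint fractions; fractions may be
negative on the adjusted scale and are stored raw (display layers
conventionally truncate at 0 and hide values ≤ 0.9 %). The community
response is the CLR of the *rarefied* table — this makes RDA the
Euclidean-embedding equivalent of db-RDA on Aitchison distances and keeps
the varpart input consistent with the richness response (rarefied ASV
counts). Partitioning runs per depth layer.

**Environment–community regressions.** Within-core regressions pool
same-core aggregate pairs across cores within a depth layer (cores with
<3 aggregates excluded) and fit plain OLS of community dissimilarity on
|Δz| of one z-scored variable (z-scoring within depth layer, since the
analysis is stratified by depth). Richness–environment model selection
fits linear and quadratic polynomials and keeps the quadratic only when
the nested F-test p ≤ 0.05 *and* its AIC is lower. Fits run on an
internally standardized predictor (gene-copy densities reach 1e9 and
their square would dominate float64 least squares); coefficients are
mapped back to the data scale.

## The synthetic generator

The generator reproduces the study design: 5 plots across an 11 × 65 m
slope, two sampling points ~1 m apart per plot, two parent cores a few
centimetres apart per point and depth layer (0–5 cm "top", 15–20 cm
"deep"), five aggregates plus one bulk sample per core; a 5 % aggregate
dropout yields the field sample sizes of 190 aggregates and 40 bulk
samples.

*Environment.* A latent organic-matter (OM) axis per core and aggregate
(depth contrast + core effect + aggregate noise; top layer has higher mean
and variance) drives all measured variables: C and N increase with OM with
correlated noise (C:N ≈ 15, mildly decreasing in OM), δ¹³C and δ¹⁵N
decrease with OM (recycled OM in the OM-poor deep layer is isotopically
enriched), water content and gene-copy density increase with OM.

*Communities.* Log abundances are a regional lognormal
species-abundance distribution (S = 2000, sdlog = 1.6) plus independent
Gaussian effects at each hierarchy level (multiplicative on abundance:
depth 1.0, plot 0.45, point 0.25, core 0.5, aggregate 0.7 on the log
scale) plus a Gaussian-niche shift along OM (strength 0.35). This yields
the nested beta-diversity ordering (same-core pairs most similar,
between-plot pairs least) and a long tail of rare taxa heterogeneous at
the aggregate scale. Bulk composition is the mean of the core's aggregate
compositions mixed with 5 % of a bulk-only habitat component carried by
3 % of taxa — aggregate-exclusive taxa arise from sampling, bulk-exclusive
taxa from habitats 2-mm aggregates never contain.

*Richness response.* Each aggregate hosts a fraction π(OM) of the rarer
taxa (the top quartile of the abundance distribution is never filtered):
environmental filtering with more niches in OM-richer aggregates. π is
unimodal in OM for the top layer and linear in the noise-free carbon
proxy exp(OM/2) for the deep layer (per-layer configurable), with an
independent per-aggregate jitter (sd 0.12). Linearity in the carbon proxy
was chosen so the *expected* richness–C relationship is linear by
construction in the monotone mode; an earlier evenness-tilt mechanism left
systematic curvature that a nested F-test at n ≈ 95 reliably detects,
which would misrepresent a monotone ecology as a unimodal one.

*Sequencing.* Per-sample depths are negative-binomial (mean 20 000,
dispersion 12, floor 500), placing ~2 % of samples below the ~8 200-read
rarefaction depths so the sample-dropping path is exercised; counts are
multinomial given depth and latent proportions.

*What the generator does not emulate.* No sequence-level error or chimera
structure, no phylogenetic correlation of niches, no taxon–taxon
interactions, and no mechanistic aggregate formation. Within-core
environmental gradients are mostly aggregate-level noise, so within-core
dissimilarity regressions on default synthetic data are weak (R² ≈ 0.02)
— much weaker than a field study can show; strengthening the niche
coupling enough to reproduce such values makes community similarity track
OM rather than distance and destroys the distance-decay ordering, so the
default favours the spatial structure. Passing tests therefore demonstrate
the machinery and its orderings, not field effect sizes.

## Numerical choices

- Rank ties (abundance categories) break lexicographically by ASV id;
  ordering ties elsewhere break by sorted identifier.
- PCoA/PCNM eigenvalue positivity threshold scales with the largest
  eigenvalue; eigenvector signs are fixed deterministically.
- Collinear predictor columns are dropped via QR with a relative 1e-9
  pivot threshold; adjusted R² uses the post-drop rank.
- Exact rank-sum p-values switch to the tie-corrected normal approximation
  when ties are present or either group exceeds 8.
- Degenerate inputs (constant predictors, zero-variance responses,
  all-zero samples, cores below the aggregate threshold) raise errors or
  are excluded and reported, never silently imputed.
- All randomness flows through per-stage `numpy` Generators seeded from
  the run seed; repeated runs are byte-identical.

## Problem sizes

The default run analyses two marker channels of 230 samples × 2000 ASVs
with 1000-permutation accumulation curves, 100-permutation per-core
curves and 999-permutation forward selection; it completes in about a
minute per channel on one CPU. Tests use smaller regional pools
(150–400 taxa) where the property under test does not depend on pool
size.
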