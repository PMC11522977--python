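# Methods

cutinet implements a two-pipeline association analysis between a seedling
transcriptome and two cuticle metabolome fractions (solvent-extractable
cuticular waxes and depolymerized lipidized-cell-wall (LCW) monomers),
followed by their integration into weighted co-expression gene networks.
This note records the statistical models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical decisions that a maintainer would otherwise have to reverse-engineer.

## Study design and data model

All stages assume a balanced factorial design: organs × genotypes ×
replicates (default 6 × 4 × 3 = 72 samples), with expression as a
genes × samples FPKM matrix and each metabolome fraction as a
metabolites × samples concentration matrix sharing the same samples.
Genes are analyzed if expressed (FPKM > 0) in strictly more than half of
the samples. Standardization is per feature to mean 0 and unit sample
variance (n−1 denominator, matching R's `scale()`), and features with zero
variance are dropped with a warning rather than erroring, because
permutation replicates can create constants.

## Metabolome statistics

**Variance partitioning** uses sequential (type-I) ANOVA in the order
genotype → organ → genotype×organ; partial R² is each term's sequential sum
of squares over the total. In a balanced design the factors are orthogonal,
so the order is immaterial (this is tested). Class-level analyses sum the
member metabolite concentrations per sample before the ANOVA. Under a null
response the expected shares are degrees-of-freedom ratios (residual
48/71 for the 4 × 6 × 3 design), which is what the null tests assert.

**Tukey HSD letters** come from all-pairs studentized-range tests followed
by an insert-and-absorb compact letter display; ties are broken by group
order so the output is deterministic.

**Embeddings.** PCA keeps all components (SVD; deterministic sign
convention). tSNE embeds the samples in 2-D from the full PC score matrix
using the exact gradient, PCA initialization, perplexity 10 (n = 72) and
1000 iterations, with the seed recorded in the output header; fixed seed ⇒
identical scores. The tSNE coordinates serve downstream as single-value
response variables, so reproducibility matters more than embedding polish.

## Co-expression modules

The network is unsigned: adjacency = |bicor|^β with β = 16. Biweight
midcorrelation uses median/MAD weights truncated at 9 MADs, with a
Pearson-style fallback for zero-MAD features. The topological overlap
matrix (TOM) is

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with unit diagonal; genes are clustered by average linkage on 1 − TOM.

**Branch cut.** The dendrogram is cut at the 5th-percentile height plus
99% of the remaining height range; every resulting branch with at least
`min_module_size` (default 30) genes is then validated against a
random-matrix null: the branch becomes a module only if its eigengene
explains at least `deep_split`-times-scaled multiples (default 2.5×) of the
Marchenko–Pastur leading-eigenvalue fraction (1 + √(m/n))²/m expected for
an iid block of the same shape. This validation replaces the dynamic
hybrid tree cut: at β = 16 TOM dissimilarities compress into a sliver
below 1, which erases the absolute branch-height geometry that gap-based
criteria rely on, whereas the eigengene criterion is invariant to that
compression. On correlation-free data essentially every gene stays
unclustered; planted modules with within-module r ≈ 0.6–0.8 are recovered
with adjusted Rand index ≥ 0.9.

Modules whose eigengenes correlate above 1 − `merge_cut_height`
(default 0.25) are merged iteratively, labels are reassigned by decreasing
size, and eigengenes (first right singular vector of the standardized
member block, unit norm, sign fixed so the mean member correlation is
nonnegative) are grouped into classes by average-linkage clustering of
1 − r cut at r = 0.5 (strictly greater than).

**Hub genes** must satisfy three criteria inside their module:
(i) intramodular connectivity (within-module TOM row sum) strictly above
the module mean (with a 1e−12 relative float guard so identical profiles
never qualify); (ii) |cor(gene, eigengene)| > 0.8; (iii) maximum |cor|
with any metabolome tSNE component above a per-module cutoff chosen from
the grid 0.05, 0.10, …, 0.95 to bring the hub fraction closest to 5%
(ties toward the larger cutoff).

## Cluster-to-metabolome association (leave-one-covariate-out forests)

A random-forest regression predicts each tSNE component of each fraction
from the module eigengenes plus individually tested unclustered genes
(capped at `max_loco_genes`, default 30, most-variable first — testing
thousands of noise genes costs one forest refit each). For every predictor
a reduced forest is refit without it; performance is compared on
out-of-bag predictions (no extra data split at n = 72) through three
metrics: predictive R² (1 − SSE/TSS), RMSE, and MAPE with an
ε = 1e−8·max|y| denominator guard because tSNE coordinates pass near zero.

Two details are essential and easy to get wrong:

* the reduced forest reuses the **absolute** feature-subset size
  (⌈p/3⌉ computed from the full model); letting `max_features` shrink with
  p handicaps every reduced fit and makes all predictors look important;
* the paired bootstrap (same resample indices for full and reduced OOB
  errors; p = (1 + #{Δ* ≤ 0})/(n_boot + 1), one-sided toward degradation)
  is BH-corrected across predictors, so its resolution floor
  p_min·n_predictors must sit below α = 0.01; the default n_boot = 4000
  (vectorized) guarantees that for up to ~40 predictors.

A predictor is associated with a fraction when at least two of the three
metrics are significant (BH q < 0.01) for at least one tSNE component;
predictors associated with both fractions are labeled "both".

## Gene-to-metabolite association

Genes are stratified by mean FPKM across samples: > 100 (strictly) is the
highly expressed stratum analyzed by multi-response PLS; the rest form the
low stratum analyzed by sparse PLS and the randomized-GLM ensemble. The
boundary value 100 goes to the low stratum.

**PLS/sPLS.** NIPALS PLS2 with per-component deflation of X and Y; the
component count is chosen by 5-fold cross-validated Y prediction error
over 1…10 (fixed fold seed). sPLS soft-thresholds each X-weight vector so
exactly `keep_per_component` (default ⌈0.1·p⌉) genes stay active, then
renormalizes. The importance score is VIP,

    S_j = sqrt( p · Σ_a SSY_a w_aj² / Σ_a SSY_a ),

whose squared values average exactly 1 over genes — this grounds the S > 1
selection convention and has a useful side effect: when strong true
signals absorb VIP mass, null genes deflate below their permutation-null
distribution, which is what keeps the false-discovery proportion down.

**rGLM.** n_bags bootstrap bags (default 500), each drawing a random
candidate subset of ⌈0.2·p⌉ genes and growing a forward-selected linear
model under AIC, capped at 5 terms. S is the selection count normalized to
mean 1. The 5-term cap is load-bearing: with looser caps every bag fills
its quota on permuted data too, the total selection count stops
distinguishing signal from null, and the mean-1 normalization loses its
deflation property. The response is the leading tSNE component of the
fraction — the single-value summary of the dominant metabolome variation.

**Permutation calibration.** The sample order of the response block is
permuted jointly (n_perm = 199 by default), all scores are recomputed, and
the null pool is shared across genes within a model/stratum/fraction
(standardized genes are exchangeable under the null; per-gene pools at
199 permutations cannot resolve p < 0.01). p = (1 + #{S_B ≥ S})/(1 + pool).
A gene is putative for a fraction when S > 1 and p < 0.01 under any of the
three models (union rule). On global-null data each model's p < 0.01 rate
sits at ~1% by construction.

## Integration and enrichment

Putative genes split into lcw-only / wax-only / both categories; a gene
becomes a network node only if its module was selected by the cluster-RF
stage for the matching fraction(s) (both categories require both).
Edges join within-module node pairs whose TOM reaches the 95th percentile
of that module's full within-module TOM distribution (ties included).
Enrichment is a one-sided hypergeometric (Fisher) test per annotation term
with at least 3 background genes, BH-corrected; the background is the set
of genes surviving the expression filter, not a whole genome.

## The synthetic-data generator

The generator emulates: the 72-sample factorial design; organ-dominant
metabolome variance (wax defaults give class-level organ partial R² of
roughly 45–88% with genotype below 10%; LCW defaults give organ 16–65%,
genotype 12–35%, interaction 11–23%); planted co-expression modules driven
by mutually orthogonalized organ signatures (optionally genotype-modulated)
with replicate-level variation; an FPKM-like scale via 10^(μ_g + 0.3·core)
with lognormal baselines so the > 100 FPKM stratum holds ~10–15% of genes;
sporadically detected (zero-inflated) background genes to exercise the
expression filter; and planted gene→metabolite links as standardized
slopes. Associated genes are organized into small co-regulated groups
(default 10 genes sharing 60–85% latent variance, inside or outside
modules): a shared low-rank program is what multivariate models can
legitimately detect, whereas dozens of mutually independent single-gene
links exceed the rank a 10-component PLS or a 2-D tSNE can represent and
are unrecoverable by the method itself, not by any implementation.

It does **not** emulate read counts, chain-length homolog structure,
missing-not-at-random metabolite detection, library-size artifacts, or
realistic gene identifiers. Passing recovery tests therefore demonstrates
that the pipeline's statistics behave as designed under the stated
generative model, not that real tissue data will yield comparable
sensitivity.

Benchmark presets (frozen):

* `null_config` — no modules, no organ signal on expression, no links;
  X ⫫ Y by construction, used for type-I calibration.
* `association_benchmark_config` — 40 planted genes per fraction among
  2000, in groups of 10 outside any module, slopes 2.2 over 3 metabolites
  each, weak organ structure; measures union sensitivity and FDP.
* `network_benchmark_config` — one 300-gene module hosting 20 lcw-only,
  20 wax-only and 20 both-fraction genes as sub-groups (slopes 3.0).
  A single associated module is planted deliberately: the cluster stage
  regresses 2-D tSNE coordinates, which can only carry the dominant
  structure axes, so with several competing modules the weakest one loses
  its embedding footprint and its selection becomes a property of the
  embedding, not of the method. Multi-module recovery is assessed
  separately on the default configuration.

Benchmark problem sizes (2000 genes, 199 permutations, 100–150 bags,
150–800 trees, 10–20 seeds per study) were chosen so each study completes
in minutes on a laptop core while keeping every threshold resolvable.

## Determinism

Every stochastic stage consumes an explicit seed derived from a single
top-level seed via `numpy.random.SeedSequence` spawning; forests and tSNE
run single-threaded with fixed random states; tables are serialized with
shortest-round-trip float reprs. Two runs with the same config are
byte-identical (wall-clock timings go to the log, which is excluded from
that guarantee; the manifest holds only config, version, checksums and
counts).

## Known limitations

* The dynamic-cut replacement validates whole flat-cut branches; it does
  not re-assign borderline genes (no PAM stage), so module boundaries are
  slightly conservative.
* LOCO importance under predictor redundancy under-credits each copy;
  correlated eigengenes can mask each other (mitigated in the generator by
  replicate-level latent variation, unavoidable on real data).
* MAPE on near-zero responses is guard-railed, not meaningful; selection
  effectively rests on R²/RMSE plus one wobbly metric, which the
  two-of-three rule tolerates.
* The enrichment stage is a flat Fisher test; no ontology-graph
  propagation or redundancy trimming.
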