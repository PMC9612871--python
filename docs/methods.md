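# Methods

This note documents the statistical models implemented in `gliaxis`, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions that matter
for reproducing results.

## Single-cell differential expression

Counts are library-size normalized and shifted-log transformed,
`x → ln(1 + x · s / total)`, with scale factor `s = 10⁴` (the convention for
droplet data); the sparsity pattern is preserved. Genes detected in fewer
than `min_cells` cells (default 100 at data scale) are removed first.

Each condition is compared to the untreated control separately within every
donor. The test is the two-sided Wilcoxon rank-sum with mid-ranks, the
tie-corrected variance and a 0.5 continuity correction; when both groups
have at most 8 cells the p-value is instead computed by exhaustive
enumeration of all rank assignments, using the symmetric deviation
|R − E[R]| as the two-sided criterion (this reduces to the classical
doubled tail for tie-free data). The log fold change is computed on the
de-logged mean scale with a pseudo-count of 1,
`ln[(mean expm1(a) + 1)/(mean expm1(b) + 1)]`, which keeps fold changes
bounded when one group is all-zero.

Before testing, a per-donor inclusion filter requires detection in ≥ 10 %
of cells in at least one group and |logfc| ≥ 0.25 (both configurable).
Widely used DE front-ends apply such defaults silently; exposing them keeps
the DEG counts interpretable. **Note for calibration studies:** the logfc
pre-filter selects on the effect estimate and therefore inflates the
apparent hit rate among *tested* genes under the null; type-I-error checks
must disable both filters, as the calibration tests here do.

Per-donor p-values are combined with Tippett's minimum-p method,
`p_comb = 1 − (1 − min p)^k` (numerically via `expm1`/`log1p`). Donors
lacking cells on either side of a comparison are dropped and `k` shrinks
accordingly; genes surviving the filter in no donor are absent from the
output. DEGs are genes with `p_comb` strictly below α = 0.05.

Pseudo-bulk profiles are arithmetic means of normalized expression over all
cells sharing a metadata key combination (donor × treatment, subtype,
genotype, age, sex, …), with member counts recorded. Exclusion of
contaminating populations (fibroblast-like, proliferating) is expected as
input metadata; clustering is out of scope.

## Overlap statistics

The hypergeometric upper tail `P(X ≥ k)` is summed in natural-log space
from log-gamma pmf terms with log-sum-exp, so any positive tail probability
is representable (the pipeline's own headline values are of order 10⁻¹⁰¹
and e⁻¹⁰⁰⁸). All internal storage is in log space; linear-scale values are
derived for display only. The test is one-sided (enrichment). Reported
log values are natural logs. Benjamini–Hochberg adjustment (statsmodels'
step-up implementation) is applied per comparison table — the caller
defines the family. Jaccard = k/(K + n − k).

## PPI network tests

Edge lists from any number of sources are unioned into one undirected
graph; identifiers are optionally mapped (unmappable rows skipped and
counted), self-loops dropped, duplicate and reversed pairs collapsed.
Within-set connectivity counts edges with both endpoints in the set;
between-set connectivity counts edges with one endpoint in each, and an
edge inside the intersection of the two sets counts once.

The null model draws gene sets matched to the query on the joint
distribution of node degree and CDS length: the background is stratified
into joint quantile bins (default 10 × 10 deciles), and each random set
draws, without replacement within each bin, exactly the query's bin counts
— the joint histogram is preserved exactly, by construction, for every
draw. Degree is computed on the network restricted to the background, so
the matching covariate lives in the tested universe. Under-supplied bins
merge with their nearest neighbour (logged) before sampling. In between
mode only the query side is randomized; the target set is a fixed
reference. The empirical p is `(r + 1)/(n_rand + 1)` with `r` the number of
null draws at least as extreme — never zero — and `r = 0` additionally
reports the conventional bound `p < 1/n_rand` (10,000 randomizations →
"< 0.0001"; 100,000 → "< 1 × 10⁻⁵").

## Batch correction and the disease axis

Count-mode datasets are filtered (genes with total < 20 across samples
removed) and stabilized by log2(x + 1). The stabilization is deliberately
simple: upstream per-dataset transforms (regularized log for RNA-seq, RMA
for arrays) belong to dataset-specific preprocessing, and the axis
machinery is agnostic to the exact transform as long as values are on a
roughly variance-stabilized scale — the generator emits post-transform
values directly.

Batch correction is the parametric empirical-Bayes location–scale
algorithm: (1) gene-wise standardization against a batch-design fit (grand
mean = sample-size-weighted batch means; pooled variance = mean squared
residual); (2) per-batch per-gene location (γ̂) and scale (δ̂², ddof = 1)
estimates on the standardized data; (3) method-of-moments hyperpriors per
batch — normal on location, inverse-gamma on scale; (4) the standard
iterative solution for the shrunken γ*, δ²* (convergence 10⁻⁶); (5)
adjusted data = pooled_sd · (Z − γ*)/√δ²* + grand mean. The implementation
agrees with scanpy's ComBat to ~10⁻³ (the residual is iteration
tolerance). No group covariates are protected: protecting the biological
grouping would leak the labels that the axis is later read from. A single
batch passes through unchanged (warned); genes with zero variance inside a
batch are dropped (logged) because their scale effect is unidentifiable;
exactly collinear scale estimates across genes fall back to the no-shrinkage
limit via a floored prior variance.

PCA runs on per-gene-centered, *unscaled* data (variance scaling changes
loadings materially and the default-configured PCA of standard statistical
environments does not scale). The axis is the first component, sign-fixed
so the disease-group mean score exceeds the reference mean; the loading
vector is unit-norm, and training means, per-component variance fractions
and orientation metadata are frozen with it.

**Projection.** A new dataset is corrected along with the training datasets
(one extra batch), its corrected block is per-gene centered, and the
centered values are multiplied by the frozen PC1 loadings restricted to the
shared genes — no renormalization of the loading sub-vector, and the shared
count is always reported so users can judge coverage (a projection needs at
least 50 % of axis genes by default). Centering uses the projected
dataset's own per-gene means by default; `center_on="train"` uses the
training means instead. Both are defensible readings of "center the
corrected data of the dataset to be projected"; self-centering is the
default and makes projected scores translation-invariant per dataset, so
cross-dataset comparisons should rely on within-dataset contrasts. For a
dataset that *is* one of the training batches, correcting it "along with
the rest" is exactly the fit-time correction, so the fitted block is reused
— this makes training projections reproduce their PC1 scores to machine
precision (up to the per-dataset recentering). A dataset constant across
samples projects to all-zero scores without a correction run (any per-gene
affine correction centers to zero).

**Axis-level tests.** Window enrichment ranks axis genes by loading
(ascending for the "lowest" end), intersects with the background, and
tests windows of 50–1000 genes in steps of 50 with the log-space
hypergeometric tail, BH-adjusted across the windows of the call. The rank
randomization test ranks all projected samples (average ranks on ties),
takes the mean rank of the query samples, and compares it to the mean ranks
of uniformly drawn same-size subsets (default 100,000); p = (r + 1)/(n + 1)
with r counting draws at least as high.

## Synthetic data: what it emulates, and what it does not

All generators derive their streams from one global seed through fixed
per-stage offsets, so identical (config, seed) reproduce bit-identical
outputs and stages can be re-run independently.

**Multi-study datasets.** Sample value = scale·(baseline + 1{disease} ·
effect · axis + location) + Gaussian noise, with a unit-norm random axis,
per-batch per-gene locations N(0, sd = 2) and log-normal scales (log-sd
0.1). Defaults: 2000 genes, 7 datasets (mirroring a seven-study
meta-analysis), 10 samples each, noise sd 1. The default group effect is
60 in projected-separation units, i.e. a per-gene shift of
60/√2000 ≈ 1.3 against unit noise — the "large and small shifts across a
great many genes" regime the axis is designed for. The value was fixed by a
spiked-covariance power calculation: PC1 recovery requires the spike
strength (effect²/4 per unit noise variance) to clear √(p/n) ≈ 5.3 by a
wide margin; at effect 60 the predicted loading cosine is ≈ 0.98, and a
projected separation of order 1 (however desirable as a "small effect"
condition) is mathematically undetectable by PCA at these dimensions.

**Single-cell counts.** Negative binomial with variance μ + μ²·φ
(φ = 0.3), means = library size (uniform 1000–5000) × softmax-normalized
gene propensities, per-donor logit shifts (sd 0.15), and planted responder
genes whose logits move by ±ln 2 in every non-control condition. Defaults
mirror an 8-condition × 4-donor × 200-cells design. The generator does not
emulate read-level artefacts, UMI collapsing, ambient RNA or doublets —
passing tests say nothing about those failure modes; nor does it emulate
per-condition heterogeneous effects, so recall numbers reflect a shared
response.

**Networks.** Chung–Lu expected-degree graphs with Pareto weights (tail
exponent 2.5, mean degree ≈ 8 before probability capping), log-normal CDS
lengths (log-mean 7.7, log-sd 0.6 → median ≈ 2.2 kb), optional planted
edges added verbatim, isolated genes kept as nodes so backgrounds cover the
universe.

**Annotations.** Orthologue tables with an exact 1:1 fraction (rest half
dropped, half duplicated to emulate many-to-many), and gene sets including
a GWAS-like set whose members can be biased toward the low-loading end of a
supplied axis (sampling weights exp(−corr · z(axis))).

## Calibration and problem sizes

The statistical acceptance tests run at sizes chosen for a laptop-scale
suite: null DEG calibration pools 200 replicate two-donor experiments
(60 genes, 40 cells/condition) and checks the hit rate against the binomial
99 % CI of α; randomization-test calibration uses 200 replicates with
n_rand ≈ 200–500 and a KS test at 0.01. The PPI calibration deliberately
uses a denser network and a larger query (mean within-set count ~10²)
because with sparse sets the integer count statistic ties so heavily that
the empirical p is visibly conservative and a continuous-uniform KS check
is not meaningful — a known property of discrete permutation tests, not an
implementation artefact. Axis recovery runs 20 seeds of the default
generator config and requires median loading cosine ≥ 0.95 with correction
and < 0.5 without.

## Known limitations

- The conserved-DE pre-filters make printed DEG counts depend on unstated
  tool defaults; absolute counts are not comparable across implementations.
- BH families are defined per call; the package does not decide family
  boundaries across analyses.
- The matched-null bin-merge strategy (nearest neighbouring joint bin) is
  one of several defensible schemes; results on real data depend on the
  binning resolution, which is exposed as a parameter.
- Projected scores are translation-invariant per dataset under the default
  self-centering; only within-dataset contrasts (and ranks) are
  scale-meaningful.
- The empirical-Bayes correction assumes the location–scale batch model;
  batch effects interacting with biology (group × batch) are not removed
  and will distort the axis.
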