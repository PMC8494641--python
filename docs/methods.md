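# Methods

This note documents the statistical procedures implemented in
`methylatlas`, the choices made where the design was genuinely open, what
the synthetic-data generator does and does not emulate, and the problem
sizes the test suite runs at.

## Counts, coordinates and quality control

Base-level input is the ALLC table (chrom, 1-based position, strand,
trinucleotide context, mc, cov, indicator).  Internally every interval is
BED-style 0-based half-open; ALLC positions are converted on read.  CpG
strand pairs can be summed on read (the − strand record at p+1 merges into
the + strand record at p).  Contexts are classed as CG (C followed by G)
or CH, with CCC tracked separately because the global mCCC fraction bounds
the bisulfite non-conversion rate; CCC is excluded from the CH class used
for clustering unless requested otherwise.

Cell filters (all strict inequalities): mCCC < 0.03, mCG > 0.5,
mCH < 0.2, final reads > 500,000, mapping rate > 0.5.  Feature filters
keep 100-kb bins whose mean total basecalls lie in the closed interval
[250, 3000] — the published rule states the *exclusion* bounds ("<250 or
>3,000"), so both endpoints are kept — and which overlap no blacklist
interval.  The feature filter is computed after cell filtering.  The
detected-feature ratio counts features with coverage strictly above 20.

## Beta-binomial normalization

Per cell and context the raw levels mc/cov over covered features give the
sample mean m and variance v; the beta prior is α = m(m(1−m)/v − 1),
β = (1−m)(m(1−m)/v − 1).  The normalized level of a feature is
((α+mc)/(α+β+cov)) / (α/(α+β)); cov = 0 yields exactly 1 and is set so
explicitly to avoid float drift.  Numerical guards: m is clipped to
[1e−4, 1−1e−4]; when v ≤ 1e−12 or m(1−m)/v ≤ 1 (no proper beta exists)
the prior falls back to the same mean with fixed strength α+β = 100 —
weak but proper.

Fitting the raw levels deliberately absorbs binomial counting noise into
the prior (noisier cells get weaker priors).  When the goal is instead to
recover the latent beta shape from count data, `estimate_beta_prior`
accepts a `mean_cov` argument and applies the classical beta-binomial
moment correction v_p = (v − m(1−m)/c̄)/(1 − 1/c̄); without it the fitted
shapes are biased low by roughly m(1−m)/(c·v) relative (about 18% at
coverage 50 for Beta(2,8)), which is a property of the raw-level fit, not
an implementation defect.

Highly variable features: dispersion (variance of normalized levels) is
z-scored within a 20 × 5 quantile grid of (mean level, mean coverage) —
the grid sizes are our defaults; groups with fewer than two members use
the global dispersion scale.  Ties fall back to raw dispersion, then
feature order.  PCA runs per context on z-scaled HVF matrices (no extreme-
value clipping before scaling) with the full SVD solver; CH components
come first in the concatenation.  The default of 32 components per context
is configurable and the variance-ratio report supports manual elbow
inspection.

## Consensus clustering

KNN graph: exact Euclidean neighbours (k = 25 default) on the concatenated
PCs, symmetrized.  Leiden (RB-configuration modularity) is repeated
`n_runs` times with consecutive seeds; the production default is 300 runs.
The cell–cell distance is the fraction of runs assigning two cells to
different communities — labels are compared only within a run, which is
the only permutation-safe reading of a distance over run-label matrices.
DBSCAN (min_samples 5) is traversed over epsilon 0.05–0.6 in steps of
0.05; candidates whose cluster count lies within the [min, max] per-run
range are retained, deduplicated.

Each candidate is evaluated by a random forest with
class_weight="balanced_subsample" (the closest installed equivalent to a
class-balanced random forest) on a stratified 90/10 split, scored by
balanced accuracy on the held-out 10%.  Clusters with fewer than two
members are merged into the Euclidean-nearest centroid first.  Recursive
feature elimination (step 10%) is available as an evaluation device but
off by default: it measures reproducibility and does not define the
partition.  The best candidate's model rescues outliers whose maximum
predicted probability strictly exceeds 0.3.

Resolution selection takes the largest resolution whose final partition
has outlier fraction < 0.05, held-out accuracy > 0.9 and ≥ 30 cells per
cluster on average; an audit log records every rejection.  The iterative
hierarchy re-runs normalization, HVF selection, PCA and consensus inside
each cluster, accepts per-level configurations (rounds typically use
different HVF/PC budgets, exactly as per-round parameter tables do in
practice), and stops a branch below 60 cells or when no resolution
qualifies.

## Differential methylation

**Genes.**  Per ordered cluster pair, a one-sided Wilcoxon rank-sum test
for decreased normalized methylation, BH-corrected across genes within the
comparison (the correction scope across pairs is not standardized; within-
pair is our reading).  Significance needs adjusted P < 1e−3, delta mean
normalized level < −0.5 and AUROC > 0.8, all strict.  AUROC is the
probability that the partner cluster's level exceeds the hypo cluster's,
so values near 1 mean clean hypo-methylation.  Constant genes score
P = 1, AUROC = 0.5.  The ≥5-marker rule is enforced by iteratively merging
the smallest failing cluster into its nearest PC-space centroid; a pair's
marker count sums both directions.  Non-neuronal analyses use normalized
mCG instead of mCH via the context argument.

**Taxonomy and scores.**  Top-50 markers per pair (ascending adjusted P,
then descending |delta|, then gene id), union deduplicated; subtype ×
gene median normalized levels; average-linkage, correlation-distance
dendrogram.  Impact score at a node with branches of M and N leaves:
IS_A = (a−b)/(M·N) with a, b counts of significant comparisons favouring
each side; IS_B = −IS_A exactly; total impact is Σ h_i·|IS_A| over
non-singleton nodes, restrictable to any node subset.  Heights are
correlation-distance linkage heights, so total-impact values are
comparable only within one tree.  Overlap scores and the >0.3 matching
rule follow the definition in the README; pseudo-cells aggregate cells
within a cluster by k-means with k = n/50 (minimum 1), discarding groups
under 10 cells.

**Sites and regions.**  The site-level statistic is the coverage-weighted
RMS deviation of per-sample fractions from the pooled fraction; the null
permutes methylated basecalls among samples preserving per-sample
coverage (sequential hypergeometric draws), with add-one empirical P and
BH correction across tested sites (site significance at adjusted
P < 0.01).  The named test family fixes the statistic class, not its
implementation constants; ours is validated against an exhaustive
enumeration oracle at small coverage and calibrated on null beta-binomial
sites (type-I 0.048 at nominal 0.05 with 999 permutations).  Note the
permutation floor matters: with 199 permutations the smallest attainable
P (0.005) cannot clear BH at α = 0.01 over hundreds of sites, so
production uses 999.

Significant sites within 250 bp inclusive merge into regions.  Per
region, samples are ordered by mCG fraction and the robust mean m averages
those between the 25th and 75th percentile ranks (median below 4
samples); a sample is assigned hypo if its fraction < m − 0.3 *and* at
least one member site deviates below the pooled fraction in that sample
(our site-level reading of a per-sample significant call), hyper
symmetrically; regions with neither assignment are dropped.

**Correlations.**  DMR mCG and gene mCH subtype profiles each have a
global-methylation covariate regressed out by least squares (global mCG
for DMRs, global mCH for genes); Pearson correlations are computed for
pairs with |DMR centre − TSS| ≤ 1 Mb on one chromosome, and the two-sided
empirical P pools 100 shuffled-subtype recomputations of all pairs.
Reported pairs satisfy |r| > 0.3 and P < 0.005, positives and negatives
flagged by sign.  Chance alignment between a profile and the regressed
covariate erodes residual correlations as 1/√n_subtypes; at atlas scale
(~100+ subtypes) the erosion is negligible, and validation uses that
scale.

**Gradients.**  Cells are quartiled by global mCH; 400 cells per group
(configurable) are pooled and regions called across the four groups;
15 random groups ignoring global mCH provide control regions removed by
interval overlap; each surviving region's Pearson ρ of group fractions
against (1, 2, 3, 4) classifies it as +DMR (ρ > 0.75), −DMR (ρ < −0.75)
or weakly correlated (excluded), all strict.  Gene enrichment compares
DMS vs cytosine counts in gene bodies against ±1 Mb flanks by one-sided
Fisher tests; enriched genes need BH-adjusted P < 0.01 and strictly more
than 20 DMSs, with genes ≤ 5 kb excluded.

## 3D-genome statistics

Pair tables are binned per chromosome (intra-chromosomal only; pairs
closer than 1 kb optionally dropped as self-ligations).  Balancing is
symmetric alternating row/column scaling to unit row sums (tolerance
1e−6), the fixed point of the same problem Knight–Ruiz solves; empty bins
are masked, not fatal.  Observed/expected divides each diagonal by its
mean.  The insulation score of bin i is the mean of the 10×10 cross
square over the larger of the two flanking within-side square means,
masked near chromosome ends and where a flank is fully masked.  For the
saddle, bins are filtered to z-scored coverage in [−1, 2], balanced, and
the compartment score is PC1 of the observed/expected of the balanced
matrix — taking PC1 before dividing out the distance decay lets the decay
dominate the leading component, so the o/e step is required for the score
to track compartments.  PC1's sign is oriented by an optional reference
track; the corner-ratio strength (mean of the two like-with-like 10×10
corners of the 50×50 saddle over the two cross corners) is sign-invariant
up to the near-equal category binning.  The embedding follows the
smoothing recipe: 3×3 box convolution, row-normalized random walk with
restart (fixed point of Q = p·M + (1−p)·Q·M, tolerance 1e−6; p = 1
returns the convolved map), top-20% binarization, PCA to 20 components.

## Spatial predictor

The multi-task network is a self-contained numpy implementation (He
initialization, ReLU, inverted dropout, softmax heads, summed
cross-entropies, Adam), fully deterministic given its seed.  Task losses
are weighted equally.  Input dimensionality follows the available PCs
(min(3000, features−1) at atlas scale).  Training runs exactly the
configured epochs with no early stopping.  Fuzzy accuracy counts a region
prediction as correct when it matches the truth or an adjacent region;
the composition baseline guesses each subtype's modal region and is
scored with the same fuzzy rule.  Logistic-regression and random-forest
single-task baselines are provided behind one helper for benchmark
comparisons.  Permutation importance shuffles one PC column at a time
(5 shuffles) and reports the mean accuracy drop.

## What the generator emulates — and what it does not

`simulate` draws, per cell: a cluster (and a dissection region from a
per-cluster composition), a global level per context (defaults: mCH
1–4%, mCG 65–85%), negative-binomial feature coverage (mean 500,
dispersion 10 — per-feature coverage distributions for this assay are not
published; NB is a stand-in), and per-feature levels from a beta centred
on the cluster mean scaled by the cell's relative global level, with
concentration 50 (realistic overdispersion while keeping moment recovery
testable).  Region effects are multiplicative offsets on a configurable
feature subset, so spatial origin carries signal beyond cluster
composition.  Gradient populations plant CpG-site regions whose mCG moves
monotonically with global mCH across a 0.85 fraction span — with four
groups the interquartile robust mean sits mid-gradient, so the extreme
group only clears the ±0.3 filter when the planted span exceeds 0.8.
Contact maps combine power-law distance decay, aperiodic balanced-random
compartment labels (a strictly periodic checkerboard makes the
within/between mix deterministic per distance and the o/e step erases the
signal), and per-type domain boosts, Poisson-sampled per cell.

Not emulated: chromosome-scale genomes, sequence-level bisulfite reads,
doublets, batch effects, covariance between coverage and methylation, and
replicate structure.  Passing tests therefore demonstrate that the
statistical machinery behaves as specified under its own model
assumptions — not that those assumptions exhaust real data.

## Test-profile problem sizes

The suite validates the full procedures at reduced scale as the package's
test profile: consensus ensembles of 10–50 Leiden runs (production
default 300), cohorts of 200–2,000 cells with 100–1,000 features,
999-permutation site tests on up to 2,000 sites, 100-permutation
correlation nulls, 200-bin contact matrices, and 10-seed predictor
comparisons.  The planted two-level hierarchy uses class markers about
twice the relative effect of subtype markers (Δ mCH 0.017 vs 0.013 over
60 vs 40 features), mirroring atlases where classes differ globally and
subtypes subtly; recovery scores adjusted Rand > 0.95 at both levels.

## Known limitations

Balancing falls back to the best iterate (with a warning) when the
tolerance is not reached; impact scores assume binary trees (multifurcating
nodes would need an explicit branch pairing); the pipeline orchestrator
covers the simulate → normalize → cluster → DMG demo path, while the DMR,
3D and predictor stages are driven directly through their module
functions; the permutation site test is exact only under exchangeability
of basecalls across samples, i.e. genuine per-sample heterogeneity beyond
a shared site-level fraction inflates rejections by design.
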