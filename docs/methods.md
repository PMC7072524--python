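# Methods

`methinv` reconstructs tumor-invasiveness labels for primary breast cancers
from genome-wide DNA methylation and trains classifiers on the resulting
pseudo-labels. This note records the statistical model behind each stage, the
defaults and why they were chosen, what the bundled cohort simulator does and
does not emulate, and the numerical decisions a maintainer would want to know.

## Data model and preprocessing

The carrier object is a probes × samples matrix of beta values
β ∈ [0, 1] (proportion methylated at a CpG), HM450-style, with `NaN` for
missing entries. Preprocessing is a fixed chain:

1. **Probe-class filter.** Only `cg` (CpG) probes are kept; `rs` (SNP) and
   `ch` (CpH) probes, and any unknown prefix, are dropped and logged.
2. **Missingness filter.** A probe is dropped when its missing fraction is
   *strictly greater* than `max_na_fraction` (default 0.30; a probe missing
   in exactly 30% of samples survives).
3. **KNN imputation.** Distance between probe rows is the plain Euclidean
   distance over their mutually observed samples (no rescaling by the number
   of shared columns). A missing entry is the unweighted mean of the
   `knn_k = 10` nearest donor probes observed in that sample, clipped to
   [0, 1]. The target column never contributes to the distance because the
   target's own entry there is missing. A probe row with no observed values
   is an error. The chain is idempotent.

`knn_k = 10` is the conventional default for array imputation; the value is
configurable and results are insensitive to it at the default missingness
rate (~0.2% of entries).

## Distance pseudo-labeling

Matched primary/lymph-node-metastasis pairs anchor the invasive class. On the
preprocessed matrix:

* **Pair distances.** One Euclidean distance per matched pair over all probes.
* **Quartile filter.** Pairs with distance above the upper Tukey fence
  Q3 + 1.5·IQR (type-7 quantiles) are discarded as aberrant; the multiplier
  is configurable. At least four pairs are required.
* **Margin rule.** For every unpaired primary, compute its minimum distance
  d_min to the retained metastasis profiles. The sample is called
  *noninvasive* iff d_min > max(retained pair distance) + margin, with a
  strict inequality at the boundary. Default margin: 10 distance units.
  Everything else stays *unlabeled* and is excluded from training; *normal*
  comes only from the sample sheet.

The margin is on the genome-wide beta Euclidean scale and therefore grows
with the square root of the probe count; it is exposed as a knob because any
cohort with a different probe universe needs it rescaled. With ~20,000 probes
and typical beta dispersion, within-pair distances sit near 5 units and
tumor-to-unrelated-metastasis distances near 11, so a +10 margin only fires
for samples that are genuinely far from every metastasis.

Because pair distances concentrate tightly around their mean at genome scale,
the Tukey fence behaves like a ≈2.7σ cut: for approximately Gaussian pair
distances a clean pair exceeds it with probability ~0.3%, so occasional
false removals are possible on unlucky seeds; they do not propagate beyond a
slightly smaller invasive training set.

## Differential methylation

Statistics run on M-values, M = log2((β + ε)/(1 − β + ε)) with ε = 1e−6 —
the log-scale representation on which two-group linear models are
approximately homoscedastic. "logFC" throughout means the difference of
group-mean M-values and the 1.5 selection threshold applies to |logFC|.

### Engine 1: empirical-Bayes moderated t

Per probe g, a two-group mean model gives residual variance s²_g on
d_g = n₁ + n₂ − 2 df. The prior (d₀, s₀²) is estimated by moment matching of
log s²_g against a scaled-F marginal: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
solve ψ′(d₀/2) = var(e) − ψ′(d_g/2) by Newton inversion of the trigamma
function and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When var(e) does not
exceed the sampling component, d₀ = ∞ and every variance shrinks fully to
s₀². The posterior variance is the usual convex combination
s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g), the moderated t is
logFC/(s̃_g √(1/n₁ + 1/n₂)) on d₀ + d_g df, and q-values are
Benjamini–Hochberg. The non-robust fit reproduces the R reference
implementation (limma `eBayes`) to ~1e−10 on a frozen fixture (see the test
suite).

**Robust variant (default).** The log-variances e_g are winsorized at their
5th/95th percentiles before moment matching, and probes above the upper
winsorization bound e_hi receive a *down-weighted* per-probe prior df,
d₀·exp(−(e_g − e_hi)), so hypervariable outlier probes are shrunk less and
cannot borrow a spuriously small posterior variance. This is this package's
own robustification: simple, monotone in the exceedance, and in the same
spirit as rank-conditioned robust EB schemes, which are underdetermined from
their published descriptions.

`d0_override=0` disables shrinkage entirely (the ordinary pooled t), which
is also how the engine is validated against the textbook statistic.

### Engine 2: SAM permutations

d(i) = (mean₁ − mean₂)/(s(i) + s₀), with s(i) the pooled standard error of
the mean difference and s₀ a stabilizing constant. Default
s₀ = median of the s(i); a Tusher-style percentile search (minimizing the
coefficient of variation of mad(d) across s-strata) is available as
`percentile_s0`. Group labels are permuted M = 1000 times (exhaustively when
the balanced-assignment count is smaller, with M truncated and logged); each
permutation's d vector is sorted descending, the rank-wise mean across
permutations gives the expected order statistic dE(i), and Δ(i) = |d(i) −
dE(i)| after aligning ranks back to probes. The permutation p-value pools
|d| over all probes and permutations with an add-one correction,
p_i = (1 + #{|d_null| ≥ |d_i|}) / (1 + M·G), so no p-value is exactly zero.
Tie counting uses a 1e−9 relative tolerance so a permutation that reproduces
the observed split counts as a tie despite summation-order rounding.

### Selection and overlap

Both engines are filtered with |logFC| ≥ 1.5, p < 0.01 and BH q ≤ 0.01
(Δ > threshold optionally for SAM), and the two candidate lists are
intersected (ordered by the first list) to suppress false positives. BH on
permutation p-values replaces SAM's median-false-positive Δ-tuning so one
FDR rule governs both engines; Δ remains available as an additional filter.

## Dimensionality reduction

All four reducers are scikit-learn estimators fitted on training data only;
projections store training means/loadings so held-out cohorts are
transformed without refitting.

* **MRMD-style selector.** score(f) = w_r·minmax(|Pearson r(f, y)|) +
  w_d·minmax(mean Euclidean distance from f to all other features); both
  terms are min-max scaled across features because they live on incomparable
  scales. Ties break on the feature name. Constant features get relevance 0.
* **mRMR selector.** Features are discretized into per-feature quantile
  tertiles (configurable); ranking is greedy MID — first pick maximizes
  I(f; y), each later pick maximizes I(f; y) − mean over selected s of
  I(f; s) — with plug-in mutual information in bits.
* Both selectors choose the panel size by sweeping top-k prefixes
  (k ≤ `max_subset`, default 20) with a 100-tree seeded Random Forest under
  stratified CV and taking the *smallest* k attaining the maximum mean
  accuracy (parsimony on plateaus).
* **PCA.** Full SVD; keep the smallest number of leading components whose
  cumulative explained-variance fraction reaches 0.95.
* **Factor analysis.** Maximum-likelihood FA; the factor count defaults to
  the PCA component count at the same variance threshold. Convergence
  tolerance 1e−3 with a 2000-iteration cap, raising an explicit
  iteration-limit error beyond it: in the post-selection regime (tens of
  samples, hundreds-plus of sites) the EM log-likelihood is nearly flat and
  tighter tolerances do not converge in any reasonable budget.

## Classification and clustering

Two 500-tree seeded Random Forests (sqrt-features per split, stratified
10-fold CV; folds shrink with a warning when the smallest class is smaller
than k): one separates normal from tumor on the tumor-vs-normal feature
representation, one separates invasive from noninvasive tumors. Cohort
prediction is two-stage — the normal gate first, then the invasiveness model
on tumor calls — since two independent binary models need a composition rule;
both raw per-model outputs are also reported. Class imbalance (40 vs 20) is
handled by stratification only; class weights are available on the sklearn
estimator if needed. Complete-linkage hierarchical clustering (Euclidean)
with a 2-cluster cut provides the unsupervised check that the selected sites
separate the two tumor groups; dendrograms export to Newick.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, with
a ground-truth manifest for every planted element:

* probe means from a bimodal Beta mixture (hypo/hyper peaks), clipped to
  [0.05, 0.95];
* values drawn from Beta(mean·ν, (1−mean)·ν) with precision ν = 50
  (within-group beta SD ≈ 0.05–0.07, a realistic array dispersion);
* matched pairs share a latent pair profile: the pair-level mean uses
  precision ν/w and members use ν/(1−w) with pair weight w = 0.75, so
  within-pair distances are well below between-sample distances;
* planted differential sets: 5% of probes shifted by Δβ = 0.3 for
  tumor-vs-normal and a disjoint 5% for invasive-vs-noninvasive, shifted
  toward whichever side of 0.5 has room;
* noninvasive samples get independent per-probe mean jitter (SD 0.08),
  pushing their distance to every metastasis above the paired maximum by
  comfortably more than the 10-unit margin at 20,000 probes;
* 4 aberrant pairs with 16× inflated within-pair dispersion (quartile-filter
  fodder); 0.2% missing entries; 50 SNP/CpH decoy probes; clinical
  indicators drawn per true label (e.g. T3: 60% in invasive vs 10% in
  noninvasive) with 5% unknowns.

Defaults are 20,000 probes (not the full ~480k/393k array) so the whole
pipeline runs in minutes on one CPU; the margin scale is calibrated to that
probe count as described above. A held-out cohort can be drawn from the same
latent model (same probe means and planted sets, fresh samples) for
prediction and enrichment.

**What the simulator does not emulate:** genomic annotation (chromosome,
gene, CpG-island context), probe-type chemistry differences, batch and
purity confounders, copy-number effects, correlated probe blocks, and
subtype heterogeneity. Passing tests therefore demonstrate that the
machinery recovers planted structure under idealized dispersion — not
clinical performance on real cohorts.

## Enrichment evaluation

For each predicted group and clinical indicator (T3, N3, HER2+, LN+ by
default), the background is the classified tumor samples with known status:
N total, K positive; the group contributes n with k positive. The enrichment
ratio is (k/n)/(K/N) and the p-value the hypergeometric upper tail
P(X ≥ k); samples with unknown status are excluded from both N and n
(imputing presence would bias ratios toward the group with more missing
pathology). BH adjustment runs over all (group × indicator) tests emitted in
one run, and Fig.-style stars (`**`) mark raw p < 0.01; both p and q are
reported because either convention appears in practice.

## Determinism and numerical edge cases

Every stochastic stage (cohort generation, SAM permutations, CV folds,
forests) derives from one config seed; a full `run-all` is byte-identical
across reruns with the same seed. Degenerate inputs fail loudly: all-zero
variances in the EB fit, a single-class contrast after labeling (e.g. a
margin above every distance), probe gaps at prediction time, and FA
non-convergence each raise typed errors naming the stage. Quantiles
everywhere are numpy type-7 (linear interpolation). The `Δ = |d − dE|`
alignment uses a stable descending sort so ties cannot reorder probes
between runs.

## Problem sizes used by the test suite and acceptance script

The bundled checks run the default 20,000-probe cohort for labeling,
differential testing, reduction, classification and enrichment, a
2,000-probe null and planted design (n = 20/20, ΔM = 2, within-group SD 0.6)
for engine calibration and recovery, and exhaustive 2-vs-2 permutation
oracles for SAM — sizes chosen so each property is measured at the scale
where its expected behavior is unambiguous while the full suite stays in the
minutes range on a single CPU.
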