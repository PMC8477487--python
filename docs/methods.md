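# Methods

## The classification model

The classifier throughout is bootstrap aggregation (bagging) of
classification trees. Each of `n_trees` trees (default 500) is grown to
purity (`min_leaf = 1`) on a bootstrap resample of the training samples,
considering `features_per_split` randomly chosen genes at each split
(default `sqrt` of the current gene universe, Gini criterion). A sample's
**probability score** is the fraction of trees voting the positive (IBC)
class; the call is positive iff the score is *strictly* greater than the
threshold (default 0.5), so a score of exactly 0.5 goes negative. Scores
therefore lie on the grid k/`n_trees`. The tree learner is scikit-learn's
`RandomForestClassifier`; the vote-fraction score, out-of-bag (OOB)
statistics and the text serialization are implemented on top of the fitted
trees. Everything is a pure function of (data, config, seed), fitted
single-threaded, so results do not depend on thread count. Serialized
models store each tree as flat arrays (children, split feature, threshold,
leaf class) and reproduce the original votes exactly on reload.

## Predictor importance

Two measures are exposed:

* **Impurity importance** (default): mean decrease in Gini impurity
  accumulated over all splits, normalized by the learner.
* **OOB permutation importance**: per tree, each gene actually used by that
  tree has its values permuted among the tree's OOB samples (`n_repeats`
  independent permutations, default 3, averaged) and the decrease in OOB
  accuracy is recorded; trees not using the gene contribute zero, and
  negative averages are clipped to zero.

Impurity is the default because at the training sizes this design produces
(~40 matched samples) each tree holds only ~14 OOB samples, so per-tree
permutation decreases are quantized at 1/14 and the resulting ranking is
noticeably noisier: in planted-signature recovery simulations (59 planted
genes at 1.5 noise-SD among 2000, five seeds) recursive discovery recovers
on average 0.83 of the planted genes with impurity ranking versus 0.77–0.80
with permutation ranking. Both are available through `ForestConfig`.

## Matched training design

Training samples are paired by *exact* equality of the ordinal
(ER, HER2) score pair — not propensity or distance matching — because the
design's purpose is to remove receptor-driven molecular-subtype signal
outright. Within a score stratum any positive may pair with any negative,
so the maximum-cardinality matching is `min(#pos, #neg)` pairs per stratum,
taken in lexicographic sample-id order for determinism (the result is
invariant to input sample order). Up to `allow_unmatched` extra samples per
class (default 1, mirroring a 22-of-24-matched design) are appended
unmatched, chosen as the leftover positive/negative combinations nearest in
L1 distance on the score grid — the least-assumption completion. Holdout is
every sample not in training, normal samples included: accuracy is always
computed with non-IBC *and* normal samples as negatives.

## Signature discovery

`discover_signature` defaults to **recursive elimination**: fit the
ensemble on the surviving genes over the matched training samples, keep the
top `elim_fraction` (default half) by importance, repeat until `k` genes
remain, and take the final ranking's top `k` with their scores. Single-pass
ranking (`mode="single"`) is available but recovers planted genes less
efficiently (~0.75 vs ~0.83 at default conditions): each elimination round
re-estimates importance on a smaller, less diluted universe. `k` is a
parameter (default 59); the package takes no position on whether a
signature size should be preset or chosen from an importance elbow.

## Random-set null

Specificity is quantified against ensembles trained on uniformly random
gene sets of the signature's size, one independent draw and one retrain per
iteration (reference protocol: size 59, 10,000 iterations; the bundled
checks use 200). All iterations are evaluated on one fixed sample set so
null and observed accuracies are comparable: the design's holdout by
default, or — when the observed accuracy was measured on an independent
validation cohort — that same cohort via `eval_cohort`. The default is
unsuitable when maximum matching leaves only a handful of holdout samples
(a random set then reaches 100% on, say, 7 samples with non-trivial
probability); the cross-cohort evaluation set is the honest choice there.
The empirical p-value uses the add-one formula
`(1 + #{null ≥ observed}) / (n_iterations + 1)`.

## Unsupervised checks

Samples are clustered on per-gene z-scored signature expression
(z-scoring, linkage and metric configurable; defaults: average linkage,
Euclidean — the standard choices for expression heatmaps, since the
original analysis does not pin them down). The Caliński–Harabasz index
`[B/(k−1)]/[W/(n−k)]` is computed in the same z-scored space for
k = 2..`k_max` (default 8); partitions with zero within-cluster scatter (or
k = 1, k = n) are reported as NaN rather than infinite, and `optimal_k` is
the argmax over defined values. PCA is mean-centered with each component's
sign fixed so its largest-magnitude loading is positive, making projections
deterministic and invariant to gene order; signature genes are sorted
internally before the sign convention is applied.

## Subtyping and ROR

Intrinsic-subtype calls use Spearman rank correlation between a sample's
panel-gene expression and five subtype centroids (Luminal A/B,
HER2-enriched, Basal-like, Normal-like); the call is the argmax with ties
broken by fixed subtype order. Rank correlation makes calls invariant to
any monotone per-sample transformation. The risk-of-recurrence score is the
subtype-only (ROR-S) form: an affinely rescaled weighted sum of the five
correlations, `ror = offset + scale · Σ w_s · r_s`, with the published
subtype weights (Basal 0.05, HER2 0.12, LumA −0.34, LumB 0.23) as defaults.
The centroid panel is a pluggable text file (gene × subtype matrix plus a
coefficient header), so any published centroid/coefficient set can be
supplied; the bundled `synthetic_demo_panel` is random, fixed by seed, and
carries no biological meaning — it exists to exercise the machinery.

## Survival

Kaplan–Meier curves use the product-limit estimator (via lifelines). The
two-group comparison is the Mantel–Haenszel log-rank test: at each distinct
event time a 2×2 deaths/at-risk table is tabulated (simultaneous-event
convention for ties), giving the statistic `(O1−E1)²/V` with the
hypergeometric variance and a chi-square(1) p-value. The hazard ratio is
the O/E form `(O1/E1)/(O2/E2)` with a log-scale 95% CI from variance
`1/E1 + 1/E2`; this needs no iterative fitting and matches the
single-HR-plus-CI summary the analysis reports. A Cox model would be the
natural extension but is out of scope.

## The simulator

Per gene g and sample s on the log2 scale:
`x[g,s] = baseline[g] + delta[g]·1{class(s)=IBC} + eps[g,s]`, with
`baseline ~ N(8, 1.5)` (microarray-like), `eps ~ N(0, noise_sd)`
(`noise_sd = 1`; a Laplace switch exists for robustness checks), and
`delta = ±effect_size·noise_sd` on the `n_signal` planted genes (default
59 at 1.5), zero elsewhere. Signs are random per gene so the signature is
bidirectional — a one-directional shift would also separate classes in
clustering, but bidirectional blocks are more realistic and stress the
importance ranking harder. Normal-tissue samples carry no shift. Defaults
mirror the discovery design: 2000 genes, 20 IBC / 20 non-IBC / 5 normal.

Receptor scores are drawn from a small categorical (ER, HER2) grid; a
`matchable_fraction` (default 0.9) of the smaller class is then guaranteed
an exact cross-class partner by copying score pairs, emulating a cohort
assembled so that most training samples are receptor-matchable (iid draws
alone would leave only ~60–75% matchable at these counts).

Validation cohorts (default 33 IBC / 28 non-IBC, pre-treatment) reuse the
discovery cohort's planted genes and signs, then add a batch effect — a
global +0.5 offset plus per-gene N(0, 0.3) jitter. In post-treatment mode
the planted effect is multiplied by `attenuation` (default 0.2), emulating
chemotherapy-induced expression changes that destroy the signature's
signal.

Survival times are exponential with hazard `h0` (default 0.05 per unit
time; the time unit is arbitrary) for the negative class and `h0 · HR`
(default HR 3.15) for the positive class. With probability
`censoring_rate` (default 0.3) a subject is censored at a Uniform(0, T)
time before its event — a simple scheme that realizes the configured
censoring probability exactly and keeps censoring independent of group.

What the simulator does **not** emulate: gene–gene correlation (genes are
independent given class), platform/probe effects, heavy-tailed or
intensity-dependent noise, annotation errors, or informative censoring.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and well calibrated under its own assumptions — not that a real
cohort of this size would yield an equally clean signature.

## Problem sizes and determinism

The bundled checks and `scripts/acceptance.py` use the default cohort
sizes, five simulation replicates for recovery, 200 null iterations
(scaled down from the 10,000-iteration reference protocol) and 200
survival replicates — sizes chosen so the whole suite runs in minutes on a
single CPU while keeping Monte-Carlo error well inside the asserted
margins. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` streams; identical seed and config give
bit-identical cohorts, models and scores.

## Known limitations

* Binary positive-vs-rest classification only; "normal" samples are scored
  by the binary model, never modelled as a third class.
* No gene-identifier alias resolution: signature comparison is exact string
  matching (optional case folding).
* Missing expression values are rejected rather than imputed.
* The O/E hazard ratio is biased away from 1 relative to a Cox estimate in
  small, heavily censored groups; its CI is approximate.
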