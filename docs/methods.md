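# Methods

This note records the models, numerical choices and known limitations of
`nrf2modnet`, in the order the pipeline runs.

## Fold-change construction

An experiment is a (compound, concentration, time) condition. Its value for
gene g is `mean(log2 treated) − mean(log2 vehicle at the same time)`.
Vehicle matching is by time only; the pipeline starts from normalised log2
intensities (array normalisation such as RMA is out of scope). Missing
values and duplicate gene identifiers are hard errors: each gene is assumed
to be represented by a single (already collapsed) probe set upstream.

## Co-expression network and module detection

* **Adjacency.** `a_ij = |pearson(g_i, g_j)|^beta`, unsigned, so co-induced
  and co-repressed genes group together. Zero-variance genes are rejected
  with the offending gene named; they must be filtered upstream.
* **TOM.** `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`
  with `k_i = Σ_{u≠i} a_iu`; dissimilarity `1 − TOM` feeds average-linkage
  hierarchical clustering (scipy implementation).
* **Tree cut.** A *static* cut at `cut_height × max merge height`
  (default 0.99) with a minimum module size of 5; clusters below the floor
  are unassigned. This deliberately diverges from WGCNA's dynamic hybrid
  tree cut: the static cut is deterministic and easy to reason about, and
  recovers planted structure at desk scale. The min size of 5 admits the
  6–11-gene modules this analysis cares about. Consequence: module counts
  are not comparable to dynamic-tree-cut outputs at scale.
* **Soft-power selection.** Rather than a scale-free-topology fit index
  (whose threshold choice is arbitrary and unstable), the power in
  {4, 6, 8, 10} is chosen to maximise the Welch unequal-variance t-statistic
  of mean vehicle log2 intensity, module members vs non-members. The
  rationale is biological: genes not expressed in the test system are noise
  and should not be co-expressed, so a good power concentrates expressed
  genes inside modules. Each gene's intensity summary is its mean across
  all vehicle arrays. Ties prefer the smallest power. Powers at which every
  gene ends up unassigned are excluded from the argmax with a warning.
* **Merging.** Pairs of modules whose eigengenes (raw, pre-Z scores)
  correlate at or above 0.8 (signed Pearson) are merged greedily, highest
  correlation first, recomputing eigengenes after each merge until no pair
  qualifies. Signed rather than absolute correlation: anti-correlated
  programmes stay distinct. The post-condition (no surviving pair ≥ 0.8) is
  asserted by the tests.

## Module score (eigengene)

Standard module eigengenes centre-and-scale each gene before the SVD, which
manufactures non-zero scores for experiments in which nothing happened. The
score used here deviates in two ways, both preserving "unperturbed = 0":

1. member fold-change columns are divided by their standard deviation
   (n−1 denominator) but **not** centred;
2. the raw score — first left singular vector of the uncentred, scaled
   submatrix times the first singular value, sign-oriented so mean member
   correlation is ≥ 0 — is divided by its own standard deviation across
   experiments, again without mean subtraction.

An all-zero experiment row therefore scores exactly 0, each score column has
unit variance, and scores are invariant to positive rescaling of any member
gene. Whether the singular value is folded into the raw score is immaterial
after Z-scaling; it is folded in so the merge step sees magnitudes.
One subtlety: appending an all-zero experiment rescales the other scores
*exactly* proportionally only in the noise-free rank-1 limit; with noise,
per-column standard deviations shift non-uniformly and proportionality is
approximate (correlation > 0.999 in the tests). Zero-variance member genes
and modules with constant scores are errors, not silent NaNs.

Per-module gene correlations (eigengene vs member fold changes) define the
hub gene as the argmax, ties broken lexicographically by gene identifier.

## siRNA screen

Donor-paired contrasts (siNRF2 vs siCON, siKEAP1 vs siCON) are tested with a
moderated paired t-test: per-gene difference variances are shrunk towards a
scaled inverse-chi-square prior (d0, s0²) fitted across genes by the method
of moments on log variances (polygamma inversion; d0 = ∞, i.e. complete
shrinkage, when the observed spread of log variances does not exceed the
chi-square sampling component). The statistic `mean(d)/(s_post/√n)` is
referred to a t distribution with d0 + n − 1 degrees of freedom. Under a
4-donor Gaussian null the empirical type-I error at p < 0.05 averages 0.050
(range 0.040–0.060 over 50 seeds). A gene with zero variance and zero mean
difference gets p = 1 by convention. Benjamini–Hochberg adjustment is
applied per contrast over all tested genes (the adjustment universe is a
choice; per-contrast is the least surprising default). A full linear-model
empirical-Bayes fit (limma-style, with covariates and array weights) is
deliberately not reproduced: the downstream filter consumes only signs and
adjusted p-values of donor-paired contrasts.

The opposite-regulation filter calls a gene *positively controlled* when
adj p < 0.05 with log2FC < 0 under siNRF2 **and** adj p < 0.05 with
log2FC > 0 under siKEAP1, and *negatively controlled* under the mirrored
condition. Requiring opposite behaviour under the two knockdowns guards
against single-siRNA off-target effects. Genes significant in only one
contrast, or in the same direction in both, are excluded. If multiple
probes per gene exist they must be collapsed upstream; a gene is a hit if
any of its probes passes consistently in both contrasts.

## Enrichment

Modules overlapping the screen set are tested with the upper-tail
hypergeometric probability P(X ≥ overlap); modules with zero overlap are
excluded from both the tests and the Bonferroni multiplier. The default
universe is every gene in the fold-change matrix; restricting it to
module-assigned genes is configurable (`enrichment.universe: assigned`),
since the appropriate universe is a genuine modelling choice.

## Compound classification and performance

A compound positively perturbs a module when the **maximum** score over its
experiments is **≥ 2.0** (inclusive, applied to full-precision scores, never
to rounded display values). The combined metric is "any selected module
positive"; in the pipeline the selected modules are those enriched for
screen genes when the screen ran, otherwise all modules. Indicators follow
the classical confusion-matrix definitions (sensitivity, specificity,
accuracy, PPV, NPV); zero-denominator ratios are reported as NaN, never 0.
Compounds outside the positive/negative classes of a contrast are excluded
before counting; compounds absent from a call table count as not-called.
Class definitions: reactivity = reactive vs not-bioactivated-or-reactive
(bioactivated and unknown excluded — whether bioactivated compounds belong
in the negative class is ambiguous, so they are excluded by default and the
classes are overridable per call); bioactivation = bioactivated vs
not-bioactivated-or-reactive; DILI = most vs less/none concern (ambiguous
and unannotated excluded). ROC curves sweep the observed scores as
thresholds; the trapezoidal AUC equals the Mann–Whitney U statistic scaled
by n₊·n₋ with ties counted ½ (property-tested against the all-pairs count).

Negative-control module selection reduces the published criteria to
(a) size within 6–11 genes and (b) disjointness from a caller-supplied
exclusion gene set; proper GO-term enrichment needs an external ontology
and is out of scope.

The packaged 47-compound fixture stores the published eigengene values
(rounded to one decimal) together with explicit per-cell significance
marks, because a displayed "2.0" occurs both marked and unmarked —
significance is never re-derived from displayed values. The fixture
contains only responding compounds, so indicator evaluation restricted to
it has no true negatives; full indicator analyses need score tables
covering all compounds.

## Synthetic world

The generator emulates a compound-perturbation repository at desk scale:
2,000 genes, 60 compounds × 3 concentrations × 3 times (540 experiments),
two vehicle arrays per time point. Ten modules are planted through one
latent factor each, with member loadings uniform in (0.5, 1.0]:

* the first 4 modules form a correlated "NRF2-like" programme: each
  *reactive* compound (15% of compounds) drives each signal module with
  probability 0.6 at magnitude 4 log2FC units × a per-(compound, module)
  multiplier uniform in (0.5, 1.5); *bioactivated* compounds (25%) drive
  signal modules with probability 0.3 at half magnitude;
* each remaining (background) module is driven by 3 dedicated compounds
  from the non-reactive pool — unrelated biology that must not be confused
  with the stress programme;
* perturbation magnitude scales linearly with concentration and time level
  (mean of the two fractional level indices; 1 at high/late). No specific
  dose–response model is implied — only the max-over-experiments rule
  consumes this;
* background factor sd 0.4, i.i.d. gene noise sd 0.3 (Gaussian by decision;
  the empirical fold-change distribution of real repositories is not
  modelled);
* module genes are "expressed" (vehicle intensity ~N(8, 1)) and unassigned
  genes sit at background (~N(4, 1)) — the gap the soft-power heuristic
  detects;
* treated arrays equal the time-matched vehicle mean plus the planted fold
  change, so array-level technical noise is folded into the single noise_sd.

The per-compound×module random magnitudes keep the four signal factors
correlated (as related stress modules are) but below the 0.8 merge
threshold *as factors*; on the default design their eigengenes nonetheless
correlate above 0.8 and the merge step unifies them into one module — the
intended behaviour of the merge rule, and recovery ARI stays ≥ 0.99.

The knockdown generator plants genes positively controlled by NRF2
(−effect under siNRF2, +0.8·effect under siKEAP1; default effect 1 log2
unit) and a smaller repressed set moving oppositely, on top of per-donor
random intercepts (sd 0.5) that cancel in paired differences and i.i.d.
noise (sd 0.25), for 4 donors. In the pipeline the positively controlled
genes are the signal-module members and the repressed genes are drawn from
unassigned genes — mirroring the fact that many screen-identified genes do
not meet co-expression criteria.

What a green synthetic test does **not** establish: recovery of any
particular published module count or AUC (those depend on the full
repository and on dynamic-tree-cut internals), robustness to batch effects,
probe-level artefacts, non-Gaussian noise, or correlated noise across
genes — none of which are modelled.

Null behaviour worth knowing: with perturbation magnitude 0, Z-scaled
scores are approximately unit-variance per experiment, so the
max-over-9-experiments rule calls a compound positive on a given module at
a rate near 1 − Φ(2)⁹ ≈ 0.19 — the threshold is calibrated against a panel
containing real perturbations, not against a pure null. The tests check
this nominal rate, not a smaller one.

## Determinism and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical outputs.
`run_pipeline` writes a manifest with a config hash and a SHA-256 checksum
per output file; a rerun with the same config reproduces every file
byte-for-byte.
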