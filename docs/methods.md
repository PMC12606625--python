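# Methods

This note records the models, conventions and design choices behind
`chemflag`, in the spirit of the methods documentation of the larger
modelling packages: what is computed, under which assumptions, which knobs
matter, and what the synthetic validation does and does not show.

## Curation

Activity-record tables are filtered by nine assay-quality criteria applied
in a fixed order (standard type ∈ {IC50, GI50, EC50, ED50}; relation ∈
{=, >, <}; unit nM; target type CELL-LINE; target organism Human; assay
type F; assay organism Homo sapiens; BAO label "Cell-based format"; and an
assay description naming a 24/48/72/96 h readout and an MTT/SRB/MTS/CCK8
method). Matching on the description is a case-insensitive token search
with configurable token lists. Records missing a mandatory field are
rejected with an explicit `malformed` reason — never silently dropped —
and each rejection logs the *first* failing criterion. Filtering is
idempotent.

Duplicate records for one standardized structure are collapsed to the
record whose value is closest to the weighted average of all reported
values. The weighting behind that average is not fixed by any metadata we
require, so the default is equal weights with a hook for user-supplied
weights; equidistant ties resolve to the lower activity value, then to
stable input order. The chosen value is always a member of the input set,
never a synthetic average.

Labels use a 10 μM activity threshold on nM values: strictly greater than
10,000 nM is inactive, anything at or below is active (the boundary value
itself is active). Percent-inhibition-only records measured at 10 μM with
< 50% inhibition augment the inactive class; ≥ 50% without a
dose–response value is uninformative and discarded. Censored relations are
resolved conservatively: `>` above the threshold is inactive, `>` below it
is discarded; symmetrically `<` at/below the threshold is active, `<`
above it is discarded. The symmetric treatment of `<` is a package
decision — censoring direction makes those records uninformative in the
same way.

The 70:30 split stratifies by class and, within each class, apportions
Bemis–Murcko scaffold groups to the test set by largest-remainder
allocation, so class balance (within one compound of the target ratio per
class) and per-class scaffold diversity are both preserved. All randomness
flows through one seed.

## Featurization

Structures are standardized by cleanup, largest-fragment selection and
charge neutralization, then canonicalized; standardization is idempotent.
The descriptor panel is the toolkit's full default 2-D list (~210
descriptors). 3-D descriptors require conformer embedding and are not part
of the default panel. Non-finite descriptor values are recorded as NaN and
imputed by the column median *of the training split only*, so no test-set
information leaks into the imputation.

MACCS matrices drop a configurable exclusion list of key indices (a
12-entry list leaves 154 keys); ECFP4 fingerprints are radius-2 circular
fingerprints folded to a power-of-two length (default 1024).

The custom-fragment catalog pools fragments from four methods:
Bemis–Murcko scaffolds, RECAP and BRICS retrosynthetic leaves, and ring
detachment. Ring detachment is not a named literature algorithm; here it
isolates each fused ring system (rings sharing atoms are kept whole) and
replaces attachment-point neighbours by wildcard atoms, so the emitted
pattern matches any parent substituted at that position but not the bare
ring. Fragments are emitted as SMARTS; link atoms from RECAP/BRICS become
the same wildcard query. Catalog prevalence is counted by substructure
matching (not generation-only) and patterns below `min_count` (default 20
molecules) are excluded; counts at exactly the boundary are retained.

Bit-collision analysis folds the set of distinct unfolded Morgan
atom-environment identifiers of a sampled sub-library modulo the bit
length. The default statistic is the number of folded bits receiving two
or more distinct identifiers; an alternative (`excess_identifiers`,
identifiers minus occupied bits) is selectable. Sampling is stratified by
activity class; under the default statistic the statistic is monotone
non-decreasing in the sampled fraction, and at fraction 1.0 its sd is
exactly zero.

## Training pipeline

The standardized chain is grid search (10-fold stratified CV, scored by
MCC) → recursive feature elimination with CV (step 1 below 100 features,
5% above, for tractability on 1000-bit fingerprints) → a second grid
search restricted to the retained features → final fit with per-fold
accuracy, MCC, precision, recall, F1 and ROC-AUC recorded. Default grids
cover the parameter families that matter for tree ensembles (number of
estimators, depth, minimum samples for split/leaf). Model comparison uses
Friedman's test over matched CV folds, followed — only when the omnibus
test rejects — by pairwise Wilcoxon signed-rank tests with Bonferroni
correction (adjusted p capped at 1) and sign-based effect directions.

## Attributions

SHAP values for scikit-learn ensembles are computed by the package's own
implementation of the exact path-dependent TreeSHAP recursion, validated
in the test suite against a brute-force subset-enumeration Shapley oracle
on small trees. XGBoost models use the booster's native per-feature
contributions (the same algorithm). The explained output is the raw margin
(log-odds) for boosted models, where the per-tree decomposition is exact,
and the predicted positive-class probability for forests — their native
output scale. Additivity (row sum + base value = model output) holds to
float precision and is asserted in tests. Importance summaries rank
features by mean |attribution| with lexicographic tie-breaks; cumulative
milestones use a ≥ comparison, so k features of equal weight reach the 90%
milestone at ceil(0.9 k).

## Scaffold clustering

Murcko scaffolds (acyclic molecules map to a reserved pseudo-scaffold so
no compound is dropped) → ECFP4 Tanimoto distance (1 − similarity; two
empty fingerprints are defined as identical) → UMAP on the precomputed
distances → HDBSCAN on the embedding. The UMAP/HDBSCAN parameter grids are
small documented defaults (neighbours {15, 30}, min_dist {0.0, 0.1},
min_cluster_size {3, 5}); the combination maximizing the silhouette —
computed in the embedded space on non-noise points, where it is
well-defined — is kept. If no combination yields at least two clusters, an
explicit no-structure result places everything in one cluster. Noise
points are then reattached to the cluster maximizing their mean combined
similarity to members (unweighted average of MACCS and ECFP4 Tanimoto,
ties to the lower cluster id), so the final assignment is total.

## Flagging

Class ranges are computed per eligible cluster (≥ 3 molecules, both
activity classes) from **all** cluster members using **true** activity
labels; thresholds, by contrast, use only **correctly predicted**
molecules — the API keeps the two populations explicit. Intervals are
closed on both ends and opposite counts use closed comparisons, matching
the flag rule's "greater than or equal" convention and giving
deterministic boundary behaviour; a value inside both classes' ranges
still counts toward the opposite class.

Quantiles use linear interpolation between order statistics, identically
in the global and per-cluster formulas, so a cluster equal to the global
set reproduces the global threshold exactly. Per-cluster thresholds
require at least three correctly predicted members; sparser clusters fall
back on the global statistic rather than being over-penalized. The
percentile is selected per channel from {80, 85, 90, 95} by 5-fold
cross-validated F1 of misclassification detection (flag = positive,
misclassified = condition), with ties to the lower percentile; when the
data contain no misclassified molecules the selection is reported as
degenerate rather than guessed.

Threshold eligibility additionally requires both prediction classes in the
cluster and at least 10% of features showing non-overlapping class ranges
in some channel (touching intervals count as overlapping). Molecules in
ineligible clusters are never flagged: no evidence, no flag. The four
rules obey exact set algebra (OR = union, AND = intersection), and the
flagged fraction is non-increasing in the percentile.

The wording "max T_C" in some descriptions of the rule is interpreted as
the molecule's own cluster threshold with global fallback; counting
defaults to all retained features, with an optional top-k-by-mean-|SHAP|
subset (k = 20) for prevalence-style analyses — reports state which subset
was used.

## Synthetic worlds and what they show

The feature-world generator emulates the statistical structure the method
assumes: per (cluster, feature), active and inactive compounds occupy
unit-width intervals separated by a gap (`class_separation`, default
0.25), with Gaussian noise (`noise_sd`, default 0.7) on top; a fraction of
compounds (default 0.15) are planted boundary compounds with `k_opposite`
(default 10 of 40) features drawn from the opposite interval. The default
world is 12 clusters × 30 molecules. The gap/noise defaults make the
classes overlap the way noisy assay data do, so a gradient-boosted
classifier is accurate but imperfect and its errors concentrate on the
planted boundary compounds — the generator's defining property. With a
large gap and zero noise the world is perfectly separable and a trained
classifier reaches MCC 1.0.

These worlds are abstract numeric matrices: they exercise the flagging
logic, threshold calibration and confidence interplay, but not chemistry
(no real descriptor correlations, no scaffold/cluster mismatch, no assay
batch effects). Passing the synthetic-recovery checks therefore shows the
machinery is correct and the qualitative enrichment pattern is recoverable
when the assumed structure is present; it does not quantify performance on
real screening data. Problem sizes in the tests and the acceptance script
(108-molecule test sets, 5–10 seeds) were chosen as the smallest at which
the qualitative pattern is stable.

The activity-record generator builds its ground-truth manifest first and
materialises records from it, so curation tests assert against the
manifest rather than re-deriving expectations. It covers each filter
criterion with a dedicated failure case, plants duplicate trios whose
weighted-average-closest member is unique by construction, and includes
percent-inhibition-only inactives and a malformed record. It does not
emulate realistic assay-noise distributions.

## Known limitations

* Per-cluster min–max ranges are extreme statistics: a single outlier
  molecule widens a class range and can hide genuine separation; robust
  (quantile-based) ranges would be a natural extension.
* The opposite count treats features independently; correlated descriptor
  blocks are over-counted relative to their information content.
* Percentile selection needs misclassified molecules in the calibration
  population; very accurate models on small test sets leave it degenerate.
* Path-dependent TreeSHAP attributes with respect to the training
  distribution as encoded in node covers; interventional attributions on
  an explicit background would differ.
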