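# chemflag

Post-hoc flagging of likely-misclassified compounds in tree-ensemble
bioactivity classifiers.

Binary activity classifiers (extra trees, random forests, gradient
boosting, XGBoost) trained on molecular descriptors or fingerprints are
routinely used to triage compounds in virtual screening, but their errors
are not uniformly distributed: compounds near the decision boundary tend
to carry feature values — and SHAP attributions — that fall inside the
range typically occupied by the *opposite* activity class. `chemflag`
turns that observation into an operational filter. For medicinal chemists
and cheminformaticians it provides the full chain: assay-record curation,
four feature representations, a standardized training pipeline, exact
TreeSHAP attributions, scaffold clustering, and the per-cluster
opposite-range flagging rules with hierarchical quantile thresholds.

## The method

Test-set molecules are grouped into structural clusters (Bemis–Murcko
scaffolds → ECFP4 Tanimoto distances → UMAP embedding → HDBSCAN, with
singletons reattached by combined MACCS+ECFP4 similarity). Within each
cluster, for every feature and for both channels — the raw feature value
("RAW") and its SHAP attribution — the min–max interval occupied by each
true activity class is recorded. For a molecule predicted into class *c*,
its **opposite count** *M* is the number of features whose value lies
inside the interval of the other class. Thresholds on *M* are hierarchical
quantiles over correctly predicted molecules:

```
T_global(M) = quantile_p(M_correct)
T_C(M)      = quantile_p(M_correct in C)   if |C| >= 3, else T_global(M)
```

where |C| counts the correctly predicted molecules in cluster *C*, and the
percentile *p* ∈ {80, 85, 90, 95} is chosen per channel by 5-fold
cross-validated F1 of misclassification detection. A molecule is flagged
when its count reaches its cluster threshold (closed comparison), under
four rules: **RAW**, **SHAP**, **RAW OR SHAP** (maximum sensitivity), and
**RAW AND SHAP** (maximum precision). Clusters with fewer than three
correctly classified members, a single prediction class, or fewer than 10%
class-separating features are excluded; their molecules are never flagged.
Flagging composes with `predict_proba`-based confidence filtering and is
evaluated on confidence-stratified populations.

## Worked example

The synthetic feature-world generator plants "boundary" compounds whose
features are partially drawn from the opposite class's intervals — the
structure the method is designed to detect. One call runs the whole
pipeline (generate → train → explain → cluster-wise flagging):

```python
from chemflag.workflow import run_world_experiment

exp = run_world_experiment(seed=42)
print(exp.results.summary())
```

prints

```
Misclassification flagging summary
==================================
molecules (test set):        108
features considered:         40
clusters:                    12 (threshold-eligible: 11)
selected percentile (RAW):   95
selected percentile (SHAP):  95
T_global (RAW):              21.00
T_global (SHAP):             28.00

rule      %flagged misclassified   %flagged correct
raw                   100.0               15.6
shap                  100.0               13.3
or                    100.0               24.4
and                   100.0                4.4
```

Every misclassified test molecule is flagged while only 4–24% of correct
predictions are (AND is the most conservative rule, OR the most
sensitive); the classifier itself reaches a test MCC of 0.835 on this
world. `exp.results` also exposes the per-molecule counts and decisions,
the resolved per-cluster thresholds, the range-separation report, and
`evaluate()` for confidence-stratified percentages.

On real data the same objects are assembled step by step: `curation`
(nine-criterion assay filter, weighted-average deduplication, 10 μM
labeling, diversity-preserving 70:30 split), `featurize` (descriptor
panel, MACCS, ECFP4, custom-fragment fingerprints, bit-collision
analysis), `pipeline` (tune → RFEcv → tune → fit, metrics, Friedman/
Wilcoxon model comparison), `explain`, `cluster` and `flagging` — or via
the `chemflag` command-line interface (`chemflag --help`).

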