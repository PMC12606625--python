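"""Per-molecule Shapley attribution matrices and importance summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureMatrix
from .treeshap import TreeEnsembleExplainer


@dataclass
class ShapMatrix:
    """Signed per-molecule, per-feature attributions in model-output units.

    Each row sums (with ``base_value``) to the model's output for that
    molecule — the additivity axiom of the attribution method.
    """

    molecule_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    base_value: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.feature_names)):
            raise ValueError("shape mismatch between values, ids and feature names")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.molecule_ids, columns=self.feature_names)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# base_value={self.base_value!r}\n")
            self.to_dataframe().to_csv(fh, index_label="molecule_id")

    @classmethod
    def read_csv(cls, path) -> "ShapMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            base = float(header.split("=", 1)[1])
            df = pd.read_csv(fh, index_col="molecule_id")
        df.index = df.index.astype(str)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), base)

    def subset_molecules(self, ids) -> "ShapMatrix":
        pos = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = [pos[str(i)] for i in ids]
        return ShapMatrix([self.molecule_ids[i] for i in idx], list(self.feature_names),
                          self.values[idx].copy(), self.base_value)


def explain_predictions(model, features: FeatureMatrix) -> ShapMatrix:
    """Exact tree-ensemble attributions for every molecule in ``features``.

    ``model`` may be a fitted tree ensemble or a :class:`~chemflag.pipeline.
    TrainedModel`; in the latter case the feature matrix is aligned to the
    model's retained features first. Non-tree models raise ``TypeError``.
    """
    retained = getattr(model, "retained_features", None)
    predictor = getattr(model, "predictor", model)
    if retained is not None:
        missing = [f for f in retained if f not in features.feature_names]
        if missing:
            raise ValueError(f"features missing retained columns: {missing[:5]}")
        features = features.subset_features(list(retained))
    explainer = TreeEnsembleExplainer(predictor)
    phi, base = explainer.shap_values(features.values)
    return ShapMatrix(list(features.molecule_ids), list(features.feature_names), phi, base)


@dataclass
class ShapSummary:
    """Mean-absolute importance ranking with a cumulative-contribution curve."""

    mean_abs: pd.Series                 # indexed by feature, descending
    ranking: list[str]
    cumulative: np.ndarray              # fractions in [0, 1], non-decreasing
    n_features_at: dict = field(default_factory=dict)   # {0.5, 0.75, 0.9} -> int
    pct_nonzero: float = 0.0
    degenerate: bool = False            # all-zero attribution matrix


def shap_summary(shap: ShapMatrix, quantiles=(0.5, 0.75, 0.9)) -> ShapSummary:
    """Rank features by mean |attribution| and locate cumulative milestones.

    ``n_features_at[q]`` is the smallest k such that the top-k features carry
    at least fraction ``q`` of the total mean-absolute attribution. Ties in
    the ranking break lexicographically by feature name. An all-zero matrix
    yields an explicit degenerate summary rather than an error.
    """
    if shap.values.size == 0:
        raise ValueError("empty attribution matrix")
    mean_abs = np.abs(shap.values).mean(axis=0)
    order = sorted(range(len(mean_abs)), key=lambda j: (-mean_abs[j], shap.feature_names[j]))
    ranked = pd.Series(mean_abs[order], index=[shap.feature_names[j] for j in order])
    total = float(ranked.sum())
    if total == 0.0:
        return ShapSummary(mean_abs=ranked, ranking=list(ranked.index),
                           cumulative=np.zeros(len(ranked)), n_features_at={},
                           pct_nonzero=0.0, degenerate=True)
    cumulative = np.cumsum(ranked.to_numpy()) / total
    n_at = {q: int(np.searchsorted(cumulative, q - 1e-12) + 1) for q in quantiles}
    return ShapSummary(
        mean_abs=ranked,
        ranking=list(ranked.index),
        cumulative=cumulative,
        n_features_at=n_at,
        pct_nonzero=float((mean_abs > 0).mean()),
    )


def top_k_features(summary: ShapSummary, k: int = 20) -> list[str]:
    """The k most important features by mean-absolute attribution."""
    return summary.ranking[:k]
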