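"""Tree-ensemble training, evaluation, and model comparison.

The standardized training pipeline is: hyperparameter grid search (10-fold
stratified CV) -> recursive feature elimination with CV -> a second grid
search on the retained features -> final fit with per-fold metrics. Four
algorithms are supported: extra trees (ET), random forest (RF), gradient
boosting (GBM), and XGBoost (XGB).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFECV
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    make_scorer,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_validate
from xgboost import XGBClassifier

from .containers import FeatureMatrix

ALGORITHMS = ("extra_trees", "random_forest", "gradient_boosting", "xgboost")

#: Compact default grids over the parameter families that matter for tree
#: ensembles: number of estimators, tree depth, and minimum samples for
#: splitting / leaf formation.
DEFAULT_GRIDS: dict[str, dict] = {
    "extra_trees": {"n_estimators": [100, 300], "max_depth": [None, 8],
                    "min_samples_split": [2, 5], "min_samples_leaf": [1, 3]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 8],
                      "min_samples_split": [2, 5], "min_samples_leaf": [1, 3]},
    "gradient_boosting": {"n_estimators": [100, 200], "max_depth": [2, 3],
                          "min_samples_split": [2, 5], "min_samples_leaf": [1, 3]},
    "xgboost": {"n_estimators": [100, 200], "max_depth": [3, 6],
                "min_child_weight": [1, 3]},
}

MCC_SCORER = make_scorer(matthews_corrcoef)


def make_estimator(algorithm: str, hyperparameters: dict | None = None, seed: int = 0):
    hp = dict(hyperparameters or {})
    if algorithm == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **hp)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if algorithm == "xgboost":
        hp.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=seed, **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def _cv(cv_folds: int, seed: int) -> StratifiedKFold:
    return StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)


def tune_hyperparameters(
    X, y, algorithm: str, grid: dict | None = None, cv_folds: int = 10,
    seed: int = 0, scoring=MCC_SCORER,
) -> dict:
    """Best grid point by mean stratified-CV score (default scorer: MCC)."""
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    gs = GridSearchCV(make_estimator(algorithm, seed=seed), grid,
                      scoring=scoring, cv=_cv(cv_folds, seed), n_jobs=1)
    gs.fit(np.asarray(X, dtype=float), np.asarray(y))
    return dict(gs.best_params_)


def recursive_feature_elimination_cv(
    X, y, feature_names, algorithm: str = "gradient_boosting",
    hyperparameters: dict | None = None, cv_folds: int = 10, seed: int = 0,
    scoring=MCC_SCORER,
) -> list[str]:
    """Retained feature names after recursive elimination with CV.

    Step size is 1 below 100 features and 5% of the remaining features
    above, which keeps 1000-bit fingerprints tractable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("constant labels: elimination undefined")
    step = 1 if X.shape[1] < 100 else 0.05
    selector = RFECV(make_estimator(algorithm, hyperparameters, seed=seed),
                     step=step, cv=_cv(cv_folds, seed), scoring=scoring,
                     min_features_to_select=1, n_jobs=1)
    selector.fit(X, y)
    names = np.asarray(list(feature_names))
    return list(names[selector.support_])


@dataclass
class TrainedModel:
    algorithm: str
    hyperparameters: dict
    retained_features: list[str]
    fold_metrics: pd.DataFrame
    predictor: object
    seed: int = 0


_FOLD_SCORING = {
    "accuracy": "accuracy",
    "mcc": MCC_SCORER,
    "precision": "precision",
    "recall": "recall",
    "roc_auc": "roc_auc",
    "f1": "f1",
}


def train_classifier(
    features: FeatureMatrix, y, algorithm: str, hyperparameters: dict | None = None,
    cv_folds: int = 10, seed: int = 0,
) -> TrainedModel:
    """Fit the ensemble on the full training set, recording per-fold CV
    metrics (including ROC-AUC on the training CV folds)."""
    est = make_estimator(algorithm, hyperparameters, seed=seed)
    X = features.values
    y = np.asarray(y)
    scores = cross_validate(clone(est), X, y, cv=_cv(cv_folds, seed),
                            scoring=_FOLD_SCORING, n_jobs=1)
    fold_metrics = pd.DataFrame({k: scores[f"test_{k}"] for k in _FOLD_SCORING})
    fold_metrics.index.name = "fold"
    est.fit(X, y)
    return TrainedModel(algorithm=algorithm, hyperparameters=dict(hyperparameters or {}),
                        retained_features=list(features.feature_names),
                        fold_metrics=fold_metrics, predictor=est, seed=seed)


def standard_training_pipeline(
    features: FeatureMatrix, y, algorithm: str, grid: dict | None = None,
    cv_folds: int = 10, seed: int = 0,
) -> TrainedModel:
    """The full tune -> RFEcv -> tune -> fit chain.

    The second tuning round operates only on the retained features.
    """
    hp1 = tune_hyperparameters(features.values, y, algorithm, grid, cv_folds, seed)
    retained = recursive_feature_elimination_cv(
        features.values, y, features.feature_names, algorithm, hp1, cv_folds, seed)
    reduced = features.subset_features(retained)
    hp2 = tune_hyperparameters(reduced.values, y, algorithm, grid, cv_folds, seed)
    return train_classifier(reduced, y, algorithm, hp2, cv_folds, seed)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, MCC, precision, recall and F1 from raw confusion counts."""
    tp, tn, fp, fn = (float(v) for v in (tp, tn, fp, fn))
    n = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else np.nan
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else np.nan
    return {"accuracy": (tp + tn) / n, "mcc": mcc, "precision": precision,
            "recall": recall, "f1": f1}


def evaluate_model(model: TrainedModel, features: FeatureMatrix, y_true, molecule_ids=None):
    """Test-set metrics plus a per-molecule prediction table.

    Returns ``(metrics, predictions)`` where predictions carry the assigned
    class's probability (``class_probability >= 0.5`` in binary problems).
    A single-class test set leaves ROC-AUC as NaN (undefined) but reports
    the confusion-matrix metrics.
    """
    if list(features.feature_names) != list(model.retained_features):
        features = features.subset_features(model.retained_features)
    X = features.values
    y_true = np.asarray(y_true)
    proba = model.predictor.predict_proba(X)
    y_pred = np.asarray(model.predictor.predict(X))
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    metrics = metrics_from_confusion(tp, tn, fp, fn)
    metrics["confusion"] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
    if len(np.unique(y_true)) == 2:
        metrics["roc_auc"] = float(roc_auc_score(y_true, proba[:, 1]))
    else:
        metrics["roc_auc"] = np.nan
    ids = list(molecule_ids) if molecule_ids is not None else list(features.molecule_ids)
    predictions = pd.DataFrame({
        "molecule_id": [str(i) for i in ids],
        "true_label": y_true,
        "predicted_label": y_pred,
        "class_probability": proba[np.arange(len(y_pred)), y_pred.astype(int)],
    })
    return metrics, predictions


def filter_by_confidence(predictions: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Predictions whose assigned-class probability reaches ``threshold``."""
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("confidence threshold must lie in [0.5, 1]")
    return predictions[predictions["class_probability"] >= threshold].copy()


# ---------------------------------------------------------------------------
# Statistical model comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    significant: bool = False


def compare_models(
    fold_metrics: dict[str, np.ndarray], metric: str | None = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Friedman omnibus test over matched CV folds, then pairwise Wilcoxon
    signed-rank tests with Bonferroni correction (adjusted p capped at 1)
    and matched rank-biserial effect sizes."""
    names = list(fold_metrics)
    if len(names) < 3:
        raise ValueError("Friedman's test needs at least 3 models")
    vectors = {}
    for name in names:
        v = fold_metrics[name]
        if isinstance(v, pd.DataFrame):
            if metric is None:
                raise ValueError("metric required when passing fold tables")
            v = v[metric].to_numpy()
        vectors[name] = np.asarray(v, dtype=float)
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("fold counts differ between models")

    arrays = [vectors[n] for n in names]
    if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
        stat, p = 0.0, 1.0  # identical vectors: nothing to reject
    else:
        stat, p = stats.friedmanchisquare(*arrays)
    significant = p < alpha

    rows = []
    if significant:
        n_comp = len(names) * (len(names) - 1) // 2
        for a, b in combinations(names, 2):
            d = vectors[a] - vectors[b]
            if np.allclose(d, 0):
                raw_p, effect = 1.0, 0.0
            else:
                res = stats.wilcoxon(vectors[a], vectors[b])
                raw_p = float(res.pvalue)
                pos = float(np.sum(d[d != 0] > 0))
                nz = float(np.sum(d != 0))
                effect = 2 * pos / nz - 1  # matched rank-biserial direction
            rows.append({"model_a": a, "model_b": b, "raw_p": raw_p,
                         "adjusted_p": min(1.0, raw_p * n_comp),
                         "effect_size": effect})
    return ComparisonReport(friedman_statistic=float(stat), friedman_p=float(p),
                            pairwise=pd.DataFrame(rows), significant=significant)
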