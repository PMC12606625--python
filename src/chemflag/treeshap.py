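"""Exact path-dependent Shapley attributions for tree ensembles.

Implements the polynomial-time TreeSHAP recursion for scikit-learn decision
trees and ensembles built from them, keeping track of the proportion of all
feature subsets that flow down each path together with the fraction that
would flow if the split feature were unknown (weighted by training cover).
For binary classifiers the explained output is:

* random/extra-trees forests — the predicted probability of the positive
  class (the forest's native output scale);
* gradient boosting — the raw margin (log-odds), where the per-tree
  attributions are exact;
* XGBoost — the raw margin via the booster's built-in per-feature
  contributions (the same algorithm, computed natively).

The additivity identity ``sum(phi) + base_value == model_output`` holds to
floating-point precision for every explained row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

try:  # xgboost is an optional backend for the explainer
    from xgboost import XGBClassifier, XGBRegressor
except ImportError:  # pragma: no cover
    XGBClassifier = XGBRegressor = None


@dataclass
class _TreeData:
    children_left: np.ndarray
    children_right: np.ndarray
    features: np.ndarray
    thresholds: np.ndarray
    values: np.ndarray            # scalar output per node
    node_sample_weight: np.ndarray

    def expected_value(self) -> float:
        """Cover-weighted mean leaf value (the tree's base value)."""
        def rec(j: int) -> float:
            if self.children_left[j] < 0:
                return float(self.values[j])
            wl = self.node_sample_weight[self.children_left[j]]
            wr = self.node_sample_weight[self.children_right[j]]
            w = wl + wr
            return (wl * rec(self.children_left[j]) + wr * rec(self.children_right[j])) / w
        return rec(0)


def _extend(path: list[list[float]], pz: float, po: float, pi: int) -> None:
    l = len(path)
    path.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = pz * path[i][3] * (l - i) / (l + 1)


def _unwind(path: list[list[float]], i: int) -> None:
    depth = len(path) - 1
    o, z = path[i][2], path[i][1]
    n = path[depth][3]
    for j in range(depth - 1, -1, -1):
        if o != 0:
            t = path[j][3]
            path[j][3] = n * (depth + 1) / ((j + 1) * o)
            n = t - path[j][3] * z * (depth - j) / (depth + 1)
        else:
            path[j][3] = path[j][3] * (depth + 1) / (z * (depth - j))
    for j in range(i, depth):
        path[j][0] = path[j + 1][0]
        path[j][1] = path[j + 1][1]
        path[j][2] = path[j + 1][2]
    path.pop()


def _unwound_sum(path: list[list[float]], i: int) -> float:
    depth = len(path) - 1
    o, z = path[i][2], path[i][1]
    n = path[depth][3]
    total = 0.0
    for j in range(depth - 1, -1, -1):
        if o != 0:
            t = n * (depth + 1) / ((j + 1) * o)
            total += t
            n = path[j][3] - t * z * (depth - j) / (depth + 1)
        else:
            total += path[j][3] / z / ((depth - j) / (depth + 1))
    return total


def _tree_shap(tree: _TreeData, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(j: int, path: list[list[float]], pz: float, po: float, pi: int) -> None:
        path = [row[:] for row in path]
        _extend(path, pz, po, pi)
        if tree.children_left[j] < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                phi[int(path[i][0])] += w * (path[i][2] - path[i][1]) * tree.values[j]
            return
        f = int(tree.features[j])
        if x[f] <= tree.thresholds[j]:
            hot, cold = tree.children_left[j], tree.children_right[j]
        else:
            hot, cold = tree.children_right[j], tree.children_left[j]
        w = tree.node_sample_weight[j]
        hot_z = tree.node_sample_weight[hot] / w
        cold_z = tree.node_sample_weight[cold] / w
        iz = io = 1.0
        k = next((idx for idx in range(1, len(path)) if int(path[idx][0]) == f), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            _unwind(path, k)
        recurse(int(hot), path, hot_z * iz, io, f)
        recurse(int(cold), path, cold_z * iz, 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def _sklearn_tree_data(estimator, classifier: bool) -> _TreeData:
    t = estimator.tree_
    if classifier:
        counts = t.value[:, 0, :]
        # modern sklearn stores normalised class fractions; older stores counts
        sums = counts.sum(axis=1)
        values = np.where(sums > 0, counts[:, -1] / np.where(sums > 0, sums, 1.0), 0.0)
    else:
        values = t.value[:, 0, 0]
    return _TreeData(
        children_left=t.children_left,
        children_right=t.children_right,
        features=t.feature,
        thresholds=t.threshold,
        values=np.asarray(values, dtype=float),
        node_sample_weight=t.weighted_n_node_samples,
    )


class TreeEnsembleExplainer:
    """Per-feature Shapley attributions for a fitted tree ensemble.

    Parameters
    ----------
    model : fitted estimator
        One of DecisionTree{Classifier,Regressor}, RandomForestClassifier,
        ExtraTreesClassifier, GradientBoostingClassifier (binary), or
        XGBClassifier/XGBRegressor. Anything else raises ``TypeError``.
    """

    def __init__(self, model) -> None:
        self.model = model
        self._kind = self._detect(model)

    @staticmethod
    def _detect(model) -> str:
        if XGBClassifier is not None and isinstance(model, (XGBClassifier, XGBRegressor)):
            return "xgboost"
        if isinstance(model, GradientBoostingClassifier):
            if model.n_classes_ != 2:
                raise TypeError("only binary gradient boosting is supported")
            return "gbm"
        if isinstance(model, (RandomForestClassifier, ExtraTreesClassifier)):
            if model.n_classes_ != 2:
                raise TypeError("only binary forests are supported")
            return "forest"
        if isinstance(model, DecisionTreeClassifier):
            return "tree_clf"
        if isinstance(model, DecisionTreeRegressor):
            return "tree_reg"
        raise TypeError(f"not a supported tree ensemble: {type(model).__name__}")

    # -- expected model output over the training distribution ---------------
    @property
    def base_value(self) -> float:
        return self._base()

    def _base(self) -> float:
        if self._kind == "xgboost":
            import xgboost as xgb

            booster = self.model.get_booster()
            dummy = xgb.DMatrix(np.zeros((1, self.model.n_features_in_)))
            contribs = booster.predict(dummy, pred_contribs=True)
            return float(contribs[0, -1])
        if self._kind == "gbm":
            m = self.model
            init = float(m._raw_predict_init(np.zeros((1, m.n_features_in_)))[0, 0])
            per_tree = sum(
                _sklearn_tree_data(est[0], classifier=False).expected_value()
                for est in m.estimators_
            )
            return init + m.learning_rate * per_tree
        if self._kind == "forest":
            datas = [_sklearn_tree_data(e, classifier=True) for e in self.model.estimators_]
            return float(np.mean([d.expected_value() for d in datas]))
        data = _sklearn_tree_data(self.model, classifier=self._kind == "tree_clf")
        return data.expected_value()

    def shap_values(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """Return ``(phi, base_value)`` with ``phi`` of shape ``X.shape``."""
        X = np.asarray(X, dtype=float)
        if self._kind == "xgboost":
            import xgboost as xgb

            booster = self.model.get_booster()
            contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
            return contribs[:, :-1], float(contribs[0, -1])

        if self._kind == "gbm":
            m = self.model
            trees = [_sklearn_tree_data(est[0], classifier=False) for est in m.estimators_]
            scale = m.learning_rate
            init = float(m._raw_predict_init(X[:1])[0, 0])
            base = init + scale * sum(t.expected_value() for t in trees)
        elif self._kind == "forest":
            trees = [_sklearn_tree_data(e, classifier=True) for e in self.model.estimators_]
            scale = 1.0 / len(trees)
            base = scale * sum(t.expected_value() for t in trees)
        else:
            trees = [_sklearn_tree_data(self.model, classifier=self._kind == "tree_clf")]
            scale = 1.0
            base = trees[0].expected_value()

        phi = np.zeros_like(X)
        for t in trees:
            for i in range(X.shape[0]):
                row_phi = np.zeros(X.shape[1])
                _tree_shap(t, X[i], row_phi)
                phi[i] += scale * row_phi
        return phi, base

    def model_output(self, X: np.ndarray) -> np.ndarray:
        """The output the attributions decompose (margin or probability)."""
        X = np.asarray(X, dtype=float)
        if self._kind == "xgboost":
            return self.model.predict(X, output_margin=True)
        if self._kind == "gbm":
            return self.model.decision_function(X)
        if self._kind == "forest":
            return self.model.predict_proba(X)[:, 1]
        if self._kind == "tree_clf":
            return self.model.predict_proba(X)[:, 1]
        return self.model.predict(X)
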