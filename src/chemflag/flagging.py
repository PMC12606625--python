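"""Opposite-range misclassification flagging with hierarchical quantile
thresholds.

The method: group test-set molecules into structural clusters; within each
cluster record, per feature and per channel ("RAW" feature values and their
SHAP attributions), the min-max interval occupied by each true activity
class. For a molecule predicted into class c, its *opposite count* M is the
number of features whose value lies inside the interval of the other class.
Thresholds on M are hierarchical quantiles::

    T_global(M) = quantile_p(M_correct)                       (global)
    T_C(M)      = quantile_p(M_correct in C)   if |C| >= 3    (per cluster)

with |C| the number of correctly predicted molecules in cluster C; sparse
clusters fall back on the global statistic. The percentile p is picked from
{80, 85, 90, 95} by 5-fold cross-validated F1 of misclassification
detection, independently per channel. A molecule is flagged when its count
reaches its cluster threshold (closed comparison), under four rules: RAW,
SHAP, RAW OR SHAP (maximum sensitivity), RAW AND SHAP (maximum precision).

The public surface follows the model/results idiom:
:class:`MisclassificationFlagger` holds the data, ``fit`` computes ranges,
thresholds and decisions, and returns a :class:`FlaggingResults` carrying
the estimates, diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .containers import FeatureMatrix
from .explain import ShapMatrix

CHANNELS = ("raw", "shap")
RULES = ("raw", "shap", "or", "and")
PERCENTILE_CANDIDATES = (80, 85, 90, 95)


def _as01(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OU":
        return np.asarray([1 if str(v) == "active" else 0 for v in labels])
    return labels.astype(int)


# ---------------------------------------------------------------------------
# Class value ranges
# ---------------------------------------------------------------------------

@dataclass
class ClassRangeTable:
    """Per-(cluster, class, channel) min-max feature intervals.

    ``ranges[cluster][channel][cls]`` is a ``(min_vec, max_vec)`` pair over
    ``feature_names``; entries exist only for *range-eligible* clusters
    (>= 3 molecules, both activity classes represented). Intervals are
    closed on both ends.
    """

    feature_names: list[str]
    ranges: dict = field(default_factory=dict)
    eligibility: dict = field(default_factory=dict)   # cluster -> (bool, reason)

    def eligible_clusters(self) -> list:
        return [c for c, (ok, _) in self.eligibility.items() if ok]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, by_channel in self.ranges.items():
            for channel, by_cls in by_channel.items():
                for cls, (lo, hi) in by_cls.items():
                    for j, f in enumerate(self.feature_names):
                        rows.append({"cluster_id": c, "channel": channel,
                                     "class": "active" if cls == 1 else "inactive",
                                     "feature": f, "min": lo[j], "max": hi[j]})
        return pd.DataFrame(rows)


def class_value_ranges(
    cluster_ids, raw: FeatureMatrix, shap: ShapMatrix, true_labels,
    min_cluster_size: int = 3,
) -> ClassRangeTable:
    """Activity-class-specific min-max ranges per cluster and channel.

    Ranges use the *true* activity labels of all cluster members; clusters
    with fewer than ``min_cluster_size`` molecules or a single class are
    marked ineligible with the reason recorded.
    """
    if list(raw.feature_names) != list(shap.feature_names):
        raise ValueError("raw and shap feature names differ")
    if list(raw.molecule_ids) != list(shap.molecule_ids):
        raise ValueError("raw and shap molecule ids differ")
    y = _as01(true_labels)
    cluster_ids = np.asarray(cluster_ids)
    table = ClassRangeTable(feature_names=list(raw.feature_names))
    mats = {"raw": raw.values, "shap": shap.values}
    for c in np.unique(cluster_ids):
        mask = cluster_ids == c
        if mask.sum() < min_cluster_size:
            table.eligibility[c] = (False, f"fewer than {min_cluster_size} molecules")
            continue
        classes = np.unique(y[mask])
        if len(classes) < 2:
            table.eligibility[c] = (False, "single activity class")
            continue
        table.eligibility[c] = (True, "")
        table.ranges[c] = {}
        for channel, m in mats.items():
            table.ranges[c][channel] = {}
            for cls in (0, 1):
                sub = m[mask & (y == cls)]
                table.ranges[c][channel][cls] = (sub.min(axis=0), sub.max(axis=0))
    return table


# ---------------------------------------------------------------------------
# Opposite counts
# ---------------------------------------------------------------------------

def opposite_counts(
    raw: FeatureMatrix, shap: ShapMatrix, cluster_ids, predicted_labels,
    ranges: ClassRangeTable, feature_subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per molecule: the number of features whose RAW / SHAP value lies
    inside the opposite prediction class's closed interval.

    A value equal to the opposite-class min or max counts; a value inside
    both classes' ranges still counts toward the opposite class. Molecules
    in ineligible clusters (no opposite range available) are marked not
    applicable with NaN counts.
    """
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in ranges.feature_names]
        if missing:
            raise ValueError(f"unknown features in subset: {missing[:5]}")
        cols = [ranges.feature_names.index(f) for f in feature_subset]
    else:
        cols = list(range(len(ranges.feature_names)))
    pred = _as01(predicted_labels)
    cluster_ids = np.asarray(cluster_ids)
    mats = {"raw": raw.values, "shap": shap.values}

    rows = []
    for i, mid in enumerate(raw.molecule_ids):
        c = cluster_ids[i]
        eligible = ranges.eligibility.get(c, (False, "unknown cluster"))[0]
        row = {"molecule_id": mid, "cluster_id": c, "predicted_label": pred[i],
               "n_features_considered": len(cols), "applicable": bool(eligible),
               "raw_count": np.nan, "shap_count": np.nan}
        if eligible:
            opp = 1 - pred[i]
            for channel in CHANNELS:
                lo, hi = ranges.ranges[c][channel][opp]
                v = mats[channel][i, cols]
                row[f"{channel}_count"] = int(((lo[cols] <= v) & (v <= hi[cols])).sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hierarchical quantile thresholds
# ---------------------------------------------------------------------------

def quantile_linear(values, p: float) -> float:
    """Empirical p-th percentile with linear interpolation between order
    statistics (the convention used by both threshold equations)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    return float(np.percentile(values, p, method="linear"))


def global_threshold(counts_correct, p: float) -> float:
    """T_global(M): p-th quantile of opposite counts over correctly
    predicted molecules."""
    return quantile_linear(counts_correct, p)


def cluster_threshold(counts_correct_in_C, p: float, t_global: float) -> float:
    """T_C(M): the cluster's own p-th quantile when it holds >= 3 correctly
    predicted molecules, otherwise the global fallback."""
    counts = np.asarray(counts_correct_in_C, dtype=float)
    if counts.size >= 3:
        return quantile_linear(counts, p)
    return float(t_global)


@dataclass
class PercentileSelection:
    percentile: dict                      # channel -> chosen p
    cv_f1: pd.DataFrame                   # candidate x channel mean CV F1
    degenerate: bool = False              # no misclassified molecules


def select_percentile(
    counts: pd.DataFrame, is_correct, candidates=PERCENTILE_CANDIDATES,
    folds: int = 5, seed: int = 0,
) -> PercentileSelection:
    """Choose p per channel by 5-fold cross-validated F1 of misclassification
    detection (flag = predicted positive, misclassified = true condition).

    Within each fold the threshold is the global quantile of the training
    fold's correct-molecule counts. Ties break to the lower percentile. If
    the data contain no misclassified molecules the selection is degenerate
    and the lowest candidate is reported with NaN scores.
    """
    candidates = sorted(candidates)
    is_correct = np.asarray(is_correct, dtype=bool)
    app = counts["applicable"].to_numpy(dtype=bool)
    if len(is_correct) != len(counts):
        raise ValueError("is_correct length mismatch")
    usable = np.flatnonzero(app)
    if len(usable) < folds:
        raise ValueError(f"need at least {folds} applicable molecules")
    if is_correct[usable].all():
        f1 = pd.DataFrame(np.nan, index=candidates, columns=list(CHANNELS))
        return PercentileSelection(percentile={ch: candidates[0] for ch in CHANNELS},
                                   cv_f1=f1, degenerate=True)

    rng = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = {ch: {p: [] for p in candidates} for ch in CHANNELS}
    for train_pos, val_pos in rng.split(usable):
        train_idx, val_idx = usable[train_pos], usable[val_pos]
        for ch in CHANNELS:
            col = counts[f"{ch}_count"].to_numpy(dtype=float)
            train_correct = col[train_idx][is_correct[train_idx]]
            if train_correct.size == 0:
                continue
            for p in candidates:
                t = global_threshold(train_correct, p)
                flagged = col[val_idx] >= t
                mis = ~is_correct[val_idx]
                tp = np.sum(flagged & mis)
                fp = np.sum(flagged & ~mis)
                fn = np.sum(~flagged & mis)
                denom = 2 * tp + fp + fn
                scores[ch][p].append(2 * tp / denom if denom > 0 else 0.0)

    f1 = pd.DataFrame({ch: [float(np.mean(scores[ch][p])) if scores[ch][p] else np.nan
                            for p in candidates] for ch in CHANNELS}, index=candidates)
    chosen = {}
    for ch in CHANNELS:
        best = f1[ch].to_numpy()
        # ties (and all-NaN columns) resolve to the lowest percentile
        if np.all(np.isnan(best)):
            chosen[ch] = candidates[0]
        else:
            chosen[ch] = candidates[int(np.nanargmax(np.round(best, 12)))]
    return PercentileSelection(percentile=chosen, cv_f1=f1, degenerate=False)


@dataclass
class ThresholdSet:
    """Resolved global and per-cluster thresholds per channel."""

    percentile: dict                      # channel -> p
    t_global: dict                        # channel -> T_global
    t_cluster: dict                       # channel -> {cluster -> threshold}
    source: dict                          # channel -> {cluster -> 'cluster'|'global'}

    def threshold_for(self, channel: str, cluster) -> float:
        return self.t_cluster[channel].get(cluster, self.t_global[channel])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.t_cluster:
            for c, t in self.t_cluster[ch].items():
                rows.append({"channel": ch, "cluster_id": c, "threshold": t,
                             "source": self.source[ch][c]})
        return pd.DataFrame(rows)


def compute_thresholds(
    counts: pd.DataFrame, is_correct, percentile: dict, clusters=None,
) -> ThresholdSet:
    """Eq.-style hierarchical thresholds from applicable correct molecules."""
    is_correct = np.asarray(is_correct, dtype=bool)
    app = counts["applicable"].to_numpy(dtype=bool)
    correct_app = app & is_correct
    if not correct_app.any():
        raise ValueError("no correctly predicted applicable molecules")
    cl = counts["cluster_id"].to_numpy()
    clusters = np.unique(cl[app]) if clusters is None else clusters
    t_global, t_cluster, source = {}, {}, {}
    for ch in CHANNELS:
        p = percentile[ch]
        col = counts[f"{ch}_count"].to_numpy(dtype=float)
        tg = global_threshold(col[correct_app], p)
        t_global[ch] = tg
        t_cluster[ch], source[ch] = {}, {}
        for c in clusters:
            in_c = correct_app & (cl == c)
            t = cluster_threshold(col[in_c], p, tg)
            t_cluster[ch][c] = t
            source[ch][c] = "cluster" if in_c.sum() >= 3 else "global"
    return ThresholdSet(percentile=dict(percentile), t_global=t_global,
                        t_cluster=t_cluster, source=source)


# ---------------------------------------------------------------------------
# Cluster eligibility for thresholding
# ---------------------------------------------------------------------------

def cluster_eligibility(
    cluster: int, counts: pd.DataFrame, is_correct, ranges: ClassRangeTable,
    min_separating_fraction: float = 0.10,
) -> tuple[bool, str]:
    """Threshold-eligibility of one cluster.

    Eligible iff it holds >= 3 correctly classified molecules, both
    prediction classes are present, and at least ``min_separating_fraction``
    of the features show non-overlapping class ranges in some channel. The
    reason names the first failed test.
    """
    if not ranges.eligibility.get(cluster, (False, ""))[0]:
        return False, "range-ineligible cluster"
    mask = counts["cluster_id"].to_numpy() == cluster
    is_correct = np.asarray(is_correct, dtype=bool)
    if (mask & is_correct).sum() < 3:
        return False, "fewer than three correctly classified"
    if len(np.unique(counts.loc[mask, "predicted_label"])) < 2:
        return False, "single prediction class"
    sep = _separating_feature_fraction(ranges, cluster)
    if sep < min_separating_fraction:
        return False, f"separating-feature fraction {sep:.2f} below {min_separating_fraction:.2f}"
    return True, ""


def _nonoverlap(lo_a, hi_a, lo_b, hi_b) -> np.ndarray:
    """Per-feature boolean: closed intervals disjoint (touching = overlap)."""
    return (hi_a < lo_b) | (hi_b < lo_a)


def _separating_feature_fraction(ranges: ClassRangeTable, cluster) -> float:
    """Fraction of features with class-separating (non-overlapping) ranges
    in at least one channel."""
    any_sep = np.zeros(len(ranges.feature_names), dtype=bool)
    for ch in CHANNELS:
        lo0, hi0 = ranges.ranges[cluster][ch][0]
        lo1, hi1 = ranges.ranges[cluster][ch][1]
        any_sep |= _nonoverlap(lo0, hi0, lo1, hi1)
    return float(any_sep.mean())


def range_separation_report(ranges: ClassRangeTable) -> pd.DataFrame:
    """Per feature and channel, the percentage of eligible clusters where
    active and inactive ranges do not overlap, plus a >= 20% marker."""
    clusters = ranges.eligible_clusters()
    if not clusters:
        raise ValueError("no eligible clusters in range table")
    rows = []
    for ch in CHANNELS:
        sep = np.zeros((len(clusters), len(ranges.feature_names)), dtype=bool)
        for k, c in enumerate(clusters):
            lo0, hi0 = ranges.ranges[c][ch][0]
            lo1, hi1 = ranges.ranges[c][ch][1]
            sep[k] = _nonoverlap(lo0, hi0, lo1, hi1)
        pct = 100.0 * sep.mean(axis=0)
        for j, f in enumerate(ranges.feature_names):
            rows.append({"feature": f, "channel": ch, "pct_clusters_nonoverlap": pct[j],
                         "separating_20pct": bool(pct[j] >= 20.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flag decisions and evaluation
# ---------------------------------------------------------------------------

def apply_flagging_rules(
    counts: pd.DataFrame, thresholds: ThresholdSet, eligible_clusters=None,
) -> pd.DataFrame:
    """Four flag booleans per molecule; closed (>=) threshold comparison.

    Molecules in ineligible clusters are never flagged (``applicable``
    False, all flags False).
    """
    eligible = set(eligible_clusters) if eligible_clusters is not None else None
    rows = []
    for _, r in counts.iterrows():
        c = r["cluster_id"]
        ok = bool(r["applicable"]) and (eligible is None or c in eligible)
        if ok and (np.isnan(r["raw_count"]) or np.isnan(r["shap_count"])):
            ok = False
        if ok:
            f_raw = bool(r["raw_count"] >= thresholds.threshold_for("raw", c))
            f_shap = bool(r["shap_count"] >= thresholds.threshold_for("shap", c))
        else:
            f_raw = f_shap = False
        rows.append({"molecule_id": r["molecule_id"], "applicable": ok,
                     "flagged_raw": f_raw, "flagged_shap": f_shap,
                     "flagged_or": f_raw or f_shap, "flagged_and": f_raw and f_shap})
    return pd.DataFrame(rows)


def evaluate_flagging(
    decisions: pd.DataFrame, predictions: pd.DataFrame,
    confidence_thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
    counts: pd.DataFrame | None = None,
) -> dict:
    """Flagging percentages stratified by prediction confidence, plus the
    per-confusion-group opposite-count profile.

    Returns ``{"by_rule": DataFrame, "by_group": DataFrame}``. The by_rule
    table reports, per rule x confidence threshold, the percentage of
    flagged molecules among the misclassified and among the correctly
    classified applicable predictions passing the confidence filter; empty
    strata are reported as NaN (absent), not zero.
    """
    merged = decisions.merge(predictions, on="molecule_id", validate="one_to_one")
    merged = merged[merged["applicable"]]
    mis = _as01(merged["predicted_label"]) != _as01(merged["true_label"])

    rows = []
    for t in confidence_thresholds:
        keep = merged["class_probability"].to_numpy() >= t
        for rule in RULES:
            fl = merged[f"flagged_{rule}"].to_numpy(dtype=bool)
            n_mis = int((keep & mis).sum())
            n_cor = int((keep & ~mis).sum())
            rows.append({
                "rule": rule, "confidence": t,
                "n_misclassified": n_mis, "n_correct": n_cor,
                "pct_flagged_misclassified":
                    100.0 * (fl & keep & mis).sum() / n_mis if n_mis else np.nan,
                "pct_flagged_correct":
                    100.0 * (fl & keep & ~mis).sum() / n_cor if n_cor else np.nan,
            })
    by_rule = pd.DataFrame(rows)

    by_group = pd.DataFrame()
    if counts is not None:
        cm = counts.merge(predictions, on="molecule_id", validate="one_to_one")
        cm = cm[cm["applicable"]]
        pred = _as01(cm["predicted_label_x" if "predicted_label_x" in cm else "predicted_label"])
        true = _as01(cm["true_label"])
        groups = {"TP": (pred == 1) & (true == 1), "TN": (pred == 0) & (true == 0),
                  "FP": (pred == 1) & (true == 0), "FN": (pred == 0) & (true == 1)}
        grows = []
        for g, gmask in groups.items():
            if gmask.sum() == 0:
                continue
            grows.append({
                "group": g, "n": int(gmask.sum()),
                "raw_mean": float(cm.loc[gmask, "raw_count"].mean()),
                "raw_sd": float(cm.loc[gmask, "raw_count"].std(ddof=0)),
                "shap_mean": float(cm.loc[gmask, "shap_count"].mean()),
                "shap_sd": float(cm.loc[gmask, "shap_count"].std(ddof=0)),
            })
        by_group = pd.DataFrame(grows)
    return {"by_rule": by_rule, "by_group": by_group}


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class MisclassificationFlagger:
    """Post-hoc misclassification flagging model for one test set.

    Parameters
    ----------
    raw : FeatureMatrix
        Test-set feature values (the model's retained features).
    shap : ShapMatrix
        Matching per-molecule attributions (same ids and feature names).
    cluster_ids : array-like
        Structural cluster of each molecule (aligned with ``raw`` rows).
    predictions : DataFrame
        Columns ``molecule_id, true_label, predicted_label,
        class_probability`` as produced by the evaluation step.
    percentile_candidates : iterable of int
        Candidate percentiles for the hierarchical quantile thresholds.
    min_separating_fraction : float
        Minimum fraction of class-separating features a cluster needs to be
        threshold-eligible.
    feature_subset : list of str, optional
        Restrict counting to these features (e.g. the top 20 by mean
        absolute attribution); default all retained features.
    """

    def __init__(self, raw, shap, cluster_ids, predictions,
                 percentile_candidates=PERCENTILE_CANDIDATES,
                 min_separating_fraction: float = 0.10,
                 feature_subset: list[str] | None = None) -> None:
        order = {str(m): i for i, m in enumerate(raw.molecule_ids)}
        missing = [m for m in predictions["molecule_id"].astype(str) if m not in order]
        if missing:
            raise ValueError(f"predictions contain unknown molecules: {missing[:5]}")
        self.raw = raw
        self.shap = shap
        self.cluster_ids = np.asarray(cluster_ids)
        self.predictions = predictions.copy()
        self.predictions["molecule_id"] = self.predictions["molecule_id"].astype(str)
        self.predictions = self.predictions.set_index("molecule_id").loc[list(raw.molecule_ids)].reset_index()
        self.percentile_candidates = tuple(percentile_candidates)
        self.min_separating_fraction = float(min_separating_fraction)
        self.feature_subset = feature_subset

    def fit(self, seed: int = 0, percentile: dict | None = None) -> "FlaggingResults":
        """Compute ranges, counts, thresholds and flag decisions.

        ``percentile`` may pin the quantile per channel (e.g. ``{"raw": 80,
        "shap": 85}``); by default it is selected by cross-validation.
        """
        true = _as01(self.predictions["true_label"])
        pred = _as01(self.predictions["predicted_label"])
        is_correct = true == pred

        ranges = class_value_ranges(self.cluster_ids, self.raw, self.shap, true)
        counts = opposite_counts(self.raw, self.shap, self.cluster_ids, pred,
                                 ranges, self.feature_subset)

        eligibility = {}
        for c in np.unique(self.cluster_ids):
            eligibility[c] = cluster_eligibility(
                c, counts, is_correct, ranges, self.min_separating_fraction)
        eligible = [c for c, (ok, _) in eligibility.items() if ok]
        if not eligible:
            raise ValueError("no threshold-eligible clusters")

        # thresholds are built from correctly predicted molecules in
        # threshold-eligible clusters only
        in_eligible = np.isin(counts["cluster_id"].to_numpy(), eligible)
        counts_eff = counts.copy()
        counts_eff["applicable"] = counts_eff["applicable"].to_numpy() & in_eligible

        if percentile is None:
            selection = select_percentile(counts_eff, is_correct,
                                          self.percentile_candidates, seed=seed)
            percentile = selection.percentile
        else:
            selection = PercentileSelection(percentile=dict(percentile),
                                            cv_f1=pd.DataFrame(), degenerate=False)
        thresholds = compute_thresholds(counts_eff, is_correct, percentile,
                                        clusters=eligible)
        decisions = apply_flagging_rules(counts_eff, thresholds, eligible)
        return FlaggingResults(model=self, ranges=ranges, counts=counts_eff,
                               thresholds=thresholds, decisions=decisions,
                               percentile_selection=selection,
                               cluster_eligibility=eligibility, seed=seed)


@dataclass
class FlaggingResults:
    """Fitted thresholds, per-molecule decisions, and evaluation helpers."""

    model: MisclassificationFlagger
    ranges: ClassRangeTable
    counts: pd.DataFrame
    thresholds: ThresholdSet
    decisions: pd.DataFrame
    percentile_selection: PercentileSelection
    cluster_eligibility: dict
    seed: int = 0

    def flagged_ids(self, rule: str = "or") -> list[str]:
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule!r}")
        d = self.decisions
        return d.loc[d[f"flagged_{rule}"], "molecule_id"].tolist()

    def evaluate(self, confidence_thresholds=(0.5, 0.6, 0.7, 0.8, 0.9)) -> dict:
        return evaluate_flagging(self.decisions, self.model.predictions,
                                 confidence_thresholds, counts=self.counts)

    def separation_report(self) -> pd.DataFrame:
        return range_separation_report(self.ranges)

    def summary(self) -> str:
        n_eligible = sum(ok for ok, _ in self.cluster_eligibility.values())
        ev = self.evaluate(confidence_thresholds=(0.5,))["by_rule"]
        lines = [
            "Misclassification flagging summary",
            "==================================",
            f"molecules (test set):        {self.model.raw.n_molecules}",
            f"features considered:         {self.counts['n_features_considered'].iloc[0]}",
            f"clusters:                    {len(self.cluster_eligibility)}"
            f" (threshold-eligible: {n_eligible})",
            f"selected percentile (RAW):   {self.thresholds.percentile['raw']}",
            f"selected percentile (SHAP):  {self.thresholds.percentile['shap']}",
            f"T_global (RAW):              {self.thresholds.t_global['raw']:.2f}",
            f"T_global (SHAP):             {self.thresholds.t_global['shap']:.2f}",
            "",
            "rule      %flagged misclassified   %flagged correct",
        ]
        for rule in RULES:
            r = ev[ev["rule"] == rule].iloc[0]
            lines.append(f"{rule:<9} {r['pct_flagged_misclassified']:>17.1f}"
                         f"   {r['pct_flagged_correct']:>16.1f}")
        return "\n".join(lines)
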