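"""Opposite-range flagging: ranges, counts, thresholds, rules, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemflag.containers import FeatureMatrix
from chemflag.explain import ShapMatrix
from chemflag.flagging import (
    MisclassificationFlagger,
    ThresholdSet,
    apply_flagging_rules,
    class_value_ranges,
    cluster_eligibility,
    cluster_threshold,
    compute_thresholds,
    evaluate_flagging,
    global_threshold,
    opposite_counts,
    quantile_linear,
    range_separation_report,
    select_percentile,
)
from conftest import make_predictions


def _fm(values, names=None, ids=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    ids = ids or [f"m{i}" for i in range(values.shape[0])]
    return FeatureMatrix(ids, names, values)


def _sm(values, names=None, ids=None):
    fm = _fm(values, names, ids)
    return ShapMatrix(fm.molecule_ids, fm.feature_names, fm.values, base_value=0.0)


class TestClassRanges:
    def test_hand_min_max(self):
        vals = np.array([[1.0], [2.0], [5.0], [7.0], [9.0]])
        ranges = class_value_ranges(
            cluster_ids=[0] * 5, raw=_fm(vals), shap=_sm(vals * 10),
            true_labels=[1, 1, 1, 0, 0])
        lo, hi = ranges.ranges[0]["raw"][1]
        assert (lo[0], hi[0]) == (1.0, 5.0)
        lo, hi = ranges.ranges[0]["raw"][0]
        assert (lo[0], hi[0]) == (7.0, 9.0)
        lo, hi = ranges.ranges[0]["shap"][0]
        assert (lo[0], hi[0]) == (70.0, 90.0)

    def test_single_class_cluster_ineligible(self):
        vals = np.ones((3, 2))
        ranges = class_value_ranges([0, 0, 0], _fm(vals), _sm(vals), [1, 1, 1])
        assert ranges.eligibility[0] == (False, "single activity class")
        assert 0 not in ranges.ranges

    def test_small_cluster_ineligible(self):
        vals = np.ones((2, 2))
        ranges = class_value_ranges([0, 0], _fm(vals), _sm(vals), [1, 0])
        ok, reason = ranges.eligibility[0]
        assert not ok and "fewer than 3" in reason

    def test_value_inside_range_leaves_range_unchanged(self):
        base = np.array([[1.0], [5.0], [7.0], [9.0]])
        extended = np.vstack([base, [[3.0]]])  # inside active range [1, 5]
        r1 = class_value_ranges([0] * 4, _fm(base), _sm(base), [1, 1, 0, 0])
        r2 = class_value_ranges([0] * 5, _fm(extended), _sm(extended), [1, 1, 0, 0, 1])
        assert r1.ranges[0]["raw"][1][0] == r2.ranges[0]["raw"][1][0]
        assert r1.ranges[0]["raw"][1][1] == r2.ranges[0]["raw"][1][1]

    def test_feature_name_mismatch_errors(self):
        with pytest.raises(ValueError):
            class_value_ranges([0, 0, 0], _fm(np.ones((3, 1)), ["a"]),
                               _sm(np.ones((3, 1)), ["b"]), [1, 0, 1])


def _range_world():
    """4 actives + 4 inactives in one cluster, 6 features with known ranges."""
    rng = np.random.default_rng(0)
    raw = np.vstack([rng.uniform(0, 1, (4, 6)), rng.uniform(2, 3, (4, 6))])
    shap = np.vstack([rng.uniform(-1, 0, (4, 6)), rng.uniform(1, 2, (4, 6))])
    labels = [1, 1, 1, 1, 0, 0, 0, 0]
    return raw, shap, labels


class TestOppositeCounts:
    def test_all_outside_zero(self):
        raw, shap, labels = _range_world()
        ranges = class_value_ranges([0] * 8, _fm(raw), _sm(shap), labels)
        counts = opposite_counts(_fm(raw), _sm(shap), [0] * 8, labels, ranges)
        # every molecule predicted into its own class: nothing in the
        # opposite interval by construction
        assert (counts["raw_count"] == 0).all()
        assert (counts["shap_count"] == 0).all()

    def test_hand_fixture_two_and_three(self):
        raw, shap, labels = _range_world()
        # molecule 0 (active): push 2 raw features and 3 shap features into
        # the inactive ranges
        raw[0, :2] = 2.5
        shap[0, :3] = 1.5
        ranges = class_value_ranges([0] * 8, _fm(raw), _sm(shap), labels)
        counts = opposite_counts(_fm(raw), _sm(shap), [0] * 8, labels, ranges)
        row = counts.iloc[0]
        assert (row["raw_count"], row["shap_count"]) == (2, 3)

    def test_boundary_value_counts_closed_interval(self):
        raw = np.array([[1.0], [2.0], [7.0], [9.0]])
        shap = np.zeros((4, 1))
        labels = [1, 1, 0, 0]
        ranges = class_value_ranges([0] * 4, _fm(raw), _sm(shap), labels)
        # active molecule whose raw value equals the inactive max (9.0)
        raw2 = raw.copy(); raw2[0, 0] = 9.0
        counts = opposite_counts(_fm(raw2), _sm(shap), [0] * 4, labels, ranges)
        assert counts.iloc[0]["raw_count"] == 1

    def test_ineligible_cluster_not_applicable(self):
        vals = np.ones((3, 2))
        ranges = class_value_ranges([0, 0, 0], _fm(vals), _sm(vals), [1, 1, 1])
        counts = opposite_counts(_fm(vals), _sm(vals), [0, 0, 0], [1, 1, 1], ranges)
        assert (~counts["applicable"]).all()
        assert counts["raw_count"].isna().all()

    def test_exhaustive_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n, k = 20, 5
            raw = rng.normal(size=(n, k))
            shap = rng.normal(size=(n, k))
            labels = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            clusters = rng.integers(0, 3, n)
            if len(np.unique(labels)) < 2:
                continue
            ranges = class_value_ranges(clusters, _fm(raw), _sm(shap), labels)
            counts = opposite_counts(_fm(raw), _sm(shap), clusters, pred, ranges)
            for i in range(n):
                c = clusters[i]
                if not ranges.eligibility.get(c, (False, ""))[0]:
                    assert not counts.iloc[i]["applicable"]
                    continue
                opp = 1 - pred[i]
                for channel, mat in (("raw", raw), ("shap", shap)):
                    lo, hi = ranges.ranges[c][channel][opp]
                    expect = sum(1 for j in range(k) if lo[j] <= mat[i, j] <= hi[j])
                    assert counts.iloc[i][f"{channel}_count"] == expect


def _sorted_quantile_oracle(values, p):
    """Independent sort-and-interpolate quantile (linear convention)."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    h = (len(v) - 1) * p / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


class TestThresholds:
    def test_constant_counts_any_percentile(self):
        for p in (80, 85, 90, 95):
            assert global_threshold([4, 4, 4, 4], p) == 4.0

    def test_counts_one_to_ten_p80(self):
        assert global_threshold(list(range(1, 11)), 80) == pytest.approx(8.2)

    def test_single_value(self):
        assert global_threshold([7], 95) == 7.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            global_threshold([], 80)

    def test_small_cluster_falls_back_to_global(self):
        assert cluster_threshold([3, 9], 80, t_global=5.5) == 5.5

    def test_three_member_cluster_own_quantile(self):
        assert cluster_threshold([1, 2, 9], 80, t_global=0.0) == \
            pytest.approx(_sorted_quantile_oracle([1, 2, 9], 80))

    def test_cluster_equal_to_global_set(self):
        counts = [0, 1, 1, 2, 3, 5, 8]
        for p in (80, 85, 90, 95):
            tg = global_threshold(counts, p)
            assert cluster_threshold(counts, p, tg) == tg

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=60),
           st.sampled_from([80, 85, 90, 95]))
    def test_quantile_equals_sort_and_interpolate_oracle(self, counts, p):
        assert quantile_linear(counts, p) == pytest.approx(
            _sorted_quantile_oracle(counts, p), abs=1e-9)


class TestPercentileSelection:
    def _counts(self, values, clusters=None, applicable=True):
        n = len(values)
        return pd.DataFrame({
            "molecule_id": [f"m{i}" for i in range(n)],
            "cluster_id": clusters if clusters is not None else [0] * n,
            "predicted_label": [1] * n,
            "raw_count": values, "shap_count": values,
            "n_features_considered": [10] * n,
            "applicable": [applicable] * n,
        })

    def test_single_candidate_returned(self):
        counts = self._counts([1, 2, 3, 1, 2, 9, 8, 9, 1, 2])
        correct = [True] * 5 + [False] * 3 + [True] * 2
        sel = select_percentile(counts, correct, candidates=[90], seed=0)
        assert sel.percentile == {"raw": 90, "shap": 90}

    def test_planted_gap_prefers_discriminating_percentile(self):
        # correct counts 0..3; misclassified counts ~5: the 80th percentile
        # of correct counts separates them, the 95th overshoots less cleanly
        rng = np.random.default_rng(0)
        correct_counts = rng.integers(0, 4, 40)
        mis_counts = rng.integers(4, 7, 10)
        counts = self._counts(np.concatenate([correct_counts, mis_counts]))
        correct = [True] * 40 + [False] * 10
        sel = select_percentile(counts, correct, seed=0)
        f1 = sel.cv_f1
        assert f1.loc[sel.percentile["raw"], "raw"] == f1["raw"].max()

    def test_exact_tie_takes_lower_percentile(self):
        # correct counts constant: all candidate thresholds coincide -> tie
        counts = self._counts([2] * 15 + [9] * 5)
        correct = [True] * 15 + [False] * 5
        sel = select_percentile(counts, correct, seed=0)
        assert sel.percentile["raw"] == 80

    def test_no_misclassified_degenerate(self):
        counts = self._counts([1, 2, 3, 4, 5, 6])
        sel = select_percentile(counts, [True] * 6, seed=0)
        assert sel.degenerate and sel.percentile["raw"] == 80


class TestEligibility:
    def _setup(self, labels, pred, clusters, sep_features=1.0):
        rng = np.random.default_rng(1)
        n, k = len(labels), 10
        raw = np.empty((n, k))
        n_sep = int(round(sep_features * k))
        for i, y in enumerate(labels):
            raw[i, :n_sep] = rng.uniform(0, 1) + (0 if y else 5)
            raw[i, n_sep:] = rng.uniform(0, 1)  # overlapping features
        ranges = class_value_ranges(clusters, _fm(raw), _sm(raw), labels)
        counts = opposite_counts(_fm(raw), _sm(raw), clusters, pred, ranges)
        return ranges, counts

    def test_two_correct_members_ineligible(self):
        labels = [1, 1, 0, 0]
        pred = [1, 0, 1, 0]  # only 2 correct
        ranges, counts = self._setup(labels, pred, [0] * 4)
        ok, reason = cluster_eligibility(0, counts, np.array(labels) == np.array(pred),
                                         ranges)
        assert not ok and "fewer than three" in reason

    def test_single_prediction_class_ineligible(self):
        labels = [1, 1, 0, 0, 1]
        pred = [1, 1, 1, 1, 1]
        ranges, counts = self._setup(labels, pred, [0] * 5)
        ok, reason = cluster_eligibility(0, counts, np.array(labels) == np.array(pred),
                                         ranges)
        assert not ok and "single prediction class" in reason

    def test_insufficient_separating_features_ineligible(self):
        labels = [1, 1, 1, 0, 0, 0]
        pred = list(labels)
        pred[0], pred[3] = 0, 1  # both prediction classes, 4 correct
        ranges, counts = self._setup(labels, pred, [0] * 6, sep_features=0.0)
        ok, reason = cluster_eligibility(0, counts, np.array(labels) == np.array(pred),
                                         ranges)
        assert not ok and "separating" in reason

    def test_fully_separated_cluster_eligible(self):
        labels = [1, 1, 1, 0, 0, 0]
        pred = list(labels)
        pred[0], pred[3] = 0, 1
        ranges, counts = self._setup(labels, pred, [0] * 6, sep_features=1.0)
        ok, _ = cluster_eligibility(0, counts, np.array(labels) == np.array(pred),
                                    ranges)
        assert ok


def _threshold_set(t_raw, t_shap, clusters=(0,)):
    return ThresholdSet(percentile={"raw": 80, "shap": 80},
                        t_global={"raw": t_raw, "shap": t_shap},
                        t_cluster={"raw": {c: t_raw for c in clusters},
                                   "shap": {c: t_shap for c in clusters}},
                        source={"raw": {c: "cluster" for c in clusters},
                                "shap": {c: "cluster" for c in clusters}})


class TestRules:
    def _counts(self, raw, shap):
        n = len(raw)
        return pd.DataFrame({
            "molecule_id": [f"m{i}" for i in range(n)],
            "cluster_id": [0] * n, "predicted_label": [1] * n,
            "raw_count": raw, "shap_count": shap,
            "n_features_considered": [10] * n, "applicable": [True] * n,
        })

    def test_count_equal_to_threshold_flags(self):
        d = apply_flagging_rules(self._counts([5], [0]), _threshold_set(5, 5))
        assert d.iloc[0]["flagged_raw"] and not d.iloc[0]["flagged_shap"]

    def test_truth_table_enumeration(self):
        raw = [0, 0, 5, 5, 3, 7, 5, 9]
        shap = [0, 5, 0, 5, 7, 3, 9, 9]
        d = apply_flagging_rules(self._counts(raw, shap), _threshold_set(5, 5))
        for i in range(8):
            fr, fs = raw[i] >= 5, shap[i] >= 5
            assert d.iloc[i]["flagged_raw"] == fr
            assert d.iloc[i]["flagged_shap"] == fs
            assert d.iloc[i]["flagged_or"] == (fr or fs)
            assert d.iloc[i]["flagged_and"] == (fr and fs)

    def test_rule_algebra_subsets(self):
        rng = np.random.default_rng(0)
        d = apply_flagging_rules(
            self._counts(rng.integers(0, 10, 50), rng.integers(0, 10, 50)),
            _threshold_set(6, 4))
        AND = set(d.loc[d["flagged_and"], "molecule_id"])
        OR = set(d.loc[d["flagged_or"], "molecule_id"])
        RAW = set(d.loc[d["flagged_raw"], "molecule_id"])
        SHAP = set(d.loc[d["flagged_shap"], "molecule_id"])
        assert AND == RAW & SHAP and OR == RAW | SHAP
        assert AND <= RAW <= OR and AND <= SHAP <= OR

    def test_ineligible_cluster_never_flagged(self):
        counts = self._counts([9], [9])
        d = apply_flagging_rules(counts, _threshold_set(1, 1), eligible_clusters=[])
        assert not d.iloc[0]["applicable"] and not d.iloc[0]["flagged_or"]

    def test_flagged_fraction_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        n = 60
        counts = self._counts(rng.integers(0, 15, n), rng.integers(0, 15, n))
        correct = rng.random(n) < 0.8
        fractions = []
        for p in (80, 85, 90, 95):
            ts = compute_thresholds(counts, correct, {"raw": p, "shap": p})
            d = apply_flagging_rules(counts, ts)
            fractions.append(d["flagged_or"].mean())
        assert all(b <= a + 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestSeparationReport:
    def _ranges(self, cluster_specs):
        """cluster_specs: list of (active_lo, active_hi, inact_lo, inact_hi)."""
        from chemflag.flagging import ClassRangeTable

        t = ClassRangeTable(feature_names=["f0"])
        for c, (alo, ahi, ilo, ihi) in enumerate(cluster_specs):
            t.eligibility[c] = (True, "")
            t.ranges[c] = {ch: {1: (np.array([alo]), np.array([ahi])),
                                0: (np.array([ilo]), np.array([ihi]))}
                           for ch in ("raw", "shap")}
        return t

    def test_disjoint_everywhere_100pct(self):
        rep = range_separation_report(self._ranges([(0, 1, 2, 3)] * 3))
        assert (rep["pct_clusters_nonoverlap"] == 100.0).all()

    def test_one_of_four_clusters_25pct(self):
        specs = [(0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 2, 5), (1, 4, 2, 3)]
        rep = range_separation_report(self._ranges(specs))
        assert (rep["pct_clusters_nonoverlap"] == 25.0).all()
        assert not rep["separating_20pct"].eq(False).all()

    def test_touching_ranges_count_as_overlap(self):
        rep = range_separation_report(self._ranges([(0, 1, 1, 2)]))
        assert (rep["pct_clusters_nonoverlap"] == 0.0).all()


class TestEvaluate:
    def _decisions(self, flags, applicable=None):
        n = len(flags)
        applicable = applicable if applicable is not None else [True] * n
        return pd.DataFrame({
            "molecule_id": [f"m{i}" for i in range(n)], "applicable": applicable,
            "flagged_raw": flags, "flagged_shap": flags,
            "flagged_or": flags, "flagged_and": flags,
        })

    def test_perfect_flagging(self):
        true = [1, 1, 0, 0]
        pred = [0, 0, 0, 0]  # first two misclassified
        d = self._decisions([True, True, False, False])
        preds = make_predictions([f"m{i}" for i in range(4)], true, pred)
        rep = evaluate_flagging(d, preds, confidence_thresholds=(0.5,))["by_rule"]
        assert (rep["pct_flagged_misclassified"] == 100.0).all()
        assert (rep["pct_flagged_correct"] == 0.0).all()

    def test_hand_percentages(self):
        # 4 misclassified (2 flagged), 6 correct (1 flagged)
        true = [1] * 4 + [0] * 6
        pred = [0] * 4 + [0] * 6
        flags = [True, True, False, False, True] + [False] * 5
        d = self._decisions(flags)
        preds = make_predictions([f"m{i}" for i in range(10)], true, pred)
        rep = evaluate_flagging(d, preds, confidence_thresholds=(0.5,))["by_rule"]
        r = rep.iloc[0]
        assert r["pct_flagged_misclassified"] == pytest.approx(50.0)
        assert r["pct_flagged_correct"] == pytest.approx(100 / 6)

    def test_confidence_strata_nested(self):
        rng = np.random.default_rng(0)
        n = 40
        true = rng.integers(0, 2, n)
        pred = rng.integers(0, 2, n)
        proba = rng.uniform(0.5, 1.0, n)
        d = self._decisions(list(rng.random(n) < 0.3))
        preds = make_predictions([f"m{i}" for i in range(n)], true, pred, proba)
        rep = evaluate_flagging(d, preds)["by_rule"]
        for rule in ("raw", "or"):
            sub = rep[rep["rule"] == rule].sort_values("confidence")
            totals = (sub["n_misclassified"] + sub["n_correct"]).to_numpy()
            assert (np.diff(totals) <= 0).all()

    def test_empty_stratum_reported_absent(self):
        d = self._decisions([True, False])
        preds = make_predictions(["m0", "m1"], [1, 1], [1, 1], [0.6, 0.6])
        rep = evaluate_flagging(d, preds, confidence_thresholds=(0.9,))["by_rule"]
        assert rep["n_misclassified"].eq(0).all()
        assert rep["pct_flagged_misclassified"].isna().all()


class TestFlaggerModel:
    def test_fit_on_small_world_flags_boundary_enriched(self, small_world):
        """On a world with planted boundary compounds, using ground-truth
        clusters and a perfect 'prediction' corrupted on boundary compounds,
        the flagged set is enriched for the corrupted molecules."""
        w = small_world
        shap = _sm(w.features.values, names=w.features.feature_names,
                   ids=w.features.molecule_ids)
        pred = w.labels.copy()
        flip = w.boundary_mask & (np.random.default_rng(0).random(len(pred)) < 0.7)
        pred[flip] = 1 - pred[flip]
        preds = make_predictions(w.features.molecule_ids, w.labels, pred)
        flagger = MisclassificationFlagger(w.features, shap, w.cluster_ids, preds)
        res = flagger.fit(seed=0)
        ev = res.evaluate(confidence_thresholds=(0.5,))["by_rule"]
        r = ev[ev["rule"] == "or"].iloc[0]
        assert r["pct_flagged_misclassified"] > r["pct_flagged_correct"]
        assert "Misclassification flagging summary" in res.summary()

    def test_pinned_percentile_respected(self, small_world):
        w = small_world
        shap = _sm(w.features.values, names=w.features.feature_names,
                   ids=w.features.molecule_ids)
        pred = w.labels.copy()
        pred[:10] = 1 - pred[:10]
        preds = make_predictions(w.features.molecule_ids, w.labels, pred)
        flagger = MisclassificationFlagger(w.features, shap, w.cluster_ids, preds)
        res = flagger.fit(seed=0, percentile={"raw": 95, "shap": 85})
        assert res.thresholds.percentile == {"raw": 95, "shap": 85}

    def test_unknown_molecule_in_predictions_errors(self, small_world):
        w = small_world
        shap = _sm(w.features.values, names=w.features.feature_names,
                   ids=w.features.molecule_ids)
        preds = make_predictions(["ghost"], [1], [1])
        with pytest.raises(ValueError, match="ghost"):
            MisclassificationFlagger(w.features, shap, w.cluster_ids, preds)
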