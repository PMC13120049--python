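"""Split arithmetic, tuning contracts, aggregation, and sweep plumbing."""

import numpy as np
import pandas as pd
import pytest

from _oracles import two_stage_mean
from conftest import prepared_micro
from emgstress.degrade import DegradationSpec
from emgstress.evaluate import (
    ClassifierSpec,
    chance_level,
    make_stratified_splits,
    run_condition,
    run_sweep,
    summarize,
    tune_and_fit,
)
from emgstress.evaluate import test_accuracy as compute_accuracy
from emgstress.features import FeatureSpec


class TestStratifiedSplits:
    def test_exact_divisibility_case(self):
        labels = np.repeat(["a", "b", "c", "d"], 100)
        plan = make_stratified_splits(labels, n_repeats=3, seed=0)
        for tr, va, te in plan.repeats:
            assert (len(tr), len(va), len(te)) == (280, 60, 60)
            assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
            assert len(tr) + len(va) + len(te) == 400
            for part, size in ((tr, 70), (va, 15), (te, 15)):
                _, counts = np.unique(labels[part], return_counts=True)
                assert np.all(counts == size)

    def test_same_seed_reproduces_plan(self):
        labels = np.repeat(["a", "b", "c"], 40)
        p1 = make_stratified_splits(labels, 4, seed=9)
        p2 = make_stratified_splits(labels, 4, seed=9)
        for (a1, b1, c1), (a2, b2, c2) in zip(p1.repeats, p2.repeats):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(c1, c2)

    def test_repeats_differ(self):
        labels = np.repeat(["a", "b"], 50)
        plan = make_stratified_splits(labels, 2, seed=1)
        assert not np.array_equal(np.sort(plan.repeats[0][2]), np.sort(plan.repeats[1][2]))

    def test_stratification_on_random_multisets(self, rng):
        for _ in range(20):
            n_classes = int(rng.integers(2, 6))
            counts = rng.integers(20, 60, size=n_classes)
            labels = np.concatenate(
                [np.full(c, f"g{i}") for i, c in enumerate(counts)]
            )
            plan = make_stratified_splits(labels, 1, seed=int(rng.integers(1000)))
            _, _, te = plan.repeats[0]
            for i, c in enumerate(counts):
                frac = np.count_nonzero(labels[te] == f"g{i}") / c
                assert abs(frac - 0.15) < 1.0 / c + 1e-9

    def test_tiny_class_error_names_class(self):
        labels = np.array(["big"] * 50 + ["rare"] * 2)
        with pytest.raises(ValueError, match="rare"):
            make_stratified_splits(labels)


def _blobs(rng, n=200, centers=(-3.0, 3.0)):
    X = np.concatenate(
        [rng.normal(c, 1.0, size=(n // 2, 2)) for c in centers]
    )
    y = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    idx = rng.permutation(n)
    return X[idx], y[idx]


class TestTuneAndFit:
    def test_single_grid_point_chosen(self, rng):
        X, y = _blobs(rng)
        spec = ClassifierSpec("rf", grid={"n_estimators": [10]})
        _, params = tune_and_fit(spec, X[:100], y[:100], X[100:], y[100:])
        assert params == {"n_estimators": 10}

    def test_ties_broken_by_grid_order(self, rng):
        X, y = _blobs(rng)
        # two identical settings expressed as duplicate grid values
        spec = ClassifierSpec("svm-rbf", grid={"C": [1, 1], "gamma": [0.1]})
        model, params = tune_and_fit(spec, X[:100], y[:100], X[100:], y[100:])
        assert params == {"C": 1, "gamma": 0.1}

    @pytest.mark.parametrize("kind", ["svm-rbf", "lda", "rf"])
    def test_separable_blobs_reach_perfect_validation(self, kind, rng):
        X, y = _blobs(rng)
        spec = ClassifierSpec(kind)
        model, _ = tune_and_fit(spec, X[:100], y[:100], X[100:], y[100:])
        assert compute_accuracy(model, X[100:], y[100:]) == 1.0

    def test_single_class_train_rejected(self, rng):
        X, y = _blobs(rng)
        only = y == "pos"
        with pytest.raises(ValueError):
            tune_and_fit(ClassifierSpec("lda"), X[only], y[only], X, y)


class _FixedPredictor:
    def __init__(self, preds):
        self.preds = np.asarray(preds)
        self.n_features_in_ = 1

    def predict(self, X):
        return self.preds[: len(X)]


class TestAccuracyMetric:
    def test_perfect_and_chance_predictors(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        X = np.zeros((6, 1))
        assert compute_accuracy(_FixedPredictor(y), X, y) == 1.0
        assert compute_accuracy(_FixedPredictor(["a"] * 6), X, y) == pytest.approx(1 / 3)

    def test_matches_confusion_matrix_trace(self, rng):
        y = rng.choice(["a", "b", "c"], size=50)
        preds = rng.choice(["a", "b", "c"], size=50)
        trace = sum(
            sum((y == c) & (preds == c)) for c in ("a", "b", "c")
        )
        got = compute_accuracy(_FixedPredictor(preds), np.zeros((50, 1)), y)
        assert got == pytest.approx(trace / 50)

    def test_chance_level(self):
        assert chance_level(13) == pytest.approx(1 / 13)


class TestSummarize:
    def _table(self, rows):
        return pd.DataFrame(
            [
                dict(subject=s, session="pooled", protocol="pooled",
                     classifier="rf", features="RMS+WL", degradation="clean",
                     repeat=i, accuracy=a, params="{}")
                for s, accs in rows for i, a in enumerate(accs)
            ]
        )

    def test_uniform_subjects(self):
        out = summarize(self._table([("S1", [0.9]), ("S2", [0.9]), ("S3", [0.9])]))
        row = out.iloc[0]
        assert row.mean_accuracy == row.min_accuracy == row.max_accuracy == 0.9

    def test_min_mean_max_ordering(self):
        out = summarize(self._table([("S1", [0.8]), ("S2", [1.0])]))
        row = out.iloc[0]
        assert (row.min_accuracy, row.mean_accuracy, row.max_accuracy) == (0.8, 0.9, 1.0)

    def test_two_stage_not_pooled_on_unbalanced_repeats(self):
        rows = [("S1", [0.5] * 9), ("S2", [1.0])]
        out = summarize(self._table(rows))
        expected = two_stage_mean(
            [(s, a) for s, accs in rows for a in accs]
        )
        assert out.iloc[0].mean_accuracy == pytest.approx(expected) == 0.75
        pooled = np.mean([a for _, accs in rows for a in accs])
        assert out.iloc[0].mean_accuracy != pytest.approx(pooled)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["subject", "accuracy"]))


FAST_RF = ClassifierSpec("rf", grid={"n_estimators": [25]})
RMS_WL = FeatureSpec(names=("RMS", "WL"))


class TestRunCondition:
    def test_result_table_shape_and_ranges(self):
        prep = prepared_micro()
        res = run_condition(prep, RMS_WL, FAST_RF, n_repeats=2, seed=3)
        assert len(res) == 2 * 2  # subjects x repeats
        assert res.accuracy.between(0, 1).all()
        assert set(res.subject) == {"S01", "S02"}

    def test_paired_seeding_shares_split_plans(self):
        """Conditions differing only in tau consume identical splits: the
        normalization stats recorded per repeat must match bit-for-bit."""
        from emgstress.evaluate import evaluate_split, make_stratified_splits
        from emgstress.preprocess import concat_window_sets

        prep = prepared_micro()
        ws = concat_window_sets(list(prep["S01"].values()))
        plan = make_stratified_splits(ws.labels, 2, seed=5)
        for split in plan.repeats:
            r1 = evaluate_split(ws, split, RMS_WL, FAST_RF,
                                DegradationSpec(kind="clip", tau=1e-4))
            r2 = evaluate_split(ws, split, RMS_WL, FAST_RF,
                                DegradationSpec(kind="clip", tau=1e-1))
            np.testing.assert_array_equal(r1.norm_stats.mu, r2.norm_stats.mu)
            np.testing.assert_array_equal(r1.norm_stats.sigma, r2.norm_stats.sigma)

    def test_endpoint_tau_ordering(self):
        prep = prepared_micro()
        low = run_condition(prep, RMS_WL, FAST_RF,
                            DegradationSpec(kind="clip", tau=1e-6),
                            n_repeats=2, seed=3)
        high = run_condition(prep, RMS_WL, FAST_RF,
                             DegradationSpec(kind="clip", tau=1e-1),
                             n_repeats=2, seed=3)
        assert high.accuracy.mean() >= low.accuracy.mean()

    def test_inter_session_requires_multiple_sessions(self):
        prep = prepared_micro()
        single = {"S01": {"sess1": prep["S01"]["sess1"]}}
        with pytest.raises(ValueError):
            run_condition(single, RMS_WL, FAST_RF, protocol="inter-session",
                          n_repeats=1, seed=0)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            run_condition(prepared_micro(), RMS_WL, FAST_RF, protocol="loocv")


class TestRunSweep:
    def test_condition_product_row_count(self):
        prep = prepared_micro()
        pairs = [FeatureSpec(names=("RMS", "WL")), FeatureSpec(names=("VAR", "ZC")),
                 FeatureSpec(names=("WL", "ZC"))]
        res = run_sweep(prep, pairs, [FAST_RF], taus=[1e-4, 1e-1],
                        n_repeats=2, seed=1)
        # 3 pairs x 1 classifier x 2 taus x 2 repeats rows per subject
        assert len(res) == 3 * 1 * 2 * 2 * 2
        per_subject = res.groupby("subject").size()
        assert (per_subject == 12).all()

    def test_dropout_only_table(self):
        prep = prepared_micro()
        res = run_sweep(prep, [RMS_WL], [FAST_RF], taus=[],
                        dropout_channels=[1, 2], n_repeats=1, seed=1)
        assert set(res.degradation) == {"dropout(ch=1,zero-signal)",
                                        "dropout(ch=2,zero-signal)"}

    def test_resume_skips_completed_conditions(self):
        prep = prepared_micro()
        res = run_sweep(prep, [RMS_WL], [FAST_RF], taus=[1e-2], n_repeats=1, seed=1)
        again = run_sweep(prep, [RMS_WL], [FAST_RF], taus=[1e-2], n_repeats=1,
                          seed=1, existing=res)
        assert len(again) == len(res)
        pd.testing.assert_frame_equal(again.reset_index(drop=True),
                                      res.reset_index(drop=True))

    def test_failed_conditions_recorded_and_grid_continues(self):
        prep = prepared_micro()
        bad = FeatureSpec(names=("MNF",))  # undefined on a flat dropped channel
        res = run_sweep(prep, [bad, RMS_WL], [FAST_RF], taus=[],
                        dropout_channels=[1], n_repeats=1, seed=1)
        assert len(res.attrs["failures"]) == 1
        assert set(res.features) == {"RMS+WL"}
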