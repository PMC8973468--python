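"""Subset enumeration, CV fold arithmetic, pooled metrics, wrapper ranking."""

import numpy as np
import pandas as pd
import pytest

from pupilload.classify import (
    CLASSIFIER_FAMILIES,
    ClassifierSpec,
    ModelReport,
    _precision_recall,
    enumerate_feature_subsets,
    evaluate_model,
    make_folds,
    reports_to_frame,
    wrapper_search,
)
from pupilload.features import FEATURE_NAMES


class TestSubsets:
    @pytest.mark.parametrize("b,expected", [(1, 1), (3, 7), (7, 127)])
    def test_counts_match_power_set(self, b, expected):
        subsets = enumerate_feature_subsets(FEATURE_NAMES[:b])
        assert len(subsets) == expected
        assert len(set(subsets)) == expected  # no duplicates
        assert all(subsets)  # non-empty

    def test_brute_force_enumeration_agrees(self):
        """Independent oracle: bitmask enumeration over 3 names."""
        names = ["a", "b", "c"]
        brute = {
            tuple(n for i, n in enumerate(names) if mask >> i & 1)
            for mask in range(1, 2**3)
        }
        assert set(enumerate_feature_subsets(names)) == brute

    def test_ordered_by_size_then_position(self):
        subsets = enumerate_feature_subsets(["a", "b", "c"])
        assert subsets[:3] == [("a",), ("b",), ("c",)]
        assert subsets[-1] == ("a", "b", "c")

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_feature_subsets([])


class TestFolds:
    def test_five_folds_are_80_20(self):
        y = np.repeat(["low", "medium", "high"], 35)  # 105 rows, 21 per fold
        folds = make_folds(y, k=5, seed=0)
        for train, test in folds:
            assert len(test) == len(y) // 5
            assert len(train) == len(y) - len(test)
            assert set(train) | set(test) == set(range(len(y)))
            assert set(train) & set(test) == set()

    def test_test_folds_partition_rows(self):
        y = np.repeat(["low", "medium", "high"], 20)
        folds = make_folds(y, k=5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(len(y)))

    def test_stratification_balances_classes(self):
        y = np.repeat(["low", "medium", "high"], 20)
        for _, test in make_folds(y, k=5, seed=2):
            _, counts = np.unique(y[test], return_counts=True)
            assert (counts == 4).all()

    def test_same_seed_same_folds(self):
        y = np.repeat(["low", "medium", "high"], 10)
        a = make_folds(y, k=5, seed=3)
        b = make_folds(y, k=5, seed=3)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_grouped_folds_keep_subject_together(self):
        rng = np.random.default_rng(0)
        subjects = np.repeat([f"s{i}" for i in range(10)], 9)
        y = np.tile(np.repeat(["low", "medium", "high"], 3), 10)
        for train, test in make_folds(y, k=5, seed=0, groups=subjects):
            assert set(subjects[train]) & set(subjects[test]) == set()

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array(["low", "high"]), k=5, seed=0)


class TestMetrics:
    def test_pooled_confusion_matrix_hand_oracle(self):
        cm = np.array([[8, 1, 1], [2, 7, 1], [0, 2, 8]])
        prec, rec = _precision_recall(cm)
        assert prec == pytest.approx([0.8, 0.7, 0.8])
        assert rec == pytest.approx([0.8, 0.7, 0.8])

    def test_perfectly_separable_features_score_one(self):
        rng = np.random.default_rng(0)
        n = 40
        rows = []
        for i, lev in enumerate(("low", "medium", "high")):
            x = i * 10.0 + rng.normal(0, 0.1, n)
            rows.append(pd.DataFrame({"difficulty": lev, "x": x}))
        df = pd.concat(rows, ignore_index=True)
        report = evaluate_model(df, ClassifierSpec("lda"), ("x",), k=5, seed=0)
        assert report.macro_f1 == 1.0
        assert all(v == 1.0 for v in report.per_class_precision.values())

    def test_random_labels_score_near_chance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "difficulty": rng.permutation(np.repeat(["low", "medium", "high"], 200)),
                "x": rng.normal(size=600),
                "z": rng.normal(size=600),
            }
        )
        report = evaluate_model(df, ClassifierSpec("decision_tree"), ("x", "z"), k=5, seed=1)
        assert abs(report.macro_f1 - 1 / 3) < 0.08

    def test_pooled_metrics_match_brute_force_over_predictions(self, small_features):
        """Dual route: rebuild metrics from raw per-fold prediction lists."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.preprocessing import StandardScaler

        subset = ("MPDC", "TTP")
        y = small_features["difficulty"].to_numpy()
        X = small_features.loc[:, list(subset)].to_numpy(float)
        folds = make_folds(y, k=5, seed=7)
        y_true, y_pred = [], []
        for tr, te in folds:
            sc = StandardScaler().fit(X[tr])
            est = LinearDiscriminantAnalysis().fit(sc.transform(X[tr]), y[tr])
            y_true.extend(y[te])
            y_pred.extend(est.predict(sc.transform(X[te])))
        y_true, y_pred = np.array(y_true), np.array(y_pred)
        prec = {}
        rec = {}
        for lev in ("low", "medium", "high"):
            tp = np.sum((y_pred == lev) & (y_true == lev))
            prec[lev] = tp / max(1, np.sum(y_pred == lev))
            rec[lev] = tp / max(1, np.sum(y_true == lev))
        report = evaluate_model(small_features, ClassifierSpec("lda"), subset, folds=folds)
        for lev in ("low", "medium", "high"):
            assert report.per_class_precision[lev] == pytest.approx(prec[lev])
            assert report.per_class_recall[lev] == pytest.approx(rec[lev])
        mp = np.mean(list(prec.values()))
        mr = np.mean(list(rec.values()))
        assert report.macro_f1 == pytest.approx(2 * mp * mr / (mp + mr))

    def test_unknown_feature_rejected(self, small_features):
        with pytest.raises(ValueError, match="not in table"):
            evaluate_model(small_features, ClassifierSpec("lda"), ("nope",))


class TestWrapperSearch:
    @pytest.fixture(scope="class")
    def search(self, small_features):
        return wrapper_search(small_features, k=5, seed=7)

    def test_evaluates_all_889_configurations(self, search):
        assert len(search) == 7 * 127
        pairs = {(r.family, r.feature_subset) for r in search}
        assert len(pairs) == 889

    def test_ranking_is_monotone(self, search):
        f1 = [r.macro_f1 for r in search]
        assert all(a >= b for a, b in zip(f1, f1[1:]))

    def test_ties_prefer_fewer_features(self, search):
        for a, b in zip(search, search[1:]):
            if a.macro_f1 == b.macro_f1:
                assert len(a.feature_subset) <= len(b.feature_subset)

    def test_metrics_stay_in_unit_interval(self, search):
        for r in search:
            for v in (
                r.macro_precision,
                r.macro_recall,
                r.macro_f1,
                r.macro_f1_classwise,
                *r.per_class_precision.values(),
                *r.per_class_recall.values(),
            ):
                assert 0.0 <= v <= 1.0

    def test_frame_mirrors_ranking(self, search):
        frame = reports_to_frame(search)
        assert list(frame["rank"]) == list(range(1, 890))
        assert frame.loc[0, "f1"] == pytest.approx(search[0].macro_f1)
        assert set(frame["classifier"]) == set(CLASSIFIER_FAMILIES)
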