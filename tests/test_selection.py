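import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import fundusrad as fr
from fundusrad.imaging import ValidationError
from fundusrad.selection import MutualInfoFilter, SFFSSelector, TTestFilter

from oracles import plugin_mi_reference


class TestZScore:
    def test_hand_arithmetic_population_sd(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        (tz,), scaler = fr.zscore_normalize(train)
        np.testing.assert_allclose(tz["a"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_column_zeroed_and_flagged(self):
        train = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 4.0]})
        (tz,), scaler = fr.zscore_normalize(train)
        assert (tz["a"] == 0).all()
        assert "a" in scaler.zero_variance

    def test_validation_value_at_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"a": [1.0, 3.0, 5.0]})
        val = pd.DataFrame({"a": [3.0]})
        (tz, vz), _ = fr.zscore_normalize(train, val)
        assert vz["a"].iloc[0] == 0.0

    def test_scaler_depends_only_on_training_rows(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        val1 = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        val2 = val1 * 100 + 7  # mutate validation rows
        (_, _), s1 = fr.zscore_normalize(train, val1)
        (_, _), s2 = fr.zscore_normalize(train, val2)
        pd.testing.assert_series_equal(s1.mean, s2.mean)
        pd.testing.assert_series_equal(s1.sd, s2.sd)


class TestMutualInfoFilter:
    def test_label_copy_feature_has_one_bit(self):
        y = np.array([0, 1] * 200)
        X = pd.DataFrame({"copy": y.astype(float)})
        f = MutualInfoFilter().fit(X, y)
        assert f.mi_scores_[0] == pytest.approx(1.0, abs=1e-9)
        assert fr.mutual_information_filter(X, y) == ["copy"]

    def test_independent_feature_below_null_band_and_dropped(self):
        # permutation null at n=400: the 99th percentile of plug-in MI
        # stays under 0.05 bits, far below the 0.2 retention threshold
        mis = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.array([0, 1] * 200)
            x = rng.permutation(np.arange(400)).astype(float)
            mis.append(plugin_mi_reference(x, y))
        assert np.quantile(mis, 0.99) < 0.05
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"noise": rng.normal(size=400)})
        assert fr.mutual_information_filter(X, np.array([0, 1] * 200)) == []

    def test_zero_threshold_retains_everything(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = (rng.random(100) < 0.5).astype(int)
        kept = fr.mutual_information_filter(X, y, threshold=0.0)
        assert kept == list("abcde")

    def test_matches_reference_estimator(self):
        rng = np.random.default_rng(5)
        y = (rng.random(150) < 0.4).astype(int)
        x = rng.normal(size=150) + 0.8 * y
        X = pd.DataFrame({"x": x})
        f = MutualInfoFilter().fit(X, y)
        assert f.mi_scores_[0] == pytest.approx(plugin_mi_reference(x, y), rel=1e-9)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            fr.mutual_information_filter(X, np.zeros(3, dtype=int))


class TestTTestFilter:
    def test_fully_separated_degenerate_groups_retained(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]})
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert fr.ttest_filter(X, y) == ["a"]

    def test_identical_groups_dropped(self):
        X = pd.DataFrame({"a": [2.0, 2.0, 2.0, 2.0]})
        y = np.array([0, 0, 1, 1])
        assert fr.ttest_filter(X, y) == []

    def test_pooled_t_closed_form(self):
        # {1..5} vs {3..7}: pooled sp^2 = 2.5, so t = -2 / sqrt(2.5 * 2/5)
        # = -2.0 with 8 df and two-sided p = 0.08052 -> dropped at 0.05
        X = pd.DataFrame({"a": [1, 2, 3, 4, 5, 3, 4, 5, 6, 7.0]})
        y = np.array([0] * 5 + [1] * 5)
        f = TTestFilter().fit(X, y)
        assert f.statistics_[0] == pytest.approx(-2.0, abs=1e-9)
        assert f.pvalues_[0] == pytest.approx(0.080517, abs=1e-5)
        assert fr.ttest_filter(X, y, alpha=0.05) == []
        assert fr.ttest_filter(X, y, alpha=0.1) == ["a"]

    def test_tiny_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            fr.ttest_filter(X, np.array([0, 0, 1]))


class TestFilterIntersection:
    def test_idempotent(self):
        assert fr.filter_intersection(["a", "b"], ["a", "b"]) == ["a", "b"]

    def test_disjoint_empty_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = fr.filter_intersection(["a"], ["b"])
        assert out == []
        assert any("empty" in r.message for r in caplog.records)

    def test_inclusion_exclusion_bound(self):
        rng = np.random.default_rng(0)
        universe = [f"f{i}" for i in range(40)]
        a = [f for f in universe if rng.random() < 0.6]
        b = [f for f in universe if rng.random() < 0.7]
        inter = fr.filter_intersection(a, b)
        assert len(inter) >= len(a) + len(b) - len(universe)
        assert inter == fr.filter_intersection(b, a) or set(inter) == set(
            fr.filter_intersection(b, a)
        )


class TestSFFS:
    def _planted(self, seed, n=300, p=12, k=2, delta=2.0):
        X, y, truth = fr.simulate_feature_table(
            fr.TabularSimConfig(n=n, p=p, k=k, delta=delta, seed=seed)
        )
        return X, y, truth

    def test_single_candidate_boundary(self):
        X, y, _ = self._planted(0, p=3, k=1)
        trace = fr.sffs_select(X, y, candidates=["f000"], max_k=5, seed=0, n_trees=10)
        assert sorted(trace.means) == [1]
        assert trace.subsets[1] == ("f000",)

    def test_scores_bounded_and_sd_nonnegative(self):
        X, y, _ = self._planted(1)
        trace = fr.sffs_select(X, y, max_k=3, seed=1, n_trees=10)
        for k in trace.means:
            assert 0.0 <= trace.means[k] <= 1.0
            assert trace.sds[k] >= 0.0

    def test_recovers_planted_features_single_seed(self):
        X, y, truth = self._planted(3, p=15, k=2, delta=2.0)
        trace = fr.sffs_select(X, y, max_k=2, seed=3, n_trees=25)
        assert set(trace.subsets[2]) == {"f000", "f001"}

    def test_deterministic_under_seed(self):
        X, y, _ = self._planted(4, p=10)
        t1 = fr.sffs_select(X, y, max_k=2, seed=9, n_trees=10)
        t2 = fr.sffs_select(X, y, max_k=2, seed=9, n_trees=10)
        assert t1.subsets == t2.subsets
        assert t1.means == t2.means

    def test_max_k_clamped_with_warning(self, caplog):
        X, y, _ = self._planted(5, p=4)
        with caplog.at_level(logging.WARNING):
            trace = fr.sffs_select(X, y, max_k=30, seed=0, n_trees=5)
        assert trace.max_k <= 4
        assert any("clamp" in r.message for r in caplog.records)


class TestChooseFinalSet:
    def _trace(self, means):
        t = fr.SelectionTrace()
        for k, m in enumerate(means, start=1):
            t.record(k, tuple(f"f{i}" for i in range(k)), m, 0.01)
        return t

    def test_rise_then_plateau_picks_knee(self):
        means = [0.6, 0.7, 0.75, 0.78, 0.80, 0.82, 0.83, 0.84, 0.841, 0.842]
        assert len(fr.choose_final_set(self._trace(means), tol=0.005)) == 8

    def test_monotone_nonincreasing_picks_one(self):
        assert len(fr.choose_final_set(self._trace([0.8, 0.79, 0.78]))) == 1

    def test_infinite_tolerance_picks_one(self):
        assert len(fr.choose_final_set(self._trace([0.5, 0.9, 0.99]), tol=np.inf)) == 1


class TestDecisionModel:
    def test_separable_training_auc_is_one(self):
        X = pd.DataFrame({"a": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        clf = fr.fit_decision_model(X, y, ["a"], seed=0)
        from fundusrad.selection import predict_scores

        assert fr.roc_auc(predict_scores(clf, X), y) == 1.0

    def test_identical_seed_identical_probabilities(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = (rng.random(60) < 0.5).astype(int)
        from fundusrad.selection import predict_scores

        p1 = predict_scores(fr.fit_decision_model(X, y, list("abc"), seed=5), X)
        p2 = predict_scores(fr.fit_decision_model(X, y, list("abc"), seed=5), X)
        np.testing.assert_array_equal(p1, p2)

    def test_label_permutation_gives_chance_validation_auc(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=[f"f{i}" for i in range(5)])
        y = rng.permutation(np.r_[np.zeros(150), np.ones(150)]).astype(int)
        from fundusrad.selection import predict_scores

        clf = fr.fit_decision_model(X.iloc[:200], y[:200], list(X.columns), seed=0)
        auc = fr.roc_auc(predict_scores(clf, X.iloc[200:]), y[200:])
        assert 0.35 <= auc <= 0.65

    def test_unknown_feature_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValidationError):
            fr.fit_decision_model(X, [0, 1, 0, 1], ["zz"], seed=0)


class TestFeatureTable:
    def _table(self, values, severe):
        labels = pd.DataFrame({"grade": ["C0"] * len(severe), "severe": severe})
        tags = pd.Series(["train"] * len(severe))
        cats = pd.Series("morphologic", index=values.columns)
        return fr.FeatureTable(values, cats, labels, tags)

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0]})
        with pytest.raises(ValidationError, match="missing"):
            self._table(X, [0, 1, 0])

    def test_single_class_train_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError, match="classes"):
            self._table(X, [1, 1, 1])

    def test_split_accessors(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        labels = pd.DataFrame({"grade": ["C0"] * 4, "severe": [0, 1, 0, 1]})
        tags = pd.Series(["train", "train", "validation", "validation"])
        t = fr.FeatureTable(X, pd.Series("clinic", index=X.columns), labels, tags)
        assert list(t.train_X["a"]) == [1.0, 2.0]
        assert list(t.validation_y) == [0, 1]


class TestSklearnEstimatorApi:
    def test_selector_mixin_transform_shapes(self):
        X, y, _ = fr.simulate_feature_table(
            fr.TabularSimConfig(n=200, p=10, k=2, delta=2.0, seed=0)
        )
        f = MutualInfoFilter(threshold=0.05).fit(X, y)
        assert f.transform(X).shape[1] == f.get_support().sum() > 0
        t = TTestFilter().fit(X, y)
        assert t.transform(X).shape[1] == t.get_support().sum()

    def test_sffs_selector_fit_transform_and_clone(self):
        X, y, _ = fr.simulate_feature_table(
            fr.TabularSimConfig(n=200, p=8, k=2, delta=2.0, seed=1)
        )
        selr = SFFSSelector(max_k=2, n_trees=10, seed=0)
        clone(selr)  # must be cloneable for sklearn model selection
        selr.fit(X, y)
        assert selr.chosen_k_ == len(selr.selected_features_)
        assert selr.transform(X).shape == (200, selr.chosen_k_)

    def test_filters_commute(self):
        X, y, _ = fr.simulate_feature_table(
            fr.TabularSimConfig(n=150, p=12, k=3, delta=1.0, seed=2)
        )
        mi = fr.mutual_information_filter(X, y, threshold=0.05)
        tt = fr.ttest_filter(X, y)
        assert set(fr.filter_intersection(mi, tt)) == set(fr.filter_intersection(tt, mi))
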