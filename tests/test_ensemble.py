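"""Balanced trials, RFE ranking, trial evaluation and the parameter grid."""

import math

import numpy as np
import pandas as pd
import pytest

from dilipred import (
    ModelParams,
    confusion_metrics,
    fit_trial,
    grid_search,
    make_balanced_trials,
    rfe_rank,
    youden_threshold,
)
from dilipred.ensemble import default_rfe_schedule
from dilipred.synthetic_data import DescriptorSimConfig, generate_descriptors
from dilipred import preprocess


def _pool(n_pos, n_neg):
    pos = [f"p{i}" for i in range(n_pos)]
    neg = [f"n{i}" for i in range(n_neg)]
    return pos, neg


class TestBalancedTrials:
    def test_majority_undersampled_to_minority_size(self):
        pos, neg = _pool(155, 164)
        trials = make_balanced_trials(pos, neg, n_trials=20, seed=3)
        assert len(trials) == 20
        for t in trials:
            n_neg = len(t.train_neg) + len(t.test_neg)
            n_pos = len(t.train_pos) + len(t.test_pos)
            assert n_neg == n_pos == 155

    def test_ninety_ten_split_with_ceil(self):
        pos, neg = _pool(155, 164)
        t = make_balanced_trials(pos, neg, n_trials=1, seed=0)[0]
        expected_test = math.ceil(0.1 * 155)
        assert len(t.test_pos) == len(t.test_neg) == expected_test
        assert len(t.train_pos) == 155 - expected_test

    def test_train_test_disjoint(self):
        pos, neg = _pool(30, 40)
        for t in make_balanced_trials(pos, neg, n_trials=5, seed=1):
            assert not set(t.train_ids) & set(t.test_ids)

    def test_equal_classes_use_everyone(self):
        pos, neg = _pool(10, 10)
        t = make_balanced_trials(pos, neg, n_trials=3, seed=0)[0]
        assert set(t.train_neg) | set(t.test_neg) == set(neg)

    def test_same_seed_identical_trials(self):
        pos, neg = _pool(20, 30)
        a = make_balanced_trials(pos, neg, n_trials=10, seed=42)
        b = make_balanced_trials(pos, neg, n_trials=10, seed=42)
        assert a == b

    def test_empty_class_is_configuration_error(self):
        with pytest.raises(ValueError):
            make_balanced_trials([], ["n1"], n_trials=1)


class TestRFESchedule:
    @pytest.mark.parametrize("n,top", [(731, 15), (200, 15), (20, 5), (11, 10)])
    def test_strictly_decreasing_and_contains_top(self, n, top):
        sched = default_rfe_schedule(n, top)
        assert list(sched) == sorted(set(sched), reverse=True)
        assert top in sched
        assert all(s < n for s in sched)


def _planted_frame(n_samples, n_noise, rng, effect=3.0, duplicate=False):
    y = np.repeat([1, 0], n_samples // 2)
    inf1 = rng.normal(size=n_samples) + effect * y
    inf2 = rng.normal(size=n_samples) - effect * y
    cols = {"inf1": inf1, "inf2": inf2 if not duplicate else inf1}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.normal(size=n_samples)
    X = pd.DataFrame(cols, index=[f"s{i}" for i in range(n_samples)])
    X = (X - X.mean()) / X.std(ddof=0)
    return X, pd.Series(y, index=X.index)


class TestRFERank:
    def test_informative_features_rank_top(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            X, y = _planted_frame(200, 8, rng)
            ranking = rfe_rank(X, y, ModelParams(cost=1.0, top=2))
            if set(ranking[:2]) == {"inf1", "inf2"}:
                hits += 1
        assert hits >= 9

    def test_single_feature_degenerate(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"only": rng.normal(size=20)})
        y = pd.Series(np.repeat([0, 1], 10), index=X.index)
        assert rfe_rank(X, y, ModelParams(cost=1.0, top=1)) == ["only"]

    def test_duplicated_informative_outranks_noise(self):
        rng = np.random.default_rng(7)
        X, y = _planted_frame(200, 8, rng, duplicate=True)
        ranking = rfe_rank(X, y, ModelParams(cost=1.0, top=2))
        assert set(ranking[:2]) == {"inf1", "inf2"}

    def test_full_ranking_is_a_permutation(self):
        rng = np.random.default_rng(1)
        X, y = _planted_frame(60, 10, rng)
        ranking = rfe_rank(X, y, ModelParams(cost=1.0, top=3))
        assert sorted(ranking) == sorted(X.columns)

    def test_agrees_with_sklearn_rfe_at_step_one(self):
        """One-at-a-time elimination must match sklearn's RFE ranking."""
        from sklearn.feature_selection import RFE
        from sklearn.svm import SVC

        rng = np.random.default_rng(3)
        X, y = _planted_frame(80, 6, rng)
        schedule = tuple(range(X.shape[1] - 1, 0, -1))
        ranking = rfe_rank(
            X, y, ModelParams(cost=1.0, top=1, rfe_schedule=schedule)
        )
        ref = RFE(SVC(kernel="linear", C=1.0), n_features_to_select=1, step=1)
        ref.fit(X.to_numpy(), y.to_numpy())
        # sklearn ranking_: 1 = kept longest; convert to an ordering
        order = [f for _, f in sorted(zip(ref.ranking_, X.columns))]
        assert ranking == order


class TestTrialEvaluation:
    def _trial_data(self, effect, seed):
        config = DescriptorSimConfig(
            n_pos=40, n_neg=40, n_features=20, n_informative=4,
            effect_size=effect, seed=seed,
        )
        matrix, y, _ = generate_descriptors(config)
        scaled, _ = preprocess(matrix)
        pos = sorted(y.index[y == 1])
        neg = sorted(y.index[y == 0])
        return scaled.values, y, pos, neg

    def test_separable_limit(self):
        X, y, pos, neg = self._trial_data(effect=6.0, seed=2)
        trial = make_balanced_trials(pos, neg, n_trials=1, seed=5)[0]
        res = fit_trial(trial, X, y, ModelParams(cost=1.0, top=4), seed=5)
        assert res.auc == 1.0
        assert res.metrics.sensitivity == 1.0
        assert res.metrics.specificity == 1.0

    def test_metric_identities(self):
        X, y, pos, neg = self._trial_data(effect=1.0, seed=3)
        for trial in make_balanced_trials(pos, neg, n_trials=5, seed=8):
            res = fit_trial(trial, X, y, ModelParams(cost=1.0, top=4), seed=8)
            assert res.valid
            assert res.metrics.sensitivity + res.metrics.fnr == pytest.approx(1.0)
            assert res.metrics.specificity + res.metrics.fpr == pytest.approx(1.0)
            assert 0.0 <= res.auc <= 1.0


class TestConfusionMetrics:
    def test_threshold_zero_all_positive_truth(self):
        m = confusion_metrics([1, 1, 1], [0.2, 0.6, 0.9], 0.0)
        assert m.sensitivity == 1.0 and m.fnr == 0.0
        assert m.specificity is None  # no negatives in truth

    def test_ppv_missing_when_no_predicted_positives(self):
        m = confusion_metrics([1, 0], [0.1, 0.2], 0.9)
        assert m.ppv is None

    def test_counts_example(self):
        # 8 of 10 positives above threshold, 3 of 5 negatives below
        y = [1] * 10 + [0] * 5
        p = [0.9] * 8 + [0.1] * 2 + [0.8] * 2 + [0.1] * 3
        m = confusion_metrics(y, p, 0.5)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(11 / 15)
        assert m.ppv == pytest.approx(8 / 10)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [], 0.5)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1], [1.5], 0.5)


def test_youden_threshold_separates_separable_classes():
    y = [0, 0, 0, 1, 1, 1]
    p = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
    t = youden_threshold(y, p)
    assert 0.3 <= t < 0.7
    m = confusion_metrics(y, p, t)
    assert m.sensitivity == 1.0 and m.specificity == 1.0


class TestGridSearch:
    def _data(self):
        config = DescriptorSimConfig(
            n_pos=30, n_neg=36, n_features=12, n_informative=3,
            effect_size=2.0, seed=4,
        )
        matrix, y, _ = generate_descriptors(config)
        scaled, _ = preprocess(matrix)
        pos = sorted(y.index[y == 1])
        neg = sorted(y.index[y == 0])
        return scaled.values, y, pos, neg

    def test_single_cell_grid_is_best(self):
        X, y, pos, neg = self._data()
        trials = make_balanced_trials(pos, neg, n_trials=4, seed=2)
        grid = grid_search(trials, X, y, cost_grid=[1.0], top_grid=[3], seed=2)
        assert (grid.best_params.cost, grid.best_params.top) == (1.0, 3)
        assert grid.n_valid[(1.0, 3)] == 4

    def test_heatmap_frame_shape(self):
        X, y, pos, neg = self._data()
        trials = make_balanced_trials(pos, neg, n_trials=2, seed=2)
        grid = grid_search(trials, X, y, cost_grid=[0.1, 1.0], top_grid=[3, 6], seed=2)
        frame = grid.auc_frame()
        assert frame.shape == (2, 2)
        assert frame.notna().all().all()

    def test_oversized_top_values_dropped(self):
        X, y, pos, neg = self._data()
        trials = make_balanced_trials(pos, neg, n_trials=2, seed=2)
        grid = grid_search(trials, X, y, cost_grid=[1.0], top_grid=[3, 500], seed=2)
        assert set(grid.cell_means) == {(1.0, 3)}
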