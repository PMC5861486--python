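import numpy as np
import pandas as pd
import pytest

from synercomb.modeling import (
    DataSplit,
    ModelSpec,
    SynergyClassification,
    SynergyRegression,
    classify_by_threshold,
    f1_score,
    grid_search_train,
    pearson_r,
    rank_best_combination,
    split_data,
    subset_eval_by_prediction,
)


class TestSplitData:
    def test_eighty_twenty_with_five_folds(self):
        split = split_data(100, seed=0)
        assert len(split.train_idx) == 80 and len(split.test_idx) == 20
        assert all(len(f) == 16 for f in split.folds)

    def test_same_seed_reproduces_split(self):
        a, b = split_data(57, seed=3), split_data(57, seed=3)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)
        assert all(np.array_equal(x, y) for x, y in zip(a.folds, b.folds))

    def test_partition_covers_everything(self):
        split = split_data(53, seed=1)
        union = np.sort(np.concatenate([split.train_idx, split.test_idx]))
        assert np.array_equal(union, np.arange(53))
        fold_union = np.sort(np.concatenate(split.folds))
        assert np.array_equal(fold_union, split.train_idx)

    def test_rejects_tiny_datasets(self):
        with pytest.raises(ValueError):
            split_data(9, seed=0)

    def test_overlapping_folds_rejected(self):
        with pytest.raises(ValueError):
            DataSplit(np.arange(8), np.arange(8, 10),
                      (np.arange(4), np.arange(3, 8)), seed=0)


def linear_data(rng, n=60, p=4):
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
    return X, y


class TestGridSearch:
    def test_single_point_grid_is_chosen(self, rng):
        X, y = linear_data(rng)
        split = split_data(len(y), seed=0)
        spec = ModelSpec("ridge", grid={"alpha": [0.5]})
        model = grid_search_train(spec, split, X, y)
        assert model.params == {"alpha": 0.5}

    def test_matches_brute_force_cv_loop(self, rng):
        """Chosen point and score replicate an explicit CV loop."""
        from sklearn.linear_model import Ridge
        X, y = linear_data(rng)
        split = split_data(len(y), seed=1)
        grid = [0.001, 0.1, 10.0]
        spec = ModelSpec("ridge", grid={"alpha": grid})
        model = grid_search_train(spec, split, X, y)
        best_alpha, best_score = None, -np.inf
        for alpha in grid:
            scores = []
            for fold in split.folds:
                fit_idx = np.setdiff1d(split.train_idx, fold)
                est = Ridge(alpha=alpha).fit(X[fit_idx], y[fit_idx])
                scores.append(pearson_r(y[fold], est.predict(X[fold])))
            if np.mean(scores) > best_score:
                best_score, best_alpha = float(np.mean(scores)), alpha
        assert model.params == {"alpha": best_alpha}
        assert model.cv_score == pytest.approx(best_score)

    def test_test_rows_never_affect_selection(self, rng):
        X, y = linear_data(rng)
        split = split_data(len(y), seed=2)
        spec = ModelSpec("ridge", grid={"alpha": [0.001, 1.0, 100.0]})
        m1 = grid_search_train(spec, split, X, y)
        y2 = y.copy()
        y2[split.test_idx] = rng.normal(size=len(split.test_idx)) * 1e3
        m2 = grid_search_train(spec, split, X, y2)
        assert m1.params == m2.params
        assert m1.cv_score == pytest.approx(m2.cv_score)

    def test_rejects_constant_target(self, rng):
        X, _ = linear_data(rng)
        split = split_data(len(X), seed=0)
        with pytest.raises(ValueError):
            grid_search_train(ModelSpec("ridge"), split, X, np.ones(len(X)))


class TestPearson:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2, 3, 4])
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert pearson_r(y, -y) == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 4, 5, 9])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert pearson_r(a, b) == pytest.approx(num / den)

    def test_rejects_constant_or_short(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])


class TestSubsetEval:
    def test_cutoff_zero_keeps_everything(self, rng):
        y, p = rng.normal(size=50), rng.normal(size=50)
        r, n = subset_eval_by_prediction(y, p, 0.0)
        assert n == 50 and r == pytest.approx(pearson_r(y, p))

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            subset_eval_by_prediction([1.0, 2, 3], [0.1, 0.2, -0.3], 10.0)

    def test_membership_matches_brute_filter(self, rng):
        for _ in range(30):
            y = rng.normal(0, 20, 80)
            p = rng.normal(0, 20, 80)
            cutoff = float(rng.uniform(1, 15))
            mask = np.abs(p) > cutoff
            if mask.sum() < 3:
                continue
            r, n = subset_eval_by_prediction(y, p, cutoff)
            assert n == int(mask.sum())
            assert r == pytest.approx(pearson_r(y[mask], p[mask]))


class TestThresholdClassification:
    def test_drop_zone_labels(self):
        out = classify_by_threshold([25.0, -25.0, 5.0], 20.0)
        assert list(out) == [1, -1, 0]

    def test_zero_threshold_drops_exact_zeros(self):
        assert list(classify_by_threshold([4.5, -3.0, 0.0], 0.0)) == [1, -1, 0]

    @pytest.mark.parametrize("thr", [0.0, 10.0, 15.0, 20.0])
    def test_retained_counts_match_brute_force(self, rng, thr):
        scores = rng.normal(0, 20, 200)
        labels = classify_by_threshold(scores, thr)
        assert (labels != 0).sum() == np.sum((scores > thr) | (scores < -thr))


class TestF1:
    def test_perfect_prediction(self):
        y = np.array([1, 1, -1, -1])
        assert f1_score(y, y) == 1.0

    def test_closed_form_example(self):
        # TP=2, FP=1, FN=1 -> precision = recall = 2/3 -> F1 = 2/3
        y_true = np.array([1, 1, 1, -1, -1])
        y_pred = np.array([1, 1, -1, 1, -1])
        assert f1_score(y_true, y_pred) == pytest.approx(2 / 3)

    def test_matches_printed_formula(self, rng):
        for _ in range(100):
            y_true = rng.choice([1, -1], 30)
            y_pred = rng.choice([1, -1], 30)
            if not (y_true == 1).any():
                continue
            tp = np.sum((y_true == 1) & (y_pred == 1))
            fp = np.sum((y_true == -1) & (y_pred == 1))
            fn = np.sum((y_true == 1) & (y_pred == -1))
            if tp + fp == 0:
                expected = 0.0
            else:
                prec, rec = tp / (tp + fp), tp / (tp + fn)
                expected = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
            with np.errstate(all="ignore"):
                assert f1_score(y_true, y_pred) == pytest.approx(expected)

    def test_no_predicted_positives_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert f1_score(np.array([1, -1]), np.array([-1, -1])) == 0.0


class TestRanking:
    def test_perfect_predictions_rank_first(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        y = np.array([5.0, 20.0, 1.0])
        pair, rank, n = rank_best_combination(pairs, y, y)
        assert pair == ("c", "d") and rank == 1 and n == 3

    def test_reversed_predictions_rank_last(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        y = np.array([5.0, 20.0, 1.0])
        _, rank, _ = rank_best_combination(pairs, y, -y)
        assert rank == 3

    def test_prediction_ties_are_pessimistic(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        y_true = np.array([1.0, 9.0, 2.0])
        y_pred = np.array([3.0, 3.0, 3.0])
        _, rank, _ = rank_best_combination(pairs, y_true, y_pred)
        assert rank == 3

    def test_matches_brute_force_sort(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            pairs = [(f"d{i}", f"e{i}") for i in range(n)]
            y_true = rng.normal(size=n)
            y_pred = np.round(rng.normal(size=n), 1)  # provoke ties
            best = int(np.argmax(y_true))
            expected = sum(1 for v in y_pred if v >= y_pred[best])
            _, rank, _ = rank_best_combination(pairs, y_true, y_pred)
            assert rank == expected


class TestModelObjects:
    def test_regression_results_and_summary(self, rng):
        X, y = linear_data(rng, n=120, p=6)
        meta = pd.DataFrame({
            "cell_line": rng.choice(["C1", "C2", "C3"], 120),
            "drug_a": rng.choice(["D1", "D2", "D3"], 120),
            "drug_b": "D9"})
        split = split_data(120, seed=0)
        res = SynergyRegression(X, y, meta, split, family="ridge", seed=0).fit()
        rep = res.evaluate()
        assert -1 <= rep.pearson_overall <= 1
        assert rep.pearson_overall > 0.9  # near-linear, near-noiseless target
        text = res.summary()
        assert "ridge" in text and "Pearson" in text

    def test_classifier_drops_ambiguous_band(self, rng):
        X = rng.normal(size=(200, 5))
        y_scores = X[:, 0] * 30 + rng.normal(0, 5, 200)
        meta = pd.DataFrame({"cell_line": "C", "drug_a": "A", "drug_b": "B"},
                            index=range(200))
        split = split_data(200, seed=1)
        clf = SynergyClassification(X, y_scores, meta, split, threshold=15.0,
                                    family="logistic", seed=0)
        res = clf.fit()
        retained = np.abs(y_scores) > 15.0
        assert len(res.sub_split.train_idx) == retained[split.train_idx].sum()
        assert 0 <= res.f1_test() <= 1
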