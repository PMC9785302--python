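import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import enosekit as ek
from enosekit.lda import classification_energy
from tests.conftest import make_table


def _gaussian_toy(seed=0, n=40, shift=3.0):
    rng = np.random.default_rng(seed)
    A = rng.multivariate_normal([0, 0], [[1.0, 0.4], [0.4, 1.5]], n)
    B = rng.multivariate_normal([shift, 1.0], [[1.0, 0.4], [0.4, 1.5]], n)
    X = np.vstack([A, B])
    labels = ["Coa"] * n + ["Douro"] * n
    return make_table(X, labels)


class TestFit:
    def test_separable_feature_classifies_training_data(self):
        X = np.column_stack([np.r_[np.zeros(5), np.ones(5) * 10], np.zeros(10)])
        X[:, 1] = np.random.default_rng(0).normal(size=10)
        table = make_table(X, ["Coa"] * 5 + ["Douro"] * 5)
        model = ek.fit_lda(table, ["F0"])
        pred = ek.classify(model, table)
        assert (pred.to_numpy() == table.labels.to_numpy()).all()

    def test_label_swap_flips_direction_sign(self):
        table = _gaussian_toy()
        swapped = ek.FeatureTable(
            features=table.features,
            labels=table.labels.map({"Coa": "Douro", "Douro": "Coa"}),
        )
        m1 = ek.fit_lda(table, ["F0", "F1"])
        m2 = ek.fit_lda(swapped, ["F0", "F1"])
        sign = np.sign(m1.direction @ m2.direction)
        np.testing.assert_allclose(m1.direction, sign * m2.direction, rtol=1e-9)
        # predictions under the swapped model are the swapped labels
        p1 = ek.classify(m1, table)
        p2 = ek.classify(m2, table)
        assert (p1.map({"Coa": "Douro", "Douro": "Coa"}) == p2).all()

    def test_direction_matches_fisher_closed_form(self):
        table = _gaussian_toy(seed=1)
        model = ek.fit_lda(table, ["F0", "F1"])
        X = table.features.to_numpy()
        y = table.labels.to_numpy()
        mu1, mu2 = X[y == "Coa"].mean(0), X[y == "Douro"].mean(0)
        S = (
            np.cov(X[y == "Coa"].T, ddof=1) * (sum(y == "Coa") - 1)
            + np.cov(X[y == "Douro"].T, ddof=1) * (sum(y == "Douro") - 1)
        ) / (len(y) - 2)
        expected = np.linalg.solve(S, mu1 - mu2)
        np.testing.assert_allclose(model.direction, expected, rtol=1e-9)

    def test_predictions_match_sklearn_equal_priors(self):
        table = _gaussian_toy(seed=2, shift=1.5)
        model = ek.fit_lda(table, ["F0", "F1"])
        ours = ek.classify(model, table)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        sk.fit(table.features.to_numpy(), table.labels.to_numpy())
        theirs = sk.predict(table.features.to_numpy())
        assert (ours.to_numpy() == theirs).mean() == 1.0

    def test_constant_feature_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        table = make_table(X, ["Coa"] * 5 + ["Douro"] * 5)
        with pytest.raises(ValueError, match="constant"):
            ek.fit_lda(table, ["F0", "F1"])

    def test_oversized_subset_rejected(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(size=(6, 5)), ["Coa"] * 3 + ["Douro"] * 3)
        with pytest.raises(ValueError, match="subset too large"):
            ek.fit_lda(table, [f"F{i}" for i in range(5)])


class TestConfusionSummary:
    def test_reported_confusion_rates(self):
        # 35/36 class-1 correct, 31/31 class-2 correct
        summary = ek.ConfusionSummary(
            classes=("Coa", "Douro"), confusion=np.array([[35, 1], [0, 31]])
        )
        assert summary.overall_sensitivity == pytest.approx(66 / 67)
        assert round(100 * summary.overall_sensitivity, 1) == 98.5
        np.testing.assert_allclose(
            summary.per_class_sensitivity, [35 / 36, 1.0]
        )
        np.testing.assert_allclose(
            summary.per_class_specificity, [1.0, 35 / 36]
        )
        assert summary.overall_specificity == pytest.approx(
            (36 * 1.0 + 31 * 35 / 36) / 67
        )

    def test_adding_correct_sample_never_lowers_sensitivity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.integers(0, 20, size=(2, 2)).astype(float)
            if c.sum() == 0:
                continue
            s = ek.ConfusionSummary(classes=("A", "B"), confusion=c)
            c2 = c.copy()
            c2[0, 0] += 1
            s2 = ek.ConfusionSummary(classes=("A", "B"), confusion=c2)
            assert s2.overall_sensitivity >= s.overall_sensitivity - 1e-12


class TestLoocv:
    def test_wrapper_equals_manual_refit_loop(self):
        table = _gaussian_toy(seed=3, shift=1.0)
        features = ("F0", "F1")
        summary = ek.loocv_evaluate(table, features)
        # independent oracle: per-fold refits through sklearn, equal priors
        X = table.features[list(features)].to_numpy()
        y = table.labels.to_numpy()
        confusion = np.zeros((2, 2))
        classes = ("Coa", "Douro")
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            sk.fit(X[mask], y[mask])
            pred = sk.predict(X[i : i + 1])[0]
            confusion[classes.index(y[i]), classes.index(pred)] += 1
        np.testing.assert_array_equal(summary.confusion, confusion)

    def test_perfectly_separable_data_scores_one(self):
        X = np.column_stack(
            [np.r_[np.zeros(10), np.ones(10) * 100]]
            + [np.random.default_rng(0).normal(size=20)]
        )
        table = make_table(X, ["Coa"] * 10 + ["Douro"] * 10)
        summary = ek.loocv_evaluate(table, ("F0",))
        assert summary.overall_sensitivity == 1.0
        assert summary.overall_specificity == 1.0
        assert not summary.fold_errors

    def test_fold_failure_recorded_not_skipped(self):
        # a class with exactly 2 members fails inside its own folds
        X = np.random.default_rng(0).normal(size=(12, 2))
        table = make_table(X, ["Coa"] * 10 + ["Douro"] * 2)
        summary = ek.loocv_evaluate(table, ("F0", "F1"))
        assert len(summary.fold_errors) == 2
        assert summary.confusion.sum() == 10


class TestSASelection:
    def _noise_problem(self, seed=0, n=30, p=10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        labels = ["Coa"] * (n // 2) + ["Douro"] * (n - n // 2)
        X[np.array(labels) == "Coa", 0] += 8.0  # one decisive feature
        return make_table(X, labels)

    def test_finds_exhaustive_optimum_with_decisive_feature(self):
        table = self._noise_problem()
        params = ek.SAParams(
            max_subset_size=3, n_moves=400, steps_per_temp=15, gamma=0.9,
            n_restarts=2, seed=0,
        )
        result = ek.sa_select_features(table, params)
        best = np.inf
        for r in range(1, 4):
            for sub in itertools.combinations(table.columns, r):
                e = classification_energy(ek.loocv_evaluate(table, sub))
                best = min(best, e + params.parsimony_eps * len(sub))
        assert result.energy == pytest.approx(best, abs=1e-12)
        assert "F0" in result.selected_features

    def test_uninformative_labels_keep_energy_high(self):
        fails = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 6))
            labels = ["Coa"] * 15 + ["Douro"] * 15
            table = make_table(X, labels)
            params = ek.SAParams(
                max_subset_size=3, n_moves=200, steps_per_temp=10, gamma=0.9,
                n_restarts=1, seed=seed,
            )
            result = ek.sa_select_features(table, params)
            fails += result.energy < 0.25
        assert fails <= 1  # LOO accuracy stays near chance for noise labels

    def test_zero_cooling_is_greedy_and_deterministic(self):
        table = self._noise_problem(seed=1)
        params = ek.SAParams(
            max_subset_size=3, t0=0.0, gamma=0.0, n_moves=150, n_restarts=1, seed=3
        )
        a = ek.sa_select_features(table, params)
        b = ek.sa_select_features(table, params)
        assert a.selected_features == b.selected_features
        assert a.energy == b.energy

    def test_bad_params_rejected(self):
        table = self._noise_problem()
        with pytest.raises(ValueError):
            ek.sa_select_features(table, ek.SAParams(max_subset_size=0))
        with pytest.raises(ValueError, match="empty"):
            ek.sa_select_features(table, ek.SAParams(), candidates=[])


class TestClassify:
    def test_missing_feature_named(self):
        table = _gaussian_toy()
        model = ek.fit_lda(table, ["F0", "F1"])
        with pytest.raises(ValueError, match="F1"):
            ek.classify(model, table.features[["F0"]])

    def test_single_sample(self):
        table = _gaussian_toy()
        model = ek.fit_lda(table, ["F0", "F1"])
        pred = ek.classify(model, table.features.iloc[:1])
        assert len(pred) == 1
        assert pred.iloc[0] in ("Coa", "Douro")

    def test_invariant_to_extra_columns(self):
        table = _gaussian_toy(seed=5)
        model = ek.fit_lda(table, ["F0", "F1"])
        base = ek.classify(model, table)
        extended = table.features.copy()
        extended["junk"] = 999.0
        again = ek.classify(model, extended)
        assert (base.to_numpy() == again.to_numpy()).all()
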