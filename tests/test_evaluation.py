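import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatigueml.classifiers import (
    CLASSIFIER_IDS,
    KernelNaiveBayes,
    make_classifier,
    median_heuristic_gamma,
)
from fatigueml.evaluation import (
    ConfusionCounts,
    EvalConfig,
    SELECTOR_IDS,
    _standardize,
    balanced_accuracy,
    loso_evaluate,
    make_subset_objective,
    metrics_from_confusion,
    run_grid,
    undersample_balance,
)
from fatigueml.selection import GAParams, SelectionConfig

from conftest import toy_labeled_table


class TestBalancedAccuracy:
    def test_lopsided_classifier_is_near_seventy_percent(self):
        # perfect sensitivity with chance specificity still reads ~70.7%
        assert balanced_accuracy(1.0, 0.5) == pytest.approx(0.7071, abs=5e-4)

    def test_printed_table_cell(self):
        assert balanced_accuracy(0.863, 0.771) == pytest.approx(0.816, abs=5e-4)

    @pytest.mark.parametrize("s", [0.0, 0.3, 1.0])
    def test_idempotent_on_equal_arguments(self, s):
        assert balanced_accuracy(s, s) == pytest.approx(s)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(1.2, 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_bounded_by_min_max_and_arithmetic_mean(self, sens, spec):
        ba = balanced_accuracy(sens, spec)
        assert min(sens, spec) - 1e-12 <= ba <= max(sens, spec) + 1e-12
        assert ba <= (sens + spec) / 2 + 1e-12


class TestMetricsFromConfusion:
    def test_hand_arithmetic(self):
        m = metrics_from_confusion(ConfusionCounts(tp=8, fn=2, tn=9, fp=1))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.9)
        assert m.balanced_accuracy == pytest.approx(np.sqrt(0.72))
        assert m.bias == pytest.approx(-0.1)

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert (m.sensitivity, m.specificity, m.balanced_accuracy, m.bias) == (1, 1, 1, 0)

    def test_all_positive_predictor(self):
        m = metrics_from_confusion(ConfusionCounts(tp=5, fn=0, tn=0, fp=5))
        assert (m.sensitivity, m.specificity, m.balanced_accuracy, m.bias) == (1, 0, 0, 1)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


class TestUndersample:
    def make_data(self, n0, n1, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"label": [0] * n0 + [1] * n1, "x": rng.normal(size=n0 + n1)}
        )

    def test_majority_downsampled_to_minority(self):
        out = undersample_balance(self.make_data(153, 80), seed=1)
        assert out["label"].value_counts().to_dict() == {0: 80, 1: 80}

    def test_minority_rows_untouched(self):
        data = self.make_data(153, 80)
        out = undersample_balance(data, seed=2)
        assert out[out["label"] == 1].equals(data[data["label"] == 1])

    def test_already_balanced_is_identity(self):
        data = self.make_data(50, 50)
        assert undersample_balance(data, seed=3).equals(data)

    def test_two_seeds_same_counts_possibly_different_rows(self):
        data = self.make_data(100, 30)
        a = undersample_balance(data, seed=4)
        b = undersample_balance(data, seed=5)
        assert a["label"].value_counts().to_dict() == b["label"].value_counts().to_dict()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            undersample_balance(self.make_data(10, 0), seed=6)


class TestStandardization:
    def test_statistics_come_from_training_rows_only(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3.0, 2.0, size=(50, 4))
        test_a = rng.normal(size=(10, 4))
        test_b = test_a * 1e6  # wildly different test rows
        tr_a, te_a = _standardize(train, test_a)
        tr_b, _ = _standardize(train, test_b)
        assert np.array_equal(tr_a, tr_b)
        mu, sd = train.mean(axis=0), train.std(axis=0)
        assert np.allclose(te_a, (test_a - mu) / sd)

    def test_transformed_training_is_zscored(self):
        rng = np.random.default_rng(1)
        train = rng.normal(5, 3, size=(100, 3))
        tr, _ = _standardize(train, train)
        assert np.allclose(tr.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(tr.std(axis=0), 1, atol=1e-12)


class TestClassifierZoo:
    def separated_clouds(self, seed=0, n=60, d=3, sep=4.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = (rng.random(n) < 0.5).astype(int)
        X[y == 1] += sep
        return X, y

    @pytest.mark.parametrize("spec_id", CLASSIFIER_IDS)
    def test_every_classifier_separates_distant_clouds(self, spec_id):
        X, y = self.separated_clouds()
        clf = make_classifier(spec_id, seed=0, X=X)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.95

    def test_knn_k1_has_perfect_training_recall(self):
        X, y = self.separated_clouds(seed=1, sep=1.0)
        clf = make_classifier("KNN", n_neighbors=1)
        clf.fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_kernel_nb_probabilities_normalized(self):
        X, y = self.separated_clouds(seed=2)
        for kernel in ("box", "triangular", "epanechnikov"):
            clf = KernelNaiveBayes(kernel=kernel).fit(X, y)
            p = clf.predict_proba(X)
            assert np.allclose(p.sum(axis=1), 1.0)

    def test_kernel_nb_rejects_non_finite(self):
        X, y = self.separated_clouds(seed=3)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            KernelNaiveBayes().fit(X, y)

    def test_median_heuristic_positive(self):
        X, _ = self.separated_clouds(seed=4)
        assert median_heuristic_gamma(X) > 0

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("RF")


class TestLoso:
    def separable_table(self, seed=0):
        data = toy_labeled_table(seed, n_subjects=6, rows_per_subject=8,
                                 n_features=3, n_informative=3, shift=30.0)
        return data

    def test_separable_data_reaches_perfect_balanced_accuracy(self):
        data = self.separable_table()
        m, _ = loso_evaluate("LSVM", data, ("f0", "f1", "f2"), EvalConfig(seed=0, n_iterations=2))
        assert m.balanced_accuracy == pytest.approx(1.0)

    def test_protocol_accounting(self):
        data = toy_labeled_table(1, n_subjects=5, rows_per_subject=6)
        cfg = EvalConfig(seed=0, n_iterations=3)
        _, detail = loso_evaluate("NBNRM", data, ("f0", "f1"), cfg)
        per_subject = pd.DataFrame(detail).groupby("subject").size()
        assert (per_subject == cfg.n_iterations).all()
        total = sum(d["tp"] + d["fn"] + d["tn"] + d["fp"] for d in detail)
        assert total == cfg.n_iterations * len(data)

    def test_pooled_counts_conserve_class_totals(self):
        data = toy_labeled_table(2, n_subjects=5, rows_per_subject=6)
        cfg = EvalConfig(seed=0, n_iterations=2)
        _, detail = loso_evaluate("KNN", data, ("f0", "f1", "f2"), cfg)
        df = pd.DataFrame(detail)
        assert (df["tp"] + df["fn"]).sum() == cfg.n_iterations * (data["label"] == 1).sum()
        assert (df["tn"] + df["fp"]).sum() == cfg.n_iterations * (data["label"] == 0).sum()

    def test_null_labels_score_at_chance(self):
        """Shuffled labels carry no signal: mean LOSO balanced accuracy over
        seeds should sit at 0.5."""
        bas = []
        for seed in range(20):
            data = toy_labeled_table(seed, n_subjects=8, rows_per_subject=8,
                                     n_features=4, n_informative=0, shift=0.0)
            m, _ = loso_evaluate(
                "KNN", data, ("f0", "f1", "f2", "f3"), EvalConfig(seed=seed, n_iterations=1)
            )
            bas.append(m.balanced_accuracy)
        assert np.mean(bas) == pytest.approx(0.5, abs=0.06)

    def test_reproducible_under_fixed_seed(self):
        data = toy_labeled_table(3, n_subjects=5, rows_per_subject=6)
        cfg = EvalConfig(seed=11, n_iterations=2)
        m1, d1 = loso_evaluate("TREE", data, ("f0", "f1"), cfg)
        m2, d2 = loso_evaluate("TREE", data, ("f0", "f1"), cfg)
        assert m1 == m2
        assert d1 == d2


class TestObjective:
    def test_informative_subset_beats_noise_subset(self):
        data = toy_labeled_table(4, n_subjects=8, rows_per_subject=10,
                                 n_features=6, n_informative=2, shift=2.5)
        obj = make_subset_objective("LSVM", data, EvalConfig(seed=0))
        assert obj(("f0", "f1")) > obj(("f4", "f5"))

    def test_empty_subset_scores_zero(self):
        data = toy_labeled_table(5, n_subjects=4, rows_per_subject=6)
        obj = make_subset_objective("LSVM", data, EvalConfig(seed=0))
        assert obj(()) == 0.0


class TestGrid:
    @pytest.fixture(scope="class")
    def grid(self):
        data = toy_labeled_table(6, n_subjects=6, rows_per_subject=10,
                                 n_features=6, n_informative=3, shift=2.0)
        ec = EvalConfig(seed=0, n_iterations=2, selection_scope="global")
        sc = SelectionConfig(max_features=3, ga=GAParams(population=10, generations=5))
        result = run_grid(
            data, [f"f{i}" for i in range(6)], ec, sc,
            classifiers=("LSVM", "NBNRM", "KNN"),
        )
        return result

    def test_shape_and_no_failures(self, grid):
        assert grid.balanced_accuracy.shape == (3, len(SELECTOR_IDS))
        assert grid.failures == []
        assert not grid.balanced_accuracy.isna().any().any()

    def test_ba_is_geometric_mean_of_sens_spec(self, grid):
        ba = np.sqrt(grid.sensitivity * grid.specificity)
        assert np.allclose(grid.balanced_accuracy, ba, atol=1e-12)

    def test_ba_bounded_by_arithmetic_mean(self, grid):
        am = (grid.sensitivity + grid.specificity) / 2
        assert (grid.balanced_accuracy.values <= am.values + 1e-12).all()

    def test_bias_is_sens_minus_spec(self, grid):
        assert np.allclose(grid.bias, grid.sensitivity - grid.specificity, atol=1e-12)
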