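"""ROC statistics, repeated-CV evaluation and final model training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pascdx.errors import ConfigurationError, InsufficientDataError
from pascdx.features import LabeledDescriptorTable
from pascdx.modeling import (
    ModelSpec,
    cross_validate,
    roc_auc,
    roc_curve,
    train_final,
)

from conftest import make_table

FAST_LR = ModelSpec(family="LR", grid={"clf__C": [1.0]}, seed=0)


def brute_force_auc(scores, labels):
    """Pairwise Mann–Whitney count: ties as 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_frozen_example_with_tie(self):
        # pos=[0.8, 0.5], neg=[0.5, 0.2]: 3 wins + 1 tie of 4 pairs = 0.875
        assert roc_auc([0.8, 0.5, 0.5, 0.2], [1, 1, 0, 0]) == 0.875

    def test_perfect_and_chance(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(4, 30)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            labels = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)  # tie-free
        labels = np.r_[np.ones(25, int), np.zeros(25, int)]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, raw):
        scores = np.asarray(raw)
        labels = np.r_[np.ones(len(scores) // 2, int),
                       np.zeros(len(scores) - len(scores) // 2, int)]
        base = roc_auc(scores, labels)
        # scaling by a power of two is an exact, strictly increasing map
        assert roc_auc(scores * 8.0, labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRocCurve:
    def test_minimal_curve(self):
        fpr, tpr, thr = roc_curve([1.0, 0.0], [1, 0])
        assert fpr.tolist() == [0.0, 0.0, 1.0]
        assert tpr.tolist() == [0.0, 1.0, 1.0]

    def test_identical_scores_diagonal(self):
        fpr, tpr, _ = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert fpr.tolist() == [0.0, 1.0]
        assert tpr.tolist() == [0.0, 1.0]

    def test_trapezoid_equals_auc_and_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.choice(np.linspace(0, 1, 9), size=40)
            labels = np.r_[1, 0, rng.integers(0, 2, 38)]
            fpr, tpr, _ = roc_curve(scores, labels)
            assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
            assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
            assert np.trapezoid(tpr, fpr) == pytest.approx(
                roc_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = (scores + rng.normal(size=200) > 0).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestCrossValidate:
    def test_separable_table_high_auc(self):
        table = make_table(n_per_class=100, n_descriptors=10, n_informative=4,
                           shift=5.0, seed=1)
        report = cross_validate(table, FAST_LR, n_repeats=2, seed=0)
        assert report.mean_auc >= 0.99
        assert report.ci_low <= report.mean_auc <= report.ci_high
        assert ((report.fold_aucs >= 0) & (report.fold_aucs <= 1)).all()

    def test_permuted_labels_near_chance(self):
        table = make_table(n_per_class=100, n_descriptors=10, n_informative=4,
                           shift=2.0, seed=2)
        rng = np.random.default_rng(0)
        permuted = LabeledDescriptorTable(
            table.descriptors,
            table.labels.sample(frac=1.0, random_state=rng.integers(2**31))
            .set_axis(table.labels.index),
        )
        report = cross_validate(permuted, FAST_LR, n_repeats=2, seed=0)
        assert 0.4 <= report.mean_auc <= 0.6

    def test_same_seed_identical_report(self, small_table):
        a = cross_validate(small_table, FAST_LR, n_repeats=2, seed=3)
        b = cross_validate(small_table, FAST_LR, n_repeats=2, seed=3)
        assert np.array_equal(a.fold_aucs, b.fold_aucs)
        assert a.to_dict() == b.to_dict()

    def test_too_small_class_rejected(self):
        table = make_table(n_per_class=3, n_descriptors=4, n_informative=1, seed=0)
        with pytest.raises(InsufficientDataError):
            cross_validate(table, FAST_LR, n_folds=5, n_repeats=1, seed=0)

    def test_grid_search_selects_hyperparameters(self, small_table):
        spec = ModelSpec(family="LR", grid={"clf__C": [0.01, 1.0]}, seed=0)
        report = cross_validate(small_table, spec, n_repeats=1, seed=0)
        assert set(report.best_hyperparameters) == {"clf__C"}

    def test_leakage_canary(self):
        """A column informative only on one fold's rows cannot lift CV AUC.

        The canary column encodes the label on a subset of rows and is
        noise elsewhere. A leak-free pipeline (selection and scaling
        inside training folds) learns nothing usable from it, so AUC
        stays near chance on an otherwise signal-free table.
        """
        table = make_table(n_per_class=100, n_descriptors=8, n_informative=0,
                           shift=0.0, seed=6)
        rng = np.random.default_rng(0)
        canary = rng.normal(size=len(table))
        rows = rng.choice(len(table), size=40, replace=False)
        canary[rows] = table.y[rows] * 2.0 - 1.0
        df = table.descriptors.copy()
        df["canary"] = canary
        leaky = LabeledDescriptorTable(df, table.labels)
        report = cross_validate(leaky, FAST_LR, n_repeats=2, seed=0)
        assert report.mean_auc <= 0.75


class TestTrainFinal:
    def test_training_rows_scored_correctly(self, separable_table):
        model = train_final(separable_table, FAST_LR, seed=0)
        scores = model.score(separable_table)
        assert (scores[separable_table.y == 1] > 0.5).mean() > 0.95
        assert (scores[separable_table.y == 0] < 0.5).mean() > 0.95
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_wrong_dimension_rejected(self, small_table):
        model = train_final(small_table, FAST_LR, seed=0)
        with pytest.raises(ConfigurationError):
            model.score(np.zeros((3, 99)))

    def test_same_seed_identical_scores(self, small_table):
        probe = np.random.default_rng(1).normal(size=(10, 12))
        a = train_final(small_table, ModelSpec("MLP", {"clf__alpha": [1e-3]}, 0), seed=2)
        b = train_final(small_table, ModelSpec("MLP", {"clf__alpha": [1e-3]}, 0), seed=2)
        assert np.array_equal(a.score(probe), b.score(probe))

    @pytest.mark.parametrize("family", ["MLP", "RF", "LR", "SVM", "GB"])
    def test_all_families_fit_and_score(self, family, separable_table):
        spec = ModelSpec(family=family, grid={}, seed=0)
        model = train_final(separable_table, spec, seed=0)
        from pascdx.modeling import roc_auc as auc

        assert auc(model.score(separable_table), separable_table.y) > 0.9

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(family="XGB")
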