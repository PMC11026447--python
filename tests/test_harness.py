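"""Protocol harness: splits, metrics, training bookkeeping, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

from vitseq import (SplitSpec, TrainConfig, evaluate, random_split,
                    report_from_confusion, split_counts, train)
from vitseq.harness import (ARCHITECTURES, compare_architectures,
                            make_head, repeated_runs)
from vitseq.seq_models import TSTClassifier, TSTConfig


class TestSplitCounts:
    @pytest.mark.parametrize("n,expected", [
        (100, (60, 20, 20)),
        (351, (211, 70, 70)),
        (2294, (1378, 458, 458)),
    ])
    def test_sixty_twenty_twenty(self, n, expected):
        assert split_counts(n) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(3, 10 ** 6))
    def test_counts_conserve_total(self, n):
        tr, te, va = split_counts(n)
        assert tr + te + va == n
        assert te == int(np.floor(0.2 * n)) and va == int(np.floor(0.2 * n))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_counts(100, (0.5, 0.2, 0.2))


class TestRandomSplit:
    def _labels(self, counts):
        return np.repeat(["NC", "MCI", "AD"][:len(counts)], counts)

    def test_partition(self):
        labels = self._labels([7, 6, 7])
        tr, te, va = random_split(labels, SplitSpec(20, seed=0))
        all_idx = np.concatenate([tr, te, va])
        assert sorted(all_idx) == list(range(20))
        assert not (set(tr) & set(te) or set(tr) & set(va) or set(te) & set(va))

    def test_seed_determinism_and_sensitivity(self):
        labels = self._labels([10, 10, 10])
        a = random_split(labels, SplitSpec(30, seed=5))
        b = random_split(labels, SplitSpec(30, seed=5))
        c = random_split(labels, SplitSpec(30, seed=6))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_stratified_allocation_15_items(self):
        """5 per class at (0.6,0.2,0.2): splits get (3,3,3)/(1,1,1)/(1,1,1)."""
        labels = self._labels([5, 5, 5])
        tr, te, va = random_split(labels, SplitSpec(15, seed=1), stratified=True)
        for idx, per_class in [(tr, 3), (te, 1), (va, 1)]:
            counts = [np.sum(labels[idx] == c) for c in ("NC", "MCI", "AD")]
            assert counts == [per_class] * 3

    def test_stratified_proportions_within_one(self):
        labels = self._labels([13, 7, 10])
        tr, te, va = random_split(labels, SplitSpec(30, seed=2), stratified=True)
        assert len(te) == 6 and len(va) == 6 and len(tr) == 18
        for c, n_c in zip(("NC", "MCI", "AD"), (13, 7, 10)):
            ideal = 6 * n_c / 30
            got = np.sum(labels[te] == c)
            assert abs(got - ideal) <= 1

    def test_tiny_class_infeasible(self):
        labels = np.array(["NC"] * 9 + ["AD"])
        with pytest.raises(ValueError, match="infeasible"):
            random_split(labels, SplitSpec(10, seed=0), stratified=True)

    def test_unstratified_split_sizes(self):
        labels = self._labels([10, 10, 10])
        tr, te, va = random_split(labels, SplitSpec(30, seed=0),
                                  stratified=False)
        assert (len(tr), len(te), len(va)) == (18, 6, 6)


class TestMetrics:
    def test_perfect_classifier(self):
        r = report_from_confusion([[50, 0], [0, 50]], ("NC", "AD"))
        assert r.accuracy == 100.0
        assert np.all(r.precision == 1.0) and np.all(r.recall == 1.0)
        assert np.all(r.f1 == 1.0)

    def test_forced_arithmetic_case(self):
        r = report_from_confusion([[45, 5], [10, 40]], ("NC", "AD"))
        assert np.isclose(r.accuracy, 85.0)
        assert np.isclose(r.precision[0], 45 / 55)
        assert np.isclose(r.recall[0], 0.9)

    def test_all_one_class_predictor_flags_undefined(self):
        r = report_from_confusion([[50, 0], [50, 0]], ("NC", "AD"))
        assert r.accuracy == 50.0
        assert r.precision[1] == 0.0
        assert r.undefined_precision[1]
        assert not r.undefined_precision[0]

    def test_macro_is_unweighted_mean(self):
        r = report_from_confusion([[8, 2, 0], [1, 5, 4], [0, 0, 10]],
                                  ("NC", "MCI", "AD"))
        assert np.isclose(r.macro_precision, r.precision.mean())
        assert np.isclose(r.macro_f1, r.f1.mean())

    @pytest.mark.parametrize("confusion", [
        [[45, 5], [10, 40]],
        [[8, 2, 0], [1, 5, 4], [2, 0, 8]],
        [[3, 0], [0, 7]],
    ])
    def test_agrees_with_sklearn(self, confusion):
        """Metrics recomputed by an independent library implementation from
        reconstructed predictions agree exactly."""
        M = np.asarray(confusion)
        K = M.shape[0]
        names = tuple("C%d" % i for i in range(K))
        y_true = np.concatenate([[i] * M[i].sum() for i in range(K)])
        y_pred = np.concatenate([np.repeat(np.arange(K), M[i])
                                 for i in range(K)])
        p, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(K), zero_division=0)
        r = report_from_confusion(M, names)
        assert np.allclose(r.precision, p, atol=1e-12)
        assert np.allclose(r.recall, rec, atol=1e-12)
        assert np.allclose(r.f1, f1, atol=1e-12)
        assert np.isclose(r.accuracy, 100 * np.mean(y_true == y_pred))

    def test_invalid_confusion_rejected(self):
        with pytest.raises(ValueError):
            report_from_confusion([[1, 2, 3]], ("a", "b"))
        with pytest.raises(ValueError):
            report_from_confusion([[0, 0], [0, 0]], ("a", "b"))


def _toy_features(n=8, T=6, D=8, seed=0):
    """Linearly separable toy feature sequences, half class 0, half class 1."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, T, D)) * 0.3
    X[y == 1, :, :2] += 1.5
    return X, y


class TestTrain:
    def test_one_epoch_history_bookkeeping(self):
        X, y = _toy_features()
        model = make_head("ViT-TST", 8, 2, seed=0)
        h = train(model, X, y, cfg=TrainConfig(epochs=1, seed=0))
        assert len(h["train_loss"]) == 1
        assert h["val_loss"] == []

    def test_memorization_loss_decreases(self):
        """Training loss on a 4-sample memorization task decreases over 50
        epochs for the test-scale transformer head."""
        X, y = _toy_features(n=4)
        model = TSTClassifier(TSTConfig(model_dim=8, n_classes=2, seed=0))
        h = train(model, X, y, cfg=TrainConfig(lr=1e-3, epochs=50, seed=0))
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_identical_seeds_identical_weights(self):
        X, y = _toy_features()
        runs = []
        for _ in range(2):
            model = make_head("ViT-TST", 8, 2, seed=3)
            train(model, X, y, cfg=TrainConfig(lr=1e-3, epochs=5, seed=3))
            runs.append(model.state_dict())
        assert all(np.array_equal(runs[0][k], runs[1][k]) for k in runs[0])

    def test_empty_split_rejected(self):
        model = make_head("ViT-TST", 8, 2, seed=0)
        with pytest.raises(ValueError):
            train(model, np.empty((0, 6, 8)), np.empty(0, dtype=int))

    def test_early_stopping_truncates_on_unlearnable_validation(self):
        # pure-noise labels: validation loss cannot keep improving, so the
        # patience rule must cut training well short of the epoch budget
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6, 8))
        y = rng.integers(0, 2, size=10)
        model = make_head("ViT-TST", 8, 2, seed=0)
        h = train(model, X[:6], y[:6], X[6:], y[6:],
                  TrainConfig(lr=1e-3, epochs=500, patience=3, seed=0))
        assert len(h["train_loss"]) < 500


class TestEvaluate:
    def test_report_totals_and_label_guard(self):
        X, y = _toy_features(n=10)
        model = make_head("ViT-TST", 8, 2, seed=0)
        train(model, X, y, cfg=TrainConfig(lr=1e-3, epochs=30, seed=0))
        r = evaluate(model, X, y, ("NC", "AD"))
        assert r.n_samples == 10
        with pytest.raises(ValueError, match="label outside"):
            evaluate(model, X, np.array([0, 1, 2] + [0] * 7), ("NC", "AD"))


class TestRepeatedRuns:
    def test_k_entries_and_determinism(self):
        X, y = _toy_features(n=20)
        agg1 = repeated_runs(X, y, ("NC", "AD"), "ViT-TST", k=3, base_seed=0,
                             train_cfg=TrainConfig(lr=1e-3, epochs=10))
        agg2 = repeated_runs(X, y, ("NC", "AD"), "ViT-TST", k=3, base_seed=0,
                             train_cfg=TrainConfig(lr=1e-3, epochs=10))
        assert agg1.k == 3
        assert agg1.accuracy_mean == agg2.accuracy_mean
        assert agg1.accuracy_std == agg2.accuracy_std
        assert np.array_equal(agg1.confusion_total, agg2.confusion_total)

    def test_zero_variance_when_perfectly_separable(self):
        X, y = _toy_features(n=20, seed=1)
        X[y == 1, :, :4] += 10.0  # overwhelming separation
        agg = repeated_runs(X, y, ("NC", "AD"), "ViT-TST", k=3, base_seed=0,
                            train_cfg=TrainConfig(lr=3e-3, epochs=40))
        assert agg.accuracy_mean == 100.0
        assert agg.accuracy_std == 0.0

    def test_k_below_two_rejected(self):
        X, y = _toy_features()
        with pytest.raises(ValueError):
            repeated_runs(X, y, ("NC", "AD"), "ViT-TST", k=1, base_seed=0)


@pytest.fixture(scope="module")
def compare_volumes():
    from vitseq import PhantomSpec, generate_dataset
    return generate_dataset(PhantomSpec(grid_shape=(32, 40, 32),
                                        n_per_class=5, seed=7))


class TestCompareArchitectures:
    def test_cartesian_bookkeeping_and_binary_filter(self, compare_volumes):
        """4 architectures x 3 planes -> 12 rows; binary task drops MCI."""
        table, confusions = compare_architectures(
            compare_volumes, ["axial", "coronal", "sagittal"],
            list(ARCHITECTURES), task="binary", k=2, base_seed=0,
            train_cfg=TrainConfig(lr=1e-3, epochs=2), feature_dim=8)
        assert len(table) == 12
        assert set(table.architecture) == set(ARCHITECTURES)
        # binary filter: only the 4 NC/AD volumes remain; 2 runs x 0.2 test
        # hold-out never contains an MCI scan and totals match NC+AD counts
        for M in confusions.values():
            assert M.shape == (2, 2)        # NC/AD only: MCI filtered out
            assert M.sum() == 2 * 2          # k=2 runs x 2 test scans (of 10)
        assert len(confusions) == 12

    def test_unknown_selection_rejected(self, small_volumes):
        with pytest.raises(ValueError):
            compare_architectures(small_volumes, ["axial"], ["ResNet"],
                                  task="binary", k=2)
        with pytest.raises(ValueError):
            compare_architectures(small_volumes, [], ["ViT-TST"],
                                  task="binary", k=2)
        with pytest.raises(ValueError):
            compare_architectures(small_volumes, ["axial"], ["ViT-TST"],
                                  task="regression", k=2)
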