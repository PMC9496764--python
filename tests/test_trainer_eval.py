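import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcfn.model import FusionNet, GCFNConfig
from gcfn.trainer_eval import (
    TrainConfig,
    confusion_metrics,
    cross_entropy,
    kappa,
    make_folds,
    train_and_evaluate,
)

TINY = GCFNConfig(
    cnn_filters=2, cnn_kernel=(8, 1), gru1_units=3, gru2_units=4,
    fc1_units=5, dropout_p=0.0, eeg_input=(7, 3), image_input=(8, 6, 1),
)


class TestCrossEntropy:
    def test_closed_forms(self):
        perfect = np.eye(4)
        labels = np.eye(4)
        assert cross_entropy(perfect, labels) <= 1e-10
        uniform = np.full((3, 4), 0.25)
        y = np.eye(4)[:3]
        np.testing.assert_allclose(cross_entropy(uniform, y), np.log(4), rtol=1e-12)
        half = np.array([[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]])
        np.testing.assert_allclose(cross_entropy(half, np.eye(4)[:1]), np.log(2),
                                   rtol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy(np.full((2, 4), 0.25), np.eye(4)[:3])


class TestKappa:
    @pytest.mark.parametrize(
        "p0,expected",
        [(0.807, 0.74), (0.727, 0.64), (0.629, 0.51), (0.731, 0.64)],
    )
    def test_published_accuracy_mapping(self, p0, expected):
        assert round(kappa(p0), 2) == expected

    def test_anchors(self):
        assert kappa(0.25) == 0.0
        assert kappa(1.0) == 1.0

    @given(st.floats(0.0, 1.0), st.floats(0.0, 0.99))
    def test_strictly_increasing_in_accuracy(self, p0, pe):
        assert kappa(min(p0 + 0.01, 1.0), pe) >= kappa(p0, pe)
        if p0 + 0.01 <= 1.0:
            assert kappa(p0 + 0.01, pe) > kappa(p0, pe)

    def test_degenerate_pe(self):
        with pytest.raises(ValueError):
            kappa(0.5, pe=1.0)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.repeat(np.arange(4), 10)
        m = confusion_metrics(y, y)
        assert m.accuracy == 1.0 and m.kappa == 1.0
        np.testing.assert_array_equal(m.precision, np.ones(4))
        np.testing.assert_array_equal(m.recall, np.ones(4))

    def test_constant_predictor_is_chance(self):
        y = np.repeat(np.arange(4), 10)
        m = confusion_metrics(y, np.zeros_like(y))
        assert m.accuracy == 0.25
        assert m.kappa == 0.0
        assert np.isnan(m.precision[1:]).all()  # classes never predicted
        np.testing.assert_allclose(m.recall, [1, 0, 0, 0])

    def test_hand_computed_toy_matrix(self):
        # 8 trials, two errors: one 0->1 and one 2->3
        y_true = [0, 0, 1, 1, 2, 2, 3, 3]
        y_pred = [0, 1, 1, 1, 2, 3, 3, 3]
        m = confusion_metrics(y_true, y_pred)
        expected = np.array([[1, 1, 0, 0], [0, 2, 0, 0], [0, 0, 1, 1], [0, 0, 0, 2]])
        np.testing.assert_array_equal(m.confusion, expected)
        assert m.accuracy == 0.75
        np.testing.assert_allclose(m.kappa, (0.75 - 0.25) / 0.75)
        np.testing.assert_allclose(m.recall, [0.5, 1.0, 0.5, 1.0])
        np.testing.assert_allclose(m.precision, [1.0, 2 / 3, 1.0, 2 / 3])

    def test_row_sums_depend_only_on_truth(self, rng):
        y_true = rng.integers(0, 4, 60)
        a = confusion_metrics(y_true, rng.integers(0, 4, 60))
        b = confusion_metrics(y_true, rng.integers(0, 4, 60))
        np.testing.assert_array_equal(a.confusion.sum(axis=1), b.confusion.sum(axis=1))

    def test_macro_recall_equals_accuracy_when_balanced(self, rng):
        y_true = np.repeat(np.arange(4), 25)
        y_pred = rng.integers(0, 4, 100)
        m = confusion_metrics(y_true, y_pred)
        np.testing.assert_allclose(np.nanmean(m.recall), m.accuracy)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestFolds:
    def test_paper_mode_partition(self):
        folds = make_folds(100, mode="paper", seed=0)
        assert len(folds) == 10
        all_val = np.concatenate([f.val_idx for f in folds])
        assert len(all_val) == 100 and len(np.unique(all_val)) == 100
        for f in folds:
            assert len(f.val_idx) == 10
            assert np.intersect1d(f.train_idx, f.val_idx).size == 0
            assert len(f.train_idx) + len(f.val_idx) == 100

    def test_group_safe_keeps_copies_together(self):
        groups = np.repeat(np.arange(30), 11)  # 30 source trials x 11 copies
        folds = make_folds(330, groups=groups, mode="group_safe", seed=1)
        for f in folds:
            assert np.intersect1d(np.unique(groups[f.train_idx]),
                                  np.unique(groups[f.val_idx])).size == 0

    def test_paper_mode_warns_on_grouped_input(self):
        groups = np.repeat(np.arange(5), 4)
        with pytest.warns(UserWarning, match="leakage"):
            make_folds(20, groups=groups, mode="paper", seed=0)

    def test_deterministic_given_seed(self):
        a = make_folds(57, mode="paper", seed=9)
        b = make_folds(57, mode="paper", seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.val_idx, fb.val_idx)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            make_folds(5)


class TestTrainAndEvaluate:
    @pytest.fixture()
    def toy_data(self, rng):
        n = 120
        eeg = rng.standard_normal((n, 7, 3))
        images = rng.random((n, 8, 6))
        labels = np.tile(np.arange(4), n // 4)
        return eeg, images, labels

    def test_untrained_model_sits_at_chance(self, toy_data):
        eeg, images, labels = toy_data
        folds = make_folds(len(labels), mode="paper", seed=0, n_folds=2)
        cfg = TrainConfig(max_epochs=0, seed=0)
        res = train_and_evaluate(lambda s: FusionNet(TINY, seed=s),
                                 eeg, images, labels, folds, cfg)
        assert 0.05 <= res["mean_accuracy"] <= 0.45  # 0.25 +- binomial noise

    def test_deterministic_replication(self, toy_data):
        eeg, images, labels = toy_data
        folds = make_folds(len(labels), mode="paper", seed=3, n_folds=2)
        cfg = TrainConfig(max_epochs=1, batch_size=32, seed=3)
        logs = [], []
        for log in logs:
            train_and_evaluate(lambda s: FusionNet(TINY, seed=s),
                               eeg, images, labels, folds, cfg, log=log)
        assert logs[0] == logs[1]  # identical per-epoch losses

    def test_each_branch_learns_its_separable_cue(self, rng):
        """The CNN branch decodes a class code written into the image
        pooling windows; the GRU branch decodes a class-coded channel
        offset in the time series."""
        n = 160
        labels = np.tile(np.arange(4), n // 4)
        images = rng.random((n, 8, 6)) * 0.1
        eeg = rng.standard_normal((n, 7, 3)) * 0.3
        for i, c in enumerate(labels):
            # binary class code across the two pooling windows (cols 0-2, 3-5)
            images[i, :, 0] += 1.0 * (c & 1)
            images[i, :, 3] += 1.0 * ((c >> 1) & 1)
            if c < 3:  # one-hot channel offset; class 3 = no offset
                eeg[i, :, c] += 1.0
        folds = make_folds(n, mode="paper", seed=1, n_folds=2)
        wider = GCFNConfig(
            cnn_filters=16, cnn_kernel=(8, 1), gru1_units=3, gru2_units=4,
            fc1_units=16, dropout_p=0.0, eeg_input=(7, 3), image_input=(8, 6, 1),
        )
        cfg = TrainConfig(max_epochs=120, learning_rate=3e-3, batch_size=32,
                          early_stop_patience=120, seed=1)
        cnn_only = train_and_evaluate(
            lambda s: FusionNet(wider, use_gru=False, seed=s),
            None, images, labels, folds, cfg)
        assert cnn_only["mean_accuracy"] > 0.8
        gru_only = train_and_evaluate(
            lambda s: FusionNet(wider, use_cnn=False, seed=s),
            eeg, None, labels, folds, cfg)
        assert gru_only["mean_accuracy"] > 0.8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="sgd")
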