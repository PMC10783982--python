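"""Classifier: deterministic initialisation, freeze protocol, training."""

import numpy as np
import pytest

from osteotex import (
    TrainConfig,
    build_model,
    load_model,
    predict_proba,
    pretrain,
    save_model,
    transfer_and_finetune,
)
from osteotex.boosting import ChannelStack
from osteotex.network import Conv2D, predict, prepare_inputs


@pytest.fixture(scope="module")
def toy_task():
    """Tiny separable 2-class task on raw 16x16 single-channel stacks."""
    rng = np.random.default_rng(33)
    n = 40
    X = np.empty((n, 16, 16, 1))
    y = np.empty(n, dtype=np.int64)
    for i in range(n):
        cls = i % 2
        base = 0.25 if cls == 0 else 0.75
        X[i, ..., 0] = np.clip(base + rng.normal(0, 0.08, (16, 16)), 0, 1)
        y[i] = cls
    return X, y


class TestBuild:
    def test_same_seed_identical_parameters(self):
        a = build_model((16, 16, 2), ["h", "d"], seed=5)
        b = build_model((16, 16, 2), ["h", "d"], seed=5)
        np.testing.assert_array_equal(a.parameter_vector(), b.parameter_vector())
        c = build_model((16, 16, 2), ["h", "d"], seed=6)
        assert not np.array_equal(a.parameter_vector(), c.parameter_vector())

    def test_parameter_budget_is_small(self):
        m = build_model((64, 64, 4), ["a", "b"], seed=0)
        assert m.n_parameters() < 100_000

    def test_untrained_probabilities_normalised(self, rng):
        m = build_model((16, 16, 1), ["a", "b"], seed=0)
        probs = predict_proba(m, rng.random((5, 16, 16, 1)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    @pytest.mark.parametrize("spec,classes", [((15, 16, 1), ["a", "b"]),
                                              ((16, 16, 0), ["a", "b"]),
                                              ((16, 16, 1), ["a"])])
    def test_invalid_specs_rejected(self, spec, classes):
        with pytest.raises(ValueError):
            build_model(spec, classes, seed=0)

    def test_unit_1x1_conv_sums_channels(self, rng):
        """A 1x1 all-ones kernel with no bias reduces to the channel sum."""
        x = rng.random((2, 4, 4, 3))
        conv = Conv2D(np.ones((1, 1, 3, 1)), np.zeros(1))
        out = conv.forward(x)
        np.testing.assert_allclose(out[..., 0], x.sum(axis=3), atol=1e-12)


class TestTraining:
    def test_zero_epochs_leaves_parameters_unchanged(self, toy_task):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=1)
        m2, log = pretrain(m, (X, y), TrainConfig(epochs=0, seed=0))
        np.testing.assert_array_equal(m.parameter_vector(), m2.parameter_vector())
        assert log == []

    def test_same_seed_same_final_parameters(self, toy_task):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=1)
        cfg = TrainConfig(epochs=3, seed=7)
        a, _ = pretrain(m, (X, y), cfg)
        b, _ = pretrain(m, (X, y), cfg)
        np.testing.assert_array_equal(a.parameter_vector(), b.parameter_vector())

    def test_training_improves_accuracy(self, toy_task):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=1)
        trained, log = pretrain(m, (X, y), TrainConfig(epochs=15, seed=7, learning_rate=0.1))
        init_acc = (predict_proba(m, X).argmax(1) == y).mean()
        final_acc = (predict_proba(trained, X).argmax(1) == y).mean()
        assert final_acc > init_acc
        # well above chance: 0.5 + 3 binomial s.e. at n=40
        assert final_acc > 0.5 + 3 * np.sqrt(0.25 / len(y))

    def test_empty_dataset_rejected(self):
        m = build_model((16, 16, 1), ["a", "b"], seed=1)
        with pytest.raises(ValueError, match="empty"):
            pretrain(m, (np.empty((0, 16, 16, 1)), np.empty(0, dtype=int)),
                     TrainConfig(epochs=1))


class TestFreezeProtocol:
    @pytest.mark.parametrize("k", [0, 2, 4])
    def test_frozen_blocks_bit_identical(self, toy_task, k):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=2)
        m, _ = pretrain(m, (X, y), TrainConfig(epochs=2, seed=3))
        tuned, _ = transfer_and_finetune(
            m, (X, y), TrainConfig(epochs=1, seed=4, freeze_upto=k)
        )
        before = [{n: p.copy() for n, p in b.params().items()} for b in m.blocks]
        after = [{n: p for n, p in b.params().items()} for b in tuned.blocks]
        for i in range(m.n_blocks):
            same = all(
                np.array_equal(before[i][n], after[i][n]) and
                before[i][n].tobytes() == after[i][n].tobytes()
                for n in before[i]
            )
            if i < k:
                assert same, f"frozen block {i} changed"
            else:
                assert not same, f"trainable block {i} did not change"

    def test_freeze_all_returns_identical_model(self, toy_task):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=2)
        tuned, _ = transfer_and_finetune(
            m, (X, y), TrainConfig(epochs=2, seed=4, freeze_upto=m.n_blocks)
        )
        assert m.parameter_vector().tobytes() == tuned.parameter_vector().tobytes()

    def test_freeze_zero_equals_ordinary_training(self, toy_task):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=2)
        cfg = TrainConfig(epochs=2, seed=4, freeze_upto=0)
        a, _ = transfer_and_finetune(m, (X, y), cfg)
        b, _ = pretrain(m, (X, y), cfg)
        np.testing.assert_array_equal(a.parameter_vector(), b.parameter_vector())

    def test_out_of_range_freeze_rejected(self, toy_task):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=2)
        with pytest.raises(ValueError, match="freeze_upto"):
            transfer_and_finetune(m, (X, y), TrainConfig(epochs=1, freeze_upto=99))


class TestPredictAndCheckpoints:
    def test_predict_single_stack(self):
        m = build_model((16, 16, 1), ["healthy", "diseased"], seed=0)
        stack = ChannelStack(
            channels=np.random.default_rng(0).random((16, 16, 1)),
            natural_count=1, provenance=(),
        )
        probs = predict(m, stack)
        assert set(probs) == {"healthy", "diseased"}
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-6)
        again = predict(m, stack)
        assert probs == again

    def test_shape_mismatch_rejected(self, rng):
        m = build_model((16, 16, 1), ["a", "b"], seed=0)
        with pytest.raises(ValueError, match="shape"):
            predict_proba(m, rng.random((2, 16, 16, 3)))

    def test_checkpoint_roundtrip(self, toy_task, tmp_path):
        X, y = toy_task
        m = build_model((16, 16, 1), ["a", "b"], seed=3)
        m, _ = pretrain(m, (X, y), TrainConfig(epochs=1, seed=5))
        path = tmp_path / "model.npz"
        save_model(m, path)
        loaded = load_model(path)
        assert loaded.classes == m.classes and loaded.input_spec == m.input_spec
        np.testing.assert_array_equal(m.parameter_vector(), loaded.parameter_vector())
        np.testing.assert_allclose(
            predict_proba(m, X[:4]), predict_proba(loaded, X[:4]), atol=1e-12
        )

    def test_prepare_inputs_boosts_and_encodes(self, small_two_class_dataset):
        X, y, classes = prepare_inputs(small_two_class_dataset, [])
        assert X.shape == (40, 32, 32, 1)
        assert set(y.tolist()) == {0, 1} and len(classes) == 2
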