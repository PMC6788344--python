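"""Siamese network: architecture contracts, gradients, training behaviour."""

import numpy as np
import pytest

from longisym.errors import ConfigurationError, InputError, TrainingError
from longisym.nn import (
    DeepSymNetConfig,
    DeepSymNetModel,
    InceptionSpec,
    TrainConfig,
    build,
    train,
)
from longisym.phantom import PhantomConfig, generate_cohort
from tests.conftest import records_to_dataset


def _rand_pairs(n, shape=(16, 16, 16), seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((n, *shape), dtype=np.float32), rng.random(
        (n, *shape), dtype=np.float32
    )


class TestArchitecture:
    def test_identical_inputs_give_one_constant_for_every_input(self, small_model):
        """|a-a| merge zeroes the head's input, so forward(x,x) ignores x."""
        outs = []
        for seed in range(5):
            x, _ = _rand_pairs(2, seed=seed)
            outs.extend(small_model.predict_proba(x, x))
        assert np.ptp(outs) < 1e-6

    def test_session_swap_symmetry(self, small_model):
        x1, x2 = _rand_pairs(6, seed=1)
        np.testing.assert_allclose(
            small_model.predict_proba(x1, x2),
            small_model.predict_proba(x2, x1),
            atol=1e-6,
        )

    def test_softmax_head_is_a_distribution(self, small_model):
        x1, x2 = _rand_pairs(3, seed=2)
        z, _ = small_model.forward_logits(x1, x2)
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        assert z.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        probs = small_model.predict_proba(x1, x2)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_module_counts_match_config(self):
        cfg = DeepSymNetConfig(
            input_shape=(16, 16, 16),
            modules_before=2,
            modules_after=1,
            inception=InceptionSpec(filters_per_branch=2),
        )
        m = build(cfg)
        assert len(m.branch) == 2 and len(m.post) == 1

    def test_shared_weights_single_storage(self, small_model, tmp_path):
        """Both branch passes reference the same arrays; the archive holds one copy."""
        w = small_model.branch[0].convs[1].W
        x1, x2 = _rand_pairs(1, seed=3)
        base1 = small_model.predict_proba(x1, x2)[0]
        w += 0.05  # in-place: must affect BOTH branch passes
        pert_swap = small_model.predict_proba(x2, x1)[0]
        pert = small_model.predict_proba(x1, x2)[0]
        assert pert != pytest.approx(base1, abs=1e-9)  # perturbation took effect
        assert pert == pytest.approx(pert_swap, abs=1e-6)  # still symmetric
        path = tmp_path / "model.zip"
        small_model.save(path)
        import io, zipfile

        with zipfile.ZipFile(path) as zf:
            names = np.load(io.BytesIO(zf.read("weights.npz"))).files
        branch_names = [n for n in names if n.startswith("branch.")]
        assert len(branch_names) == len(set(branch_names))
        assert len(branch_names) == 6  # 3 kernels x (W, b) for one shared module

    def test_too_small_input_raises(self):
        with pytest.raises(ConfigurationError):
            DeepSymNetConfig(input_shape=(2, 16, 16))
        with pytest.raises(ConfigurationError):
            DeepSymNetConfig(input_shape=(16, 16, 16), modules_before=4)

    def test_shape_mismatch_raises(self, small_model):
        x1, _ = _rand_pairs(1)
        with pytest.raises(InputError):
            small_model.predict_proba(x1, np.zeros((1, 8, 8, 8), np.float32))

    def test_save_load_roundtrip(self, small_model, tmp_path):
        x1, x2 = _rand_pairs(3, seed=4)
        path = tmp_path / "model.zip"
        small_model.save(path)
        loaded = DeepSymNetModel.load(path)
        np.testing.assert_allclose(
            loaded.predict_proba(x1, x2), small_model.predict_proba(x1, x2), atol=1e-7
        )


def test_backprop_matches_numerical_gradient(tiny_model):
    """Finite differences validate the conv/pool/merge/dense backward pass."""
    rng = np.random.default_rng(0)
    x1 = rng.random((2, 4, 4, 4), dtype=np.float32)
    x2 = rng.random((2, 4, 4, 4), dtype=np.float32)
    y = np.array([0, 1])

    def loss_value():
        z, _ = tiny_model.forward_logits(x1, x2)
        z = z.astype(np.float64)
        p = np.exp(z - z.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        return float(-np.mean(np.log(p[np.arange(2), y])))

    tiny_model.zero_grads()
    z, cache = tiny_model.forward_logits(x1, x2)
    zf = z.astype(np.float64)
    p = np.exp(zf - zf.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    onehot = np.zeros_like(p)
    onehot[np.arange(2), y] = 1
    tiny_model.backward(((p - onehot) / 2).astype(np.float32), cache)
    grads = tiny_model.named_grads()
    params = tiny_model.named_params()
    eps = 1e-3
    checked = 0
    for name in ("branch.0.conv3.W", "post.0.conv5.W", "head.W", "post.0.conv1.b"):
        arr = params[name]
        flat_idx = rng.choice(arr.size, size=min(3, arr.size), replace=False)
        for fi in flat_idx:
            orig = arr.flat[fi]
            arr.flat[fi] = orig + eps
            up = loss_value()
            arr.flat[fi] = orig - eps
            down = loss_value()
            arr.flat[fi] = orig
            numeric = (up - down) / (2 * eps)
            analytic = grads[name].flat[fi]
            assert analytic == pytest.approx(numeric, abs=5e-3), name
            checked += 1
    assert checked >= 10


class TestTraining:
    @staticmethod
    def _toy_dataset(n_per_class=6, noise=0.0):
        cfg = PhantomConfig(
            noise_sd=noise,
            misalign_max=(0.0, 0.0),
            class_atrophy_fraction={"progressor": 0.4, "non-progressor": 0.0},
        )
        _, recs = generate_cohort(
            cfg, {"progressor": n_per_class, "non-progressor": n_per_class}
        )
        return records_to_dataset(recs)

    def test_zero_learning_rate_stops_after_patience(self, small_model):
        ds = self._toy_dataset(3)
        tc = TrainConfig(learning_rate=0.0, max_epochs=20, early_stop_patience=3, seed=0)
        train(small_model, ds, np.array([0, 1, 3, 4]), np.array([2, 5]), tc)
        # constant validation loss: epoch 1 is best, then `patience` flat epochs
        assert len(small_model.training_history) == 4
        losses = [h["val_loss"] for h in small_model.training_history]
        assert np.ptp(losses) < 1e-12

    def test_training_reduces_loss_on_separable_cohort(self, small_model):
        ds = self._toy_dataset(5)
        tc = TrainConfig(learning_rate=1e-3, max_epochs=6, early_stop_patience=5, seed=0)
        train(small_model, ds, np.arange(1, 9), np.array([0, 9]), tc)
        h = small_model.training_history
        assert h[-1]["train_loss"] < h[0]["train_loss"]

    def test_fixed_seed_reproduces_history(self):
        ds = self._toy_dataset(3)
        histories = []
        for _ in range(2):
            cfg = DeepSymNetConfig(
                input_shape=(16, 16, 16), inception=InceptionSpec(filters_per_branch=2)
            )
            m = build(cfg, seed=5)
            tc = TrainConfig(learning_rate=1e-3, max_epochs=3, early_stop_patience=2, seed=9)
            train(m, ds, np.array([0, 1, 3, 4]), np.array([2, 5]), tc)
            histories.append(m.training_history)
        assert histories[0] == histories[1]

    def test_single_class_training_set_raises(self, small_model):
        ds = self._toy_dataset(3)
        with pytest.raises(TrainingError):
            train(small_model, ds, np.array([0, 1]), np.array([2, 5]), TrainConfig())

    def test_overlapping_splits_raise(self, small_model):
        ds = self._toy_dataset(3)
        with pytest.raises(TrainingError):
            train(small_model, ds, np.array([0, 3]), np.array([0, 3]), TrainConfig())

    def test_patience_must_be_smaller_than_epochs(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(max_epochs=10, early_stop_patience=10)


def test_translation_insensitivity_soft(small_model):
    """Shifting both sessions together moves the output less than shifting one."""
    rng = np.random.default_rng(42)
    both, single = [], []
    for _ in range(20):
        x1 = rng.random((16, 16, 16), dtype=np.float32)
        x2 = np.clip(x1 + 0.2 * rng.random((16, 16, 16), dtype=np.float32), 0, 1)
        p0 = small_model.predict_proba(x1[None], x2[None])[0]
        s1 = np.roll(x1, 1, axis=0)
        s2 = np.roll(x2, 1, axis=0)
        both.append(abs(small_model.predict_proba(s1[None], s2[None])[0] - p0))
        single.append(abs(small_model.predict_proba(s1[None], x2[None])[0] - p0))
    assert np.mean(both) < np.mean(single)
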