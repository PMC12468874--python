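import numpy as np
import pytest

from heartpcg.nn.layers import softmax_cross_entropy
from heartpcg.ramm import (
    RAMMConfig,
    RAMMModel,
    TrainConfig,
    build_model,
    extract_features,
    train_model,
)

from conftest import tiny_model_config


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(tiny_model_config(), seed=3)


def _images(n, size=40, seed=0):
    return np.random.default_rng(seed).normal(size=(n, size, size))


class TestBuild:
    def test_feature_layer_width(self):
        model = build_model(tiny_model_config(feature_dim=1000), seed=0)
        assert model.fc_feat.w.value.shape[1] == 1000

    def test_default_param_count_band(self):
        assert 500_000 <= build_model(RAMMConfig()).param_count() <= 660_000

    def test_patch_size_mismatch_fatal(self):
        with pytest.raises(ValueError, match="divisible"):
            RAMMConfig(input_size=200, mixer_patch=23)

    def test_softmax_rows_normalized(self, tiny_model):
        _, probs = tiny_model.forward(_images(4))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)


class TestForward:
    def test_zero_image_finite(self, tiny_model):
        feats, probs = tiny_model.forward(np.zeros((1, 40, 40)))
        assert np.all(np.isfinite(feats)) and np.all(np.isfinite(probs))
        np.testing.assert_allclose(probs.sum(), 1.0, atol=1e-6)

    def test_eval_deterministic(self, tiny_model):
        x = _images(3)
        f1, p1 = tiny_model.forward(x)
        f2, p2 = tiny_model.forward(x)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(p1, p2)

    def test_batch_permutation_equivariance(self, tiny_model):
        """Oracle: per-sample forward calls equal the batched rows."""
        x = _images(5, seed=4)
        perm = np.array([3, 0, 4, 1, 2])
        f, p = tiny_model.forward(x)
        fp, pp = tiny_model.forward(x[perm])
        np.testing.assert_allclose(fp, f[perm], atol=1e-10)
        singles = np.vstack([tiny_model.forward(x[i : i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(f, singles, atol=1e-10)

    def test_shape_mismatch_fatal(self, tiny_model):
        with pytest.raises(ValueError, match="expected 40x40"):
            tiny_model.forward(_images(2, size=20))

    def test_features_nonnegative(self, tiny_model):
        feats, _ = tiny_model.forward(_images(4, seed=9))
        assert feats.min() >= 0.0


class TestStructuralProperties:
    def test_gradients_match_finite_differences(self):
        """Backprop gradient agrees with central differences on a sampled
        weight subset of a tiny network."""
        cfg = tiny_model_config(input_size=20, mixer_patch=20, feature_dim=12)
        model = RAMMModel(cfg, seed=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 20, 20))
        y = np.array([0, 1, 0])

        def loss():
            logits, _ = model._forward_logits(x, train=True)
            return softmax_cross_entropy(logits, y)[0]

        for p in model.params():
            p.grad[...] = 0.0
        model.loss_and_grad(x, y)
        params = model.params()
        checked = 0
        for _ in range(40):
            p = params[rng.integers(len(params))]
            idx = tuple(rng.integers(s) for s in p.value.shape)
            eps = 1e-6
            orig = p.value[idx]
            p.value[idx] = orig + eps
            lp = loss()
            p.value[idx] = orig - eps
            lm = loss()
            p.value[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad[idx]
            if max(abs(num), abs(ana)) < 1e-8:
                continue
            assert abs(num - ana) / max(abs(num), abs(ana)) < 1e-3
            checked += 1
        assert checked >= 10

    def test_attention_weights_bounded_and_zero_channel_kills_output(self, tiny_model):
        se = tiny_model.se
        x = np.abs(np.random.default_rng(5).normal(size=(2, 8, 10, 10)))
        weights = se.channel_weights(x)
        assert np.all(weights > 0) and np.all(weights < 1)
        x[:, 3] = 0.0
        out = se.forward(x)
        assert np.abs(out[:, 3]).max() == 0.0

    def test_residual_branch_reduces_to_identity_with_zero_convs(self):
        from heartpcg.ramm import _ResidualBlock

        block = _ResidualBlock(4, np.random.default_rng(0))
        for p in block.params():
            p.value[...] = 0.0
        x = np.abs(np.random.default_rng(1).normal(size=(2, 4, 8, 8)))
        np.testing.assert_array_equal(block.forward(x), x)


class TestTraining:
    def _separable(self, n=40, size=40, seed=0):
        """Half the images carry a bright band -> linearly separable, so a
        raw-pixel linear classifier (the oracle) scores >= 0.9; the deep
        model must not do worse."""
        rng = np.random.default_rng(seed)
        x = 0.1 * rng.normal(size=(n, size, size))
        y = np.array([0, 1] * (n // 2))
        x[y == 1, 10:20, :] += 1.0
        return np.clip(x, 0, None), y

    def test_learns_separable_images(self):
        x, y = self._separable()
        from sklearn.linear_model import LogisticRegression

        oracle = LogisticRegression(max_iter=200).fit(x.reshape(len(x), -1), y)
        assert oracle.score(x.reshape(len(x), -1), y) >= 0.9
        model = build_model(tiny_model_config(), seed=0)
        tcfg = TrainConfig(epochs=10, batch_size=8, learning_rate=0.01, val_fraction=0.0, seed=0)
        history = train_model(model, x, y, tcfg)
        assert history[-1]["train_acc"] >= 0.9

    def test_zero_learning_rate_is_inert(self):
        x, y = self._separable(n=16)
        model = build_model(tiny_model_config(), seed=1)
        before = [p.value.copy() for p in model.params()]
        train_model(model, x, y, TrainConfig(epochs=2, batch_size=8, learning_rate=0.0, val_fraction=0.0))
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_seeded_training_reproducible(self):
        x, y = self._separable(n=16)
        histories = []
        for _ in range(2):
            model = build_model(tiny_model_config(), seed=2)
            histories.append(
                train_model(model, x, y, TrainConfig(epochs=3, batch_size=8, seed=9, val_fraction=0.25))
            )
        assert histories[0] == histories[1]

    def test_single_class_fatal(self):
        x = _images(8)
        with pytest.raises(ValueError, match="two classes"):
            train_model(build_model(tiny_model_config()), x, np.zeros(8, dtype=int),
                        TrainConfig(epochs=1))


class TestFeatures:
    def test_extract_shape_and_alignment(self, tiny_model):
        x = _images(5, seed=7)
        ids = [f"r{i}" for i in range(5)]
        labels = ["healthy", "unhealthy"] * 2 + ["healthy"]
        fm = extract_features(tiny_model, x, ids, labels)
        assert fm.values.shape == (5, 50)
        assert fm.values.min() >= 0
        assert fm.ids == ids and fm.labels == labels

    def test_duplicated_inputs_identical_rows(self, tiny_model):
        x = _images(2, seed=8)
        xx = np.concatenate([x, x])
        fm = extract_features(tiny_model, xx, list("abcd"), ["healthy"] * 4)
        np.testing.assert_array_equal(fm.values[:2], fm.values[2:])

    def test_untrained_model_warns(self, caplog):
        model = build_model(tiny_model_config(), seed=4)
        with caplog.at_level("WARNING"):
            fm = extract_features(model, _images(2), ["a", "b"], ["healthy", "unhealthy"])
        assert fm.values.shape[0] == 2
        assert any("untrained" in r.message for r in caplog.records)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(tiny_model_config(), seed=6)
        x = _images(2, seed=6)
        f1, p1 = model.forward(x)
        model.save(tmp_path / "ckpt.npz")
        loaded = RAMMModel.load(tmp_path / "ckpt.npz")
        f2, p2 = loaded.forward(x)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(p1, p2)
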