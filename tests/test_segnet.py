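import numpy as np
import pytest

from cardiot1 import _nn
from cardiot1.segnet import (NetworkConfig, TrainingPair, normalize_intensity,
                             augment, build_network, UNetSegmenter,
                             ModelWeights, PAPER_SCALE)
from conftest import make_phantom_training_set


class TestNormalizeIntensity:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 50, (32, 32))
        out = normalize_intensity(img)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6

    def test_idempotent_and_affine_invariant(self):
        rng = np.random.default_rng(1)
        x = normalize_intensity(rng.normal(size=(16, 16)))
        np.testing.assert_allclose(normalize_intensity(x), x, atol=1e-9)
        np.testing.assert_allclose(normalize_intensity(2 * x + 5), x, atol=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.full((8, 8), 3.0))


class TestNetworkConfig:
    def test_input_size_divisibility_enforced(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100, depth=3)

    def test_paper_scale_parameter_count_near_9_million(self):
        n = PAPER_SCALE.parameter_count()
        assert abs(n - 9e6) / 9e6 < 0.2


class TestBuildNetwork:
    def test_two_channel_softmax_output(self):
        cfg = NetworkConfig(input_size=64, depth=3, base_kernels=8, seed=0)
        net = build_network(cfg)
        x = np.random.default_rng(0).normal(size=(1, 1, 64, 64)).astype(np.float32)
        logits = net.forward(x, training=False)
        assert logits.shape == (1, 2, 64, 64)
        probs = _nn.softmax_channels(logits)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_inference_deterministic(self):
        cfg = NetworkConfig(input_size=32, depth=2, base_kernels=4, seed=1)
        net = build_network(cfg)
        x = np.random.default_rng(2).normal(size=(1, 1, 32, 32)).astype(np.float32)
        a = net.forward(x, training=False)
        b = net.forward(x, training=False)
        np.testing.assert_array_equal(a, b)

    def test_gradients_match_finite_differences(self):
        cfg = NetworkConfig(input_size=8, depth=2, base_kernels=2,
                            dropout_p=0.0, seed=0)
        net = build_network(cfg)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        y = (rng.random((2, 8, 8)) < 0.3).astype(np.int64)

        def loss():
            return _nn.cross_entropy_loss(net.forward(x, training=True), y)

        _, d = loss()
        net.backward(d)
        analytic = [g.copy() for g in net.grads]
        prng = np.random.default_rng(3)
        eps = 1e-3
        agree = total = 0
        for pi in prng.choice(len(net.params), size=10, replace=False):
            p = net.params[pi]
            idx = tuple(prng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = loss()
            p[idx] = orig - eps
            lm, _ = loss()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = analytic[pi][idx]
            total += 1
            if abs(num - ana) < 1e-3 or \
                    abs(num - ana) / (abs(num) + abs(ana) + 1e-9) < 0.1:
                agree += 1
        assert agree >= total - 1   # float32 finite differences are coarse


class TestAugment:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        img = rng.normal(size=(32, 32))
        lab = np.zeros((32, 32), dtype=bool)
        lab[10:20, 12:22] = True
        return TrainingPair(image=img, label=lab)

    def test_all_off_is_identity(self):
        pair = self._pair()
        out = augment(pair, np.random.default_rng(0),
                      p_translate=0.0, p_mirror=0.0, p_elastic=0.0)
        np.testing.assert_array_equal(out.image, pair.image)
        np.testing.assert_array_equal(out.label, pair.label)

    def test_mirror_only_flips_both(self):
        pair = self._pair()
        out = augment(pair, np.random.default_rng(0),
                      p_translate=0.0, p_mirror=1.0, p_elastic=0.0)
        np.testing.assert_array_equal(out.image, pair.image[:, ::-1])
        np.testing.assert_array_equal(out.label, pair.label[:, ::-1])
        assert out.label.dtype == bool

    def test_label_stays_binary_under_elastic(self):
        pair = self._pair()
        out = augment(pair, np.random.default_rng(5),
                      p_translate=0.0, p_mirror=0.0, p_elastic=1.0)
        assert set(np.unique(out.label)) <= {False, True}

    def test_translation_probability_binomial(self):
        # count translations over many draws: p = 0.95
        pair = self._pair()
        rng = np.random.default_rng(7)
        n = 2000
        moved = 0
        for _ in range(n):
            out = augment(pair, rng, p_mirror=0.0, p_elastic=0.0)
            if not np.array_equal(out.label, pair.label):
                moved += 1
        # identity shift (dy=dx=0) occurs w.p. ~1/49 among translations
        p_eff = 0.95 * (1 - 1 / 49)
        sd = np.sqrt(n * p_eff * (1 - p_eff))
        assert abs(moved - n * p_eff) < 4 * sd


class TestTrainingAndInference:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, Y = make_phantom_training_set(12, 30)
        est = UNetSegmenter(input_size=64, depth=3, base_kernels=8,
                            dropout_p=0.0, iterations=50, batch_size=6,
                            seed=0, augment_data=False)
        return est.fit(X, Y), X, Y

    def test_loss_decreases(self, fitted):
        est, _, _ = fitted
        first = est.loss_history_[:5].mean()
        last = est.loss_history_[-5:].mean()
        assert last < first

    def test_seeded_training_deterministic(self):
        X, Y = make_phantom_training_set(6, 60)
        kw = dict(input_size=64, depth=3, base_kernels=4, iterations=10,
                  batch_size=4, seed=3)
        a = UNetSegmenter(**kw).fit(X, Y)
        b = UNetSegmenter(**kw).fit(X, Y)
        assert a.loss_history_[-1] == b.loss_history_[-1]

    def test_predict_binary_same_grid(self, fitted):
        est, X, _ = fitted
        mask = est.predict(X[0])
        assert mask.shape == X[0].shape
        assert mask.dtype == bool

    def test_weights_round_trip_identical_predictions(self, fitted, tmp_path):
        est, X, _ = fitted
        path = tmp_path / "w.npz"
        est.weights_.save(path)
        loaded = ModelWeights.load(path)
        est2 = UNetSegmenter().load_weights(loaded)
        np.testing.assert_array_equal(est.predict(X[0]), est2.predict(X[0]))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            UNetSegmenter().fit(np.empty((0, 64, 64)), np.empty((0, 64, 64)))

    def test_tie_probability_resolves_to_background(self):
        # constant-zero logits give exactly p = 0.5 per channel
        probs = _nn.softmax_channels(np.zeros((1, 2, 4, 4), dtype=np.float32))
        np.testing.assert_allclose(probs[0, 1], 0.5)
        assert not (probs[0, 1] > 0.5).any()
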