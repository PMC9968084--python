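"""Segmenter contracts, gradient correctness, training, and post-processing."""

import numpy as np
import pytest
from scipy import ndimage

from octfundus.core import FundusImage, ProbabilityMap, ValidationError
from octfundus.preprocessing import AugmentConfig, PatchSet
from octfundus.segmentation import (
    ModelConfig, TrainingError, _loss_and_grad, baseline_shadowgraph, binarize,
    build_model, dti_refine, load_checkpoint, predict_image, save_checkpoint,
    train,
)


def toy_patchset(n=64, size=16, seed=0):
    """Bright background with dark bars: a linearly separable mini task."""
    rng = np.random.default_rng(seed)
    imgs = np.empty((n, size, size), dtype=np.float32)
    msks = np.zeros((n, size, size), dtype=np.uint8)
    for i in range(n):
        img = 0.7 + 0.05 * rng.standard_normal((size, size))
        col = rng.integers(2, size - 2)
        img[:, col - 1:col + 1] = 0.2
        msks[i, :, col - 1:col + 1] = 1
        imgs[i] = np.clip(img, 0, 1)
    coords = np.zeros((n, 2), dtype=int)
    return PatchSet(imgs, msks, coords, size, seed)


class TestModelContracts:
    def test_output_shape_and_range(self):
        m = build_model(ModelConfig(depth=2, base_filters=4))
        x = np.random.default_rng(0).random((3, 1, 16, 16)).astype(np.float32)
        p = m.forward(x)["prob"]
        assert p.shape == (3, 16, 16)
        assert p.min() >= 0 and p.max() <= 1

    def test_two_channel_probabilities_sum_to_one(self):
        m = build_model(ModelConfig(depth=2, base_filters=4, out_channels=2, loss="cce"))
        x = np.random.default_rng(0).random((2, 1, 16, 16)).astype(np.float32)
        probs2 = m.forward(x)["probs2"]
        np.testing.assert_allclose(probs2.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_parameters(self):
        a = build_model(ModelConfig(depth=2, base_filters=4, seed=5))
        b = build_model(ModelConfig(depth=2, base_filters=4, seed=5))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_indivisible_patch_size_rejected(self):
        m = build_model(ModelConfig(depth=3, base_filters=4))
        x = np.zeros((1, 1, 20, 20), dtype=np.float32)
        with pytest.raises(ValidationError, match="divisible"):
            m.forward(x)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            ModelConfig(depth=1)
        with pytest.raises(ValidationError):
            ModelConfig(epochs=0)
        with pytest.raises(ValidationError):
            ModelConfig(loss="cce", out_channels=1)
        with pytest.raises(ValidationError):
            ModelConfig(refine_iters=2, out_channels=2, loss="cce")

    def test_checkpoint_round_trip(self, tmp_path):
        m = build_model(ModelConfig(depth=2, base_filters=4, seed=3))
        save_checkpoint(m, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        x = np.random.default_rng(1).random((1, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(back.forward(x)["prob"], m.forward(x)["prob"])


@pytest.mark.parametrize("kind", ["bce", "cce", "refine"])
def test_analytic_gradients_match_finite_differences(kind):
    """Backprop agrees with central finite differences on a tiny float64 net."""
    if kind == "cce":
        cfg = ModelConfig(depth=2, base_filters=4, loss="cce", out_channels=2, seed=0)
        loss = "cce"
    elif kind == "refine":
        cfg = ModelConfig(depth=2, base_filters=4, loss="bce", refine_iters=2, seed=0)
        loss = "bce"
    else:
        cfg = ModelConfig(depth=2, base_filters=4, loss="bce", seed=0)
        loss = "bce"
    m = build_model(cfg)
    for p in m.params():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    rng = np.random.default_rng(0)
    x = rng.random((2, 1, 8, 8))
    t = (rng.random((2, 8, 8)) > 0.7).astype(np.uint8)
    fwd = m.forward(x, train=True)
    _, dl = _loss_and_grad(fwd, t, loss)
    m.backward_from_prob_grad(fwd, dl.astype(np.float64))

    def loss_value():
        return _loss_and_grad(m.forward(x, train=False), t, loss)[0]

    rs = np.random.default_rng(1)
    params = m.params()
    for pi in [0, len(params) // 2, len(params) - 2, len(params) - 1]:
        p = params[pi]
        flat = p.value.reshape(-1)
        for _ in range(2):
            i = rs.integers(flat.size)
            eps, old = 1e-5, flat[i]
            flat[i] = old + eps
            lp = loss_value()
            flat[i] = old - eps
            lm = loss_value()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = p.grad.reshape(-1)[i]
            assert abs(num - ana) <= 1e-3 * (abs(num) + abs(ana)) + 1e-9


class TestTraining:
    def test_loss_decreases_on_toy_task(self):
        cfg = ModelConfig(depth=2, base_filters=4, epochs=5, batch_size=16,
                          optimizer="adam", lr=1e-3, val_split=0.2, seed=0)
        model, hist = train(build_model(cfg), toy_patchset(), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == cfg.epochs
        assert all(0 <= a <= 1 for a in hist.train_accuracy)

    def test_training_is_bitwise_reproducible(self):
        cfg = ModelConfig(depth=2, base_filters=4, epochs=2, batch_size=16, seed=4)
        _, h1 = train(build_model(cfg), toy_patchset(), cfg)
        _, h2 = train(build_model(cfg), toy_patchset(), cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy

    def test_empty_patchset_rejected(self):
        cfg = ModelConfig(depth=2, base_filters=4, epochs=1)
        empty = PatchSet(np.zeros((0, 16, 16), np.float32),
                         np.zeros((0, 16, 16), np.uint8),
                         np.zeros((0, 2), int), 16, 0)
        with pytest.raises(ValidationError, match="empty"):
            train(build_model(cfg), empty, cfg)

    def test_divergence_reported_with_epoch(self):
        cfg = ModelConfig(depth=2, base_filters=4, epochs=2, batch_size=16, seed=0)
        model = build_model(cfg)
        model.params()[0].value[...] = np.nan  # poisoned weights diverge at once
        with pytest.raises(TrainingError, match="epoch 0"):
            train(model, toy_patchset(), cfg)


class TestPredictImage:
    def test_full_image_patch_equals_single_shot(self):
        m = build_model(ModelConfig(depth=2, base_filters=4, seed=1))
        rng = np.random.default_rng(2)
        img = FundusImage(rng.random((16, 16)), (0.1, 0.1))
        full = predict_image(m, img, patch_size=16, stride=16)
        single = m.predict_patches(img.pixels[None])[0]
        np.testing.assert_allclose(full.pixels, single, atol=1e-9)

    def test_sliding_window_covers_whole_image(self):
        m = build_model(ModelConfig(depth=2, base_filters=4, seed=1))
        rng = np.random.default_rng(2)
        img = FundusImage(rng.random((30, 22)), (0.1, 0.1))
        prob = predict_image(m, img, patch_size=16, stride=8)
        assert prob.shape == (30, 22)


class TestBinarize:
    def test_extreme_thresholds(self):
        p = ProbabilityMap(np.array([[0.0, 0.4], [0.8, 1.0]]))
        assert binarize(p, 0.0).pixels.all()
        np.testing.assert_array_equal(binarize(p, 1.0).pixels,
                                      [[0, 0], [0, 1]])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        p = ProbabilityMap(rng.random((20, 20)))
        prev = binarize(p, 0.1).pixels
        for thr in (0.3, 0.5, 0.7, 0.9):
            cur = binarize(p, thr).pixels
            assert (cur <= prev).all()  # higher threshold => subset
            prev = cur


class TestDTI:
    def test_seed_grows_through_low_chain(self):
        p = np.zeros((5, 8))
        p[2, 1] = 0.9
        p[2, 2:6] = 0.4
        mask = dti_refine(ProbabilityMap(p), high=0.8, low=0.3)
        assert mask.pixels[2, 1:6].all()
        assert mask.pixels.sum() == 5

    def test_isolated_low_blob_excluded(self):
        p = np.zeros((5, 5))
        p[1:3, 1:3] = 0.4
        mask = dti_refine(ProbabilityMap(p), high=0.8, low=0.3)
        assert mask.pixels.sum() == 0

    def test_invalid_thresholds_rejected(self):
        p = ProbabilityMap(np.zeros((3, 3)))
        with pytest.raises(ValidationError):
            dti_refine(p, high=0.3, low=0.3)

    def test_nesting_and_component_oracle(self):
        """DTI equals keeping low-mask components that contain a high pixel."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = ndimage.gaussian_filter(rng.random((24, 24)), 1.0)
            p = (p - p.min()) / (p.max() - p.min())
            out = dti_refine(ProbabilityMap(p), high=0.7, low=0.45).pixels.astype(bool)
            high, low = p >= 0.7, p >= 0.45
            assert (high <= out).all() and (out <= low).all()
            labels, n = ndimage.label(low, structure=np.ones((3, 3)))
            keep = np.zeros_like(low)
            for lab in range(1, n + 1):
                comp = labels == lab
                if (comp & high).any():
                    keep |= comp
            np.testing.assert_array_equal(out, keep)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(7)
        p = ndimage.gaussian_filter(rng.random((20, 20)), 1.0)
        p = (p - p.min()) / (p.max() - p.min())
        once = dti_refine(ProbabilityMap(p), high=0.7, low=0.4).pixels
        again = dti_refine(ProbabilityMap(once.astype(float)), high=0.7, low=0.4).pixels
        np.testing.assert_array_equal(once, again)


class TestShadowgraphBaseline:
    def test_recovers_vessels_on_noiseless_phantom(self, noiseless_phantom):
        from octfundus.evaluation import confusion, metrics
        from octfundus.reconstruction import ReconstructionConfig, reconstruct
        ph = noiseless_phantom
        p1 = reconstruct(ph.volume, ph.surfaces, ReconstructionConfig("P1"))
        mask = baseline_shadowgraph(p1, sigma=0.5, method="otsu", polarity="dark")
        f1 = metrics(confusion(mask, ph.vessel_mask)).f1
        assert f1 >= 0.9

    def test_constant_image_gives_empty_mask(self):
        img = FundusImage(np.full((16, 16), 0.5), (0.1, 0.1))
        assert baseline_shadowgraph(img).pixels.sum() == 0

    def test_zero_sigma_is_pure_threshold(self):
        rng = np.random.default_rng(1)
        img = FundusImage(rng.random((16, 16)), (0.1, 0.1))
        mask = baseline_shadowgraph(img, sigma=0.0, method="fixed",
                                    threshold=0.5, polarity="dark")
        np.testing.assert_array_equal(mask.pixels, (img.pixels < 0.5).astype(np.uint8))
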