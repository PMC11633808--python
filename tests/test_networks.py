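"""Network architectures: shapes, gradients, ablations, checkpoints."""

import numpy as np
import pytest

from autoconfidence import nn
from autoconfidence.losses import LossParams, focal_loss_from_probs, \
    focal_softmax_grad
from autoconfidence.masks import ImageSlice, OARMaskSet, ShapeError
from autoconfidence.networks import (ConfidenceMap, DiscriminatorSpec,
                                     GeneratorSpec, UNetGenerator,
                                     UResNetDiscriminator, build_discriminator,
                                     build_generator, load_model, save_model)


def _model_fd_check(model, x, target, rng, n_probe=8):
    """End-to-end finite-difference check in float64."""
    params = LossParams()

    def loss():
        return focal_loss_from_probs(model.forward(x, train=False),
                                     target, params)

    probs = model.forward(x, train=False)
    model.zero_grad()
    model.backward(focal_softmax_grad(probs, target, params))
    allp = model.params()
    for _ in range(n_probe):
        p = allp[rng.integers(len(allp))]
        idx = tuple(rng.integers(s) for s in p.value.shape)
        eps = 1e-5
        old = p.value[idx]
        p.value[idx] = old + eps
        lp = loss()
        p.value[idx] = old - eps
        lm = loss()
        p.value[idx] = old
        fd = (lp - lm) / (2 * eps)
        assert p.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


@pytest.fixture
def f64(monkeypatch):
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    yield


class TestGenerator:
    def test_output_shape_and_softmax(self):
        gen = build_generator(GeneratorSpec(out_classes=4, base_filters=4),
                              seed=0)
        x = np.random.default_rng(0).random((2, 32, 32, 1)).astype(np.float32)
        probs = gen.forward(x)
        assert probs.shape == (2, 32, 32, 4)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_eval_deterministic(self):
        gen = build_generator(GeneratorSpec(base_filters=4), seed=1)
        x = np.random.default_rng(1).random((1, 32, 32, 1)).astype(np.float32)
        np.testing.assert_array_equal(gen.forward(x, train=False),
                                      gen.forward(x, train=False))

    def test_end_to_end_gradients(self, f64):
        rng = np.random.default_rng(2)
        gen = UNetGenerator(GeneratorSpec(out_classes=3, base_filters=4,
                                          dropout_rate=0.0), seed=2)
        x = rng.random((2, 16, 16, 1))
        t = rng.integers(0, 3, size=(2, 16, 16))
        _model_fd_check(gen, x, t, rng)

    def test_spec_enforces_eight_layers(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_conv_layers=6)

    def test_odd_size_rejected(self):
        gen = build_generator(GeneratorSpec(base_filters=4), seed=0)
        with pytest.raises(ShapeError):
            gen.forward(np.zeros((1, 33, 32, 1), dtype=np.float32))

    def test_predict_returns_softmax_seg(self):
        gen = build_generator(GeneratorSpec(out_classes=4, base_filters=4),
                              seed=3)
        img = ImageSlice(np.random.default_rng(3).random((32, 32))
                         .astype(np.float32))
        seg = gen.predict(img)
        assert seg.probs.shape == (4, 32, 32)


class TestDiscriminator:
    def test_output_shape_two_class(self):
        disc = build_discriminator(DiscriminatorSpec(in_channels=4,
                                                     base_filters=4), seed=0)
        x = np.random.default_rng(0).random((2, 32, 32, 4)).astype(np.float32)
        probs = disc.forward(x)
        assert probs.shape == (2, 32, 32, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_end_to_end_gradients(self, f64):
        rng = np.random.default_rng(4)
        disc = UResNetDiscriminator(DiscriminatorSpec(in_channels=3,
                                                      base_filters=4), seed=4)
        x = rng.random((2, 16, 16, 3))
        t = rng.integers(0, 2, size=(2, 16, 16))
        _model_fd_check(disc, x, t, rng)

    def test_wrong_channel_count_rejected(self):
        disc = build_discriminator(DiscriminatorSpec(in_channels=4,
                                                     base_filters=4), seed=0)
        with pytest.raises(ShapeError):
            disc.forward(np.zeros((1, 32, 32, 3), dtype=np.float32))

    def test_ablate_image_ignores_image_channel(self):
        disc = build_discriminator(DiscriminatorSpec(in_channels=3,
                                                     base_filters=4), seed=5)
        disc.ablate = "image"
        rng = np.random.default_rng(5)
        x1 = rng.random((1, 32, 32, 3)).astype(np.float32)
        x2 = x1.copy()
        x2[..., -1] = rng.random((1, 32, 32))
        np.testing.assert_array_equal(disc.forward(x1), disc.forward(x2))

    def test_ablate_masks_ignores_mask_channels(self):
        disc = build_discriminator(DiscriminatorSpec(in_channels=3,
                                                     base_filters=4), seed=6)
        disc.ablate = "masks"
        rng = np.random.default_rng(6)
        x1 = rng.random((1, 32, 32, 3)).astype(np.float32)
        x2 = x1.copy()
        x2[..., :-1] = rng.random((1, 32, 32, 2))
        np.testing.assert_array_equal(disc.forward(x1), disc.forward(x2))

    def test_stack_input_image_last(self):
        disc = build_discriminator(DiscriminatorSpec(in_channels=3,
                                                     base_filters=4), seed=0)
        masks = OARMaskSet(np.zeros((2, 32, 32), dtype=np.uint8))
        img = ImageSlice(np.full((32, 32), 0.5, dtype=np.float32))
        x = disc.stack_input(masks, img)
        assert x.shape == (1, 32, 32, 3)
        np.testing.assert_array_equal(x[0, :, :, -1], img.values)

    def test_predict_returns_confidence_map(self):
        disc = build_discriminator(DiscriminatorSpec(in_channels=3,
                                                     base_filters=4), seed=7)
        masks = OARMaskSet(np.zeros((2, 32, 32), dtype=np.uint8))
        img = ImageSlice(np.zeros((32, 32), dtype=np.float32))
        conf = disc.predict(masks, img)
        assert isinstance(conf, ConfidenceMap)
        assert conf.shape == (32, 32)


class TestConfidenceMap:
    def test_binarize(self):
        cm = ConfidenceMap(np.array([[0.2, 0.8], [0.5, 0.49]]))
        np.testing.assert_array_equal(cm.binarize(0.5),
                                      [[0, 1], [1, 0]])

    def test_range_validation(self):
        with pytest.raises(ValueError):
            ConfidenceMap(np.array([[1.5]]))


class TestCheckpoints:
    def test_generator_roundtrip(self, tmp_path):
        gen = build_generator(GeneratorSpec(out_classes=4, base_filters=4),
                              seed=8)
        x = np.random.default_rng(8).random((1, 32, 32, 1)).astype(np.float32)
        gen.forward(x, train=True)  # move BN running stats off their init
        want = gen.forward(x, train=False)
        save_model(gen, tmp_path / "gen.npz")
        back = load_model(tmp_path / "gen.npz")
        np.testing.assert_array_equal(back.forward(x, train=False), want)

    def test_discriminator_roundtrip_keeps_ablate(self, tmp_path):
        disc = build_discriminator(DiscriminatorSpec(in_channels=4,
                                                     base_filters=4), seed=9)
        disc.ablate = "image"
        save_model(disc, tmp_path / "disc.npz")
        back = load_model(tmp_path / "disc.npz")
        assert isinstance(back, UResNetDiscriminator)
        assert back.ablate == "image"
        x = np.random.default_rng(9).random((1, 32, 32, 4)).astype(np.float32)
        np.testing.assert_array_equal(back.forward(x), disc.forward(x))
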