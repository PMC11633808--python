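"""Synthetic error injection: identities, exact transforms, reproducibility."""

import warnings

import numpy as np
import pytest

from autoconfidence.masks import OARMaskSet, SoftmaxSeg
from autoconfidence.errors import (ErrorInjectionConfig, apply_rigid, apply_tps,
                                   inject, perturb_class, remove_oar)


def _blob_masks(rng, k=3, h=32, w=32):
    ch = np.zeros((k, h, w), dtype=np.uint8)
    for c in range(k):
        cy, cx = rng.integers(6, h - 6), rng.integers(6, w - 6)
        r = rng.integers(2, 5)
        yy, xx = np.mgrid[0:h, 0:w]
        ch[c] = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(np.uint8)
    return OARMaskSet(ch)


class TestRigid:
    def test_identity(self):
        masks = _blob_masks(np.random.default_rng(0))
        out = apply_rigid(masks, rotation=0.0, translation=(0.0, 0.0))
        np.testing.assert_array_equal(out.channels, masks.channels)

    def test_pure_translation_exact(self):
        masks = _blob_masks(np.random.default_rng(1))
        out = apply_rigid(masks, rotation=0.0, translation=(2.0, -3.0))
        want = np.zeros_like(masks.channels)
        want[:, 2:, :-3] = masks.channels[:, :-2, 3:]
        np.testing.assert_array_equal(out.channels, want)

    def test_rotation_180_exact(self):
        masks = _blob_masks(np.random.default_rng(2))
        out = apply_rigid(masks, rotation=180.0)
        want = masks.channels[:, ::-1, ::-1]
        np.testing.assert_array_equal(out.channels, want)

    def test_rotation_inverse_roundtrip(self):
        # rotating +90 then -90 about the centre returns the original
        masks = _blob_masks(np.random.default_rng(3))
        out = apply_rigid(apply_rigid(masks, 90.0), -90.0)
        np.testing.assert_array_equal(out.channels, masks.channels)

    def test_out_of_bounds_becomes_background(self):
        ch = np.ones((1, 8, 8), dtype=np.uint8)
        out = apply_rigid(OARMaskSet(ch), rotation=0.0, translation=(3.0, 0.0))
        assert out.channels[0, :3].sum() == 0
        assert out.channels[0, 3:].all()

    def test_masks_stay_binary(self):
        masks = _blob_masks(np.random.default_rng(4))
        out = apply_rigid(masks, rotation=7.3, translation=(1.2, -0.7))
        assert set(np.unique(out.channels)) <= {0, 1}


class TestTPS:
    def test_sigma_zero_is_identity(self):
        masks = _blob_masks(np.random.default_rng(5))
        out = apply_tps(masks, sigma_mm=0.0, seed=42)
        np.testing.assert_array_equal(out.channels, masks.channels)

    def test_deterministic_per_seed(self):
        masks = _blob_masks(np.random.default_rng(6))
        a = apply_tps(masks, sigma_mm=3.0, seed=9)
        b = apply_tps(masks, sigma_mm=3.0, seed=9)
        c = apply_tps(masks, sigma_mm=3.0, seed=10)
        np.testing.assert_array_equal(a.channels, b.channels)
        assert not np.array_equal(a.channels, c.channels)

    def test_sigma_monotonicity_over_seeds(self):
        """Mean displaced-voxel fraction grows with the deformation sigma.

        Averaged over 200 seeds so the ordering is a property of the
        mechanism, not of one lucky draw.
        """
        masks = _blob_masks(np.random.default_rng(7), k=2, h=48, w=48)
        area = masks.channels.sum()
        sigmas = (1.0, 3.0, 6.0)
        mean_frac = []
        for sigma in sigmas:
            fracs = []
            for seed in range(200):
                out = apply_tps(masks, sigma_mm=sigma, seed=seed)
                changed = np.abs(out.channels.astype(int)
                                 - masks.channels.astype(int)).sum()
                fracs.append(changed / area)
            mean_frac.append(np.mean(fracs))
        assert mean_frac[0] < mean_frac[1] < mean_frac[2]

    def test_masks_stay_binary(self):
        masks = _blob_masks(np.random.default_rng(8))
        out = apply_tps(masks, sigma_mm=4.0, seed=1)
        assert set(np.unique(out.channels)) <= {0, 1}


class TestClassPerturb:
    def _softmax(self):
        # 2 organs; organ 1's voxels have class 2 as runner-up
        probs = np.zeros((3, 6, 6), dtype=np.float32)
        probs[0] = 0.1
        probs[1, :3] = 0.6
        probs[2, :3] = 0.3
        probs[2, 3:] = 0.6
        probs[1, 3:] = 0.3
        probs /= probs.sum(axis=0)
        return SoftmaxSeg(probs)

    def test_relabels_to_second_argmax(self):
        seg = self._softmax()
        out = perturb_class(seg, target_channel=0)
        # organ 0's voxels (rows 0-2) move to class 2 -> channel 1
        assert out.channels[0].sum() == 0
        assert out.channels[1].all()

    def test_other_voxels_unchanged(self):
        seg = self._softmax()
        out = perturb_class(seg, target_channel=0)
        # rows 3-5 were already organ 1 and stay organ 1
        assert out.channels[1, 3:].all()

    def test_empty_target_warns_and_noop(self):
        probs = np.zeros((3, 4, 4), dtype=np.float32)
        probs[0] = 1.0  # all background
        with pytest.warns(RuntimeWarning):
            out = perturb_class(SoftmaxSeg(probs), target_channel=0)
        assert out.channels.sum() == 0

    def test_bad_channel_raises(self):
        with pytest.raises(IndexError):
            perturb_class(self._softmax(), target_channel=5)


class TestRemoval:
    def test_removed_channel_empty_others_bit_identical(self):
        masks = _blob_masks(np.random.default_rng(9))
        out = remove_oar(masks, 1)
        assert out.channels[1].sum() == 0
        np.testing.assert_array_equal(out.channels[0], masks.channels[0])
        np.testing.assert_array_equal(out.channels[2], masks.channels[2])

    def test_input_not_mutated(self):
        masks = _blob_masks(np.random.default_rng(10))
        before = masks.channels.copy()
        remove_oar(masks, 0)
        np.testing.assert_array_equal(masks.channels, before)

    def test_bad_channel_raises(self):
        with pytest.raises(IndexError):
            remove_oar(_blob_masks(np.random.default_rng(0)), 7)


class TestInject:
    def test_zero_probabilities_identity(self):
        masks = _blob_masks(np.random.default_rng(11))
        cfg = ErrorInjectionConfig(p_geometric=0.0, p_class_perturb=0.0,
                                   p_removal=0.0, seed=0)
        out, log = inject(masks, None, cfg)
        np.testing.assert_array_equal(out.channels, masks.channels)
        assert log == []

    def test_magnitude_scale_zero_geometric_identity(self):
        masks = _blob_masks(np.random.default_rng(12))
        cfg = ErrorInjectionConfig(p_geometric=1.0, p_class_perturb=0.0,
                                   p_removal=0.0, magnitude_scale=0.0, seed=3)
        out, log = inject(masks, None, cfg)
        np.testing.assert_array_equal(out.channels, masks.channels)
        assert [e["family"] for e in log] == ["geometric"]

    def test_reproducible_from_seed(self):
        masks = _blob_masks(np.random.default_rng(13))
        cfg = ErrorInjectionConfig(p_geometric=1.0, p_class_perturb=0.0,
                                   p_removal=1.0, seed=21)
        a, la = inject(masks, None, cfg)
        b, lb = inject(masks, None, cfg)
        np.testing.assert_array_equal(a.channels, b.channels)
        assert la == lb

    def test_removal_only_touches_one_channel(self):
        masks = _blob_masks(np.random.default_rng(14))
        cfg = ErrorInjectionConfig(p_geometric=0.0, p_class_perturb=0.0,
                                   p_removal=1.0, seed=5)
        out, log = inject(masks, None, cfg)
        assert len(log) == 1 and log[0]["family"] == "removal"
        removed = log[0]["channel"]
        assert out.channels[removed].sum() == 0
        for c in range(masks.n_channels):
            if c != removed:
                np.testing.assert_array_equal(out.channels[c],
                                              masks.channels[c])

    def test_class_perturb_requires_softmax(self):
        masks = _blob_masks(np.random.default_rng(15))
        cfg = ErrorInjectionConfig(p_class_perturb=0.5)
        with pytest.raises(ValueError):
            inject(masks, None, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ErrorInjectionConfig(p_geometric=1.5)
        with pytest.raises(ValueError):
            ErrorInjectionConfig(tps_sigma=-1)
        with pytest.raises(ValueError):
            ErrorInjectionConfig(magnitude_scale=-0.1)
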