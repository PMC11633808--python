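"""IER and GDC against independent brute-force oracles."""

import numpy as np
import pytest

from autoconfidence.masks import (ConfusionMap, OARMaskSet, TN, TP, FP, FN,
                                  confusion_counts)
from autoconfidence.postprocess import (GDCParams, IERParams,
                                        geometric_distance_correction,
                                        intelligent_edge_removal,
                                        segmentation_edges)
from oracles import (oracle_edges as _oracle_edges,
                     oracle_gdc as _oracle_gdc,
                     oracle_ier as _oracle_ier,
                     oracle_square_dilate as _oracle_square_dilate)

def _random_seg(rng, k=2, h=16, w=16):
    ch = np.zeros((k, h, w), dtype=np.uint8)
    for c in range(k):
        cy, cx = rng.integers(3, h - 3), rng.integers(3, w - 3)
        r = rng.integers(2, 4)
        yy, xx = np.mgrid[0:h, 0:w]
        ch[c] = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(np.uint8)
    return OARMaskSet(ch)


# ---------------------------------------------------------------------------
# IER
# ---------------------------------------------------------------------------

class TestIER:
    def test_edges_match_oracle(self):
        rng = np.random.default_rng(2)
        seg = _random_seg(rng)
        np.testing.assert_array_equal(segmentation_edges(seg),
                                      _oracle_edges(seg))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seg = _random_seg(rng)
        err = (rng.random((16, 16)) < 0.25).astype(np.uint8)
        got = intelligent_edge_removal(err, seg, IERParams(k=3))
        np.testing.assert_array_equal(got, _oracle_ier(err, seg, k=3))

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            seg = _random_seg(rng)
            err = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            out = intelligent_edge_removal(err, seg)
            assert not np.any(out & ~err)

    def test_thin_boundary_error_removed(self):
        # an error band exactly on the organ boundary disappears entirely
        seg = _random_seg(np.random.default_rng(0), k=1)
        err = segmentation_edges(seg).astype(np.uint8)
        out = intelligent_edge_removal(err, seg)
        assert out.sum() == 0

    def test_interior_error_survives(self):
        seg = OARMaskSet(np.zeros((1, 16, 16), dtype=np.uint8))  # no edges
        err = np.zeros((16, 16), dtype=np.uint8)
        err[5:9, 5:9] = 1
        out = intelligent_edge_removal(err, seg)
        np.testing.assert_array_equal(out, err)

    def test_substantial_error_regrows_into_band(self):
        # a large error blob overlapping the boundary band keeps its in-band
        # voxels within radius k/2 of surviving interior voxels
        ch = np.zeros((1, 16, 16), dtype=np.uint8)
        ch[0, 2:8, 2:8] = 1
        seg = OARMaskSet(ch)
        err = np.zeros((16, 16), dtype=np.uint8)
        err[2:14, 6:10] = 1
        out = intelligent_edge_removal(err, seg, IERParams(k=3))
        band = _oracle_square_dilate(_oracle_edges(seg), 3)
        assert np.any(out.astype(bool) & band), "regrown voxels inside the band"
        np.testing.assert_array_equal(out, _oracle_ier(err, seg, k=3))


# ---------------------------------------------------------------------------
# GDC
# ---------------------------------------------------------------------------

class TestGDC:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([TN, TP, FP, FN], size=(14, 14),
                            p=[0.55, 0.2, 0.15, 0.1]).astype(np.uint8)
        cm = ConfusionMap(labels)
        got = geometric_distance_correction(cm, GDCParams(patch_size=7))
        want = _oracle_gdc(cm, patch_size=7)
        np.testing.assert_array_equal(got.labels, want.labels)
        np.testing.assert_array_equal(got.gdc_modified, want.gdc_modified)

    def test_fp_near_large_tp_becomes_tp(self):
        lab = np.full((21, 21), TN, dtype=np.uint8)
        lab[8:13, 8:13] = TP           # 5x5 TP block, inscribed diameter ~6
        lab[10, 14] = FP               # 2 voxels from the block edge
        out = geometric_distance_correction(ConfusionMap(lab))
        assert out.labels[10, 14] == TP
        assert out.gdc_modified[10, 14]

    def test_fn_near_large_tp_becomes_tn(self):
        lab = np.full((21, 21), TN, dtype=np.uint8)
        lab[8:13, 8:13] = TP
        lab[14, 10] = FN
        out = geometric_distance_correction(ConfusionMap(lab))
        assert out.labels[14, 10] == TN

    def test_isolated_fp_unchanged(self):
        lab = np.full((21, 21), TN, dtype=np.uint8)
        lab[10, 10] = FP               # no TP anywhere
        out = geometric_distance_correction(ConfusionMap(lab))
        assert out.labels[10, 10] == FP
        assert not out.gdc_modified.any()

    def test_far_fp_unchanged(self):
        lab = np.full((41, 41), TN, dtype=np.uint8)
        lab[19:22, 19:22] = TP         # 3x3 TP, inscribed diameter ~2.x
        lab[20, 30] = FP               # 9 voxels away: outside the diameter
        out = geometric_distance_correction(ConfusionMap(lab))
        assert out.labels[20, 30] == FP

    def test_no_cascading(self):
        # decisions use the original labels: an FP turned TP must not make a
        # farther FP eligible. Construct a chain of FPs next to a small TP.
        lab = np.full((31, 31), TN, dtype=np.uint8)
        lab[14:17, 14:17] = TP         # inscribed diameter 2*sqrt(2)... > 2
        lab[15, 17] = FP               # distance 1 -> flips
        lab[15, 19] = FP               # distance 3 from TP; only 2 from the
        out = geometric_distance_correction(ConfusionMap(lab))  # flipped FP
        want = _oracle_gdc(ConfusionMap(lab))
        np.testing.assert_array_equal(out.labels, want.labels)
        assert out.labels[15, 17] == TP

    def test_tp_tn_never_change(self):
        rng = np.random.default_rng(4)
        lab = rng.choice([TN, TP, FP, FN], size=(20, 20)).astype(np.uint8)
        out = geometric_distance_correction(ConfusionMap(lab))
        keep = (lab == TP) | (lab == TN)
        np.testing.assert_array_equal(out.labels[keep], lab[keep])

    def test_monotone_fpr_fnr(self):
        """GDC can only reduce FPR and FNR (FP->TP, FN->TN)."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            lab = rng.choice([TN, TP, FP, FN], size=(18, 18),
                             p=[0.5, 0.25, 0.15, 0.1]).astype(np.uint8)
            cm = ConfusionMap(lab)
            out = geometric_distance_correction(cm)
            tp0, tn0, fp0, fn0 = confusion_counts(cm)
            tp1, tn1, fp1, fn1 = confusion_counts(out)
            assert fp1 <= fp0 and fn1 <= fn0
            assert tp1 + tn1 + fp1 + fn1 == tp0 + tn0 + fp0 + fn0
            if fp0 + tn0 > 0 and fp1 + tn1 > 0:
                assert fp1 / (fp1 + tn1) <= fp0 / (fp0 + tn0)
            if fn0 + tp0 > 0 and fn1 + tp1 > 0:
                assert fn1 / (fn1 + tp1) <= fn0 / (fn0 + tp0)

    def test_input_not_mutated(self):
        lab = np.full((21, 21), TN, dtype=np.uint8)
        lab[8:13, 8:13] = TP
        lab[10, 14] = FP
        cm = ConfusionMap(lab)
        before = cm.labels.copy()
        geometric_distance_correction(cm)
        np.testing.assert_array_equal(cm.labels, before)


class TestParams:
    def test_ier_params_validation(self):
        with pytest.raises(ValueError):
            IERParams(k=0)
        assert IERParams(k=3).regrow_radius == 1.5

    def test_gdc_params_validation(self):
        with pytest.raises(ValueError):
            GDCParams(patch_size=4)
        with pytest.raises(ValueError):
            GDCParams(patch_size=1)
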