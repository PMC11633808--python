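"""Independent brute-force reference implementations used by the tests.

Everything here is written with plain loops (no scipy) so agreement with the
package is evidence of correctness rather than shared code paths.
"""

import numpy as np

from autoconfidence.masks import ConfusionMap, OARMaskSet, TP, FP, FN

_SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)


def oracle_d2gs(pred: OARMaskSet, gs: OARMaskSet) -> np.ndarray:
    h, w = pred.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            out[y, x] = int(any(pred.channels[c, y, x] != gs.channels[c, y, x]
                                for c in range(pred.n_channels)))
    return out


def oracle_edges(seg: OARMaskSet) -> np.ndarray:
    h, w = seg.shape
    edge = np.zeros((h, w), bool)
    for c in range(seg.n_channels):
        f = np.pad(seg.channels[c].astype(float), 1, mode="reflect")
        for y in range(h):
            for x in range(w):
                win = f[y:y + 3, x:x + 3]
                gy = (win * _SOBEL_Y).sum()
                gx = (win * _SOBEL_Y.T).sum()
                if gy * gy + gx * gx > 0:
                    edge[y, x] = True
    return edge


def oracle_square_dilate(mask: np.ndarray, k: int) -> np.ndarray:
    h, w = mask.shape
    half = k // 2
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            y0, y1 = max(y - half, 0), min(y + half + 1, h)
            x0, x1 = max(x - half, 0), min(x + half + 1, w)
            out[y, x] = mask[y0:y1, x0:x1].any()
    return out


def oracle_ier(error_map: np.ndarray, seg: OARMaskSet, k: int = 3) -> np.ndarray:
    err = error_map.astype(bool)
    band = oracle_square_dilate(oracle_edges(seg), k)
    kept = err & ~band
    regrown = np.zeros_like(kept)
    kept_pts = np.argwhere(kept)
    for y, x in np.argwhere(band & err):
        for ky, kx in kept_pts:
            if (y - ky) ** 2 + (x - kx) ** 2 <= (k / 2.0) ** 2:
                regrown[y, x] = True
                break
    return (kept | regrown).astype(np.uint8)


def oracle_gdc(cm: ConfusionMap, patch_size: int = 31) -> ConfusionMap:
    half = patch_size // 2
    lab = cm.labels
    h, w = lab.shape
    out = cm.copy()
    for y in range(h):
        for x in range(w):
            if lab[y, x] not in (FP, FN):
                continue
            y0, y1 = max(y - half, 0), min(y + half + 1, h)
            x0, x1 = max(x - half, 0), min(x + half + 1, w)
            tp_pts = [(py, px) for py in range(y0, y1) for px in range(x0, x1)
                      if lab[py, px] == TP]
            if not tp_pts:
                continue
            d_x_tp = min(np.hypot(py - y, px - x) for py, px in tp_pts)
            # inscribed-disc diameter of the in-patch TP region: for each TP
            # voxel the distance to the nearest non-TP-or-outside voxel
            best = 0.0
            for py, px in tp_pts:
                d_bg = min(np.hypot(py - qy, px - qx)
                           for qy in range(y0 - 1, y1 + 1)
                           for qx in range(x0 - 1, x1 + 1)
                           if not (y0 <= qy < y1 and x0 <= qx < x1
                                   and lab[qy, qx] == TP))
                best = max(best, d_bg)
            if d_x_tp < 2.0 * best:
                from autoconfidence.masks import TN
                out.labels[y, x] = TP if lab[y, x] == FP else TN
                out.gdc_modified[y, x] = True
    return out
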