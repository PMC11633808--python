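"""Boundary-aware post-processing of error maps and confusion maps.

Two corrections:

* **Intelligent edge removal (IER)** deletes thin error predictions hugging
  organ boundaries (partial-volume artefacts of binary masks), then regrows
  substantial errors back into the boundary band so clinically significant
  findings adjacent to an edge survive. Applied symmetrically to predicted
  error maps and to the d2GS reference before metrics are computed.

* **Geometric distance correction (GDC)** reclassifies, at evaluation time
  only, apparent false positives/negatives that lie close to a sufficiently
  large true-positive region: such voxels mark genuine low-confidence areas
  adjoining real errors rather than spurious detections. GDC consumes and
  produces confusion maps; confidence maps are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .masks import ConfusionMap, OARMaskSet, ShapeError, TP, TN, FP, FN

__all__ = [
    "IERParams",
    "GDCParams",
    "segmentation_edges",
    "intelligent_edge_removal",
    "geometric_distance_correction",
]


@dataclass
class IERParams:
    """Edge-mask width ``k`` (voxels) and Euclidean regrow radius.

    ``regrow_radius`` defaults to k/2, the half-width of the removed band.
    """

    k: int = 3
    regrow_radius: float | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.regrow_radius is None:
            self.regrow_radius = self.k / 2.0


@dataclass
class GDCParams:
    """Side length (odd, voxels) of the local patch examined around each
    FP/FN voxel."""

    patch_size: int = 31

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")


def segmentation_edges(seg: OARMaskSet) -> np.ndarray:
    """Union over channels of the non-zero Sobel gradient magnitude.

    For a binary mask this is a ~2-voxel band straddling each boundary.
    """
    edge = np.zeros(seg.shape, dtype=bool)
    for c in range(seg.n_channels):
        f = seg.channels[c].astype(np.float64)
        gy = ndimage.sobel(f, axis=0)
        gx = ndimage.sobel(f, axis=1)
        edge |= np.hypot(gy, gx) > 0
    return edge


def _euclidean_dilation(mask: np.ndarray, radius: float) -> np.ndarray:
    """All voxels within Euclidean distance ``radius`` of the mask."""
    if not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius


def intelligent_edge_removal(error_map: np.ndarray, seg: OARMaskSet,
                             params: IERParams | None = None) -> np.ndarray:
    """Remove boundary-hugging errors, regrowing substantial ones.

    Steps: (1) Sobel edges of each predicted organ mask, union over
    channels; (2) dilation with a k x k square element; (3) errors inside
    the dilated edge band are removed; (4) surviving errors are regrown
    into the band within Euclidean radius k/2 (only where the input map had
    errors); (5) union of kept and regrown errors.

    The output is always a subset of the input error map. Apply the same
    call to both the thresholded confidence map and the d2GS reference.
    """
    params = params or IERParams()
    err = np.asarray(error_map).astype(bool)
    if err.shape != seg.shape:
        raise ShapeError(f"error map {err.shape} vs segmentation {seg.shape}")
    edge = segmentation_edges(seg)
    edge_dilated = ndimage.binary_dilation(
        edge, structure=np.ones((params.k, params.k), dtype=bool))
    kept = err & ~edge_dilated
    regrown = _euclidean_dilation(kept, params.regrow_radius) & edge_dilated & err
    return (kept | regrown).astype(np.uint8)


def geometric_distance_correction(cm: ConfusionMap,
                                  params: GDCParams | None = None
                                  ) -> ConfusionMap:
    """Reclassify FP/FN voxels lying near a large true-positive region.

    For each FP or FN voxel x, within the ``patch_size`` window centred on
    x (clipped at image borders):

    * ``D(tp_max)`` — the maximum dimension of the TP region in the patch,
      taken as the inscribed-disc diameter: twice the largest Euclidean
      distance-transform value inside TP (everything outside the patch
      counts as background);
    * ``D(x_tp)`` — the Euclidean distance from x to the nearest TP voxel
      in the patch.

    If ``D(x_tp) < D(tp_max)``, FP becomes TP and FN becomes TN, with the
    ``gdc_modified`` flag set. All decisions are made on the original
    labels (no cascading); TP and TN voxels never change. With no TP in the
    patch the voxel is left untouched.
    """
    params = params or GDCParams()
    half = params.patch_size // 2
    labels = cm.labels
    h, w = labels.shape
    tp_mask = labels == TP
    out = cm.copy()
    coords = np.argwhere((labels == FP) | (labels == FN))
    for y, x in coords:
        y0, y1 = max(y - half, 0), min(y + half + 1, h)
        x0, x1 = max(x - half, 0), min(x + half + 1, w)
        patch_tp = tp_mask[y0:y1, x0:x1]
        if not patch_tp.any():
            continue
        # distance from the central voxel to the nearest in-patch TP voxel
        tp_idx = np.argwhere(patch_tp)
        d_x_tp = np.sqrt(((tp_idx - [y - y0, x - x0]) ** 2).sum(axis=1)).min()
        # inscribed-disc diameter of the TP region, patch border = background
        padded = np.pad(patch_tp, 1)
        edt = ndimage.distance_transform_edt(padded)
        d_tp_max = 2.0 * edt[1:-1, 1:-1][patch_tp].max()
        if d_x_tp < d_tp_max:
            out.labels[y, x] = TP if labels[y, x] == FP else TN
            out.gdc_modified[y, x] = True
    return out
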