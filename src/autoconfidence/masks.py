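"""Binary-mask algebra shared by the whole pipeline.

Defines the in-memory containers (image slice, per-organ mask set, softmax
segmentation, difference-to-gold-standard error label, voxel-wise confusion
map) and the elementary operations on them: d2GS construction, softmax
binarization, Dice overlap and confusion labelling.

Conventions
-----------
* Mask channels are ``uint8`` arrays of shape ``(K, H, W)`` with values in
  {0, 1}; channel ``c`` holds organ ``names[c]``.
* Softmax class 0 is background; organ channel ``c`` corresponds to softmax
  class ``c + 1``.
* The positive class of a confusion map is the *error* voxel (a voxel where
  the segmentation under test disagrees with the gold standard).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageSlice",
    "OARMaskSet",
    "SoftmaxSeg",
    "D2GSMask",
    "ConfusionMap",
    "TN",
    "TP",
    "FP",
    "FN",
    "ShapeError",
    "compute_d2gs",
    "softmax_to_masks",
    "masks_to_labelmap",
    "labelmap_to_masks",
    "dsc",
    "confusion_map",
    "confusion_counts",
]

# confusion label codes
TN, TP, FP, FN = 0, 1, 2, 3


class ShapeError(ValueError):
    """Raised when paired grids disagree in shape or channel count."""


@dataclass
class ImageSlice:
    """A 2D grayscale slice with intensities normalized to [0, 1].

    Parameters
    ----------
    values : ndarray, shape (H, W)
        Finite intensities in [0, 1].
    spacing : float
        In-plane voxel size in mm (isotropic).
    """

    values: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ShapeError(f"image must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class OARMaskSet:
    """K aligned per-organ binary masks, one channel per organ at risk."""

    channels: np.ndarray  # (K, H, W) uint8 in {0, 1}
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3:
            raise ShapeError(f"mask channels must be (K, H, W), got {self.channels.shape}")
        vals = np.unique(self.channels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be binary {0, 1}")
        self.channels = self.channels.astype(np.uint8)
        if not self.names:
            self.names = [f"organ_{i:02d}" for i in range(self.channels.shape[0])]
        if len(self.names) != self.channels.shape[0]:
            raise ShapeError("number of names must equal number of channels")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def is_disjoint(self) -> bool:
        """True when no voxel belongs to more than one organ."""
        return bool(self.channels.sum(axis=0).max(initial=0) <= 1)

    def copy(self) -> "OARMaskSet":
        return OARMaskSet(self.channels.copy(), list(self.names))


@dataclass
class SoftmaxSeg:
    """Per-voxel class probabilities over background + K organs.

    ``probs`` has shape (K+1, H, W); class 0 is background.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3:
            raise ShapeError(f"softmax must be (K+1, H, W), got {self.probs.shape}")
        if self.probs.min() < -1e-6:
            raise ValueError("softmax probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("softmax probabilities must sum to 1 per voxel")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[1:]


@dataclass
class D2GSMask:
    """Single-channel binary difference-to-gold-standard error label.

    1 marks the error class (any channel-wise disagreement between the
    segmentation under test and the gold standard), 0 the correct class.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ShapeError(f"d2GS must be 2D, got {self.values.shape}")
        if not np.all(np.isin(np.unique(self.values), (0, 1))):
            raise ValueError("d2GS values must be binary {0, 1}")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ConfusionMap:
    """Per-voxel TP/FP/FN/TN labels (positive class = error voxel).

    ``gdc_modified`` flags voxels whose label was changed by the geometric
    distance correction; it is all-False for freshly computed maps.
    """

    labels: np.ndarray  # (H, W) uint8, codes TN/TP/FP/FN
    gdc_modified: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ShapeError(f"confusion labels must be 2D, got {self.labels.shape}")
        if self.labels.max(initial=0) > 3:
            raise ValueError("confusion labels must be codes in {0, 1, 2, 3}")
        if self.gdc_modified is None:
            self.gdc_modified = np.zeros(self.labels.shape, dtype=bool)
        else:
            self.gdc_modified = np.asarray(self.gdc_modified, dtype=bool)
            if self.gdc_modified.shape != self.labels.shape:
                raise ShapeError("gdc_modified must match labels shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy(self) -> "ConfusionMap":
        return ConfusionMap(self.labels.copy(), self.gdc_modified.copy())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_d2gs(pred: OARMaskSet, gs: OARMaskSet) -> D2GSMask:
    """Difference to gold standard: channel-wise maximum absolute difference.

    A voxel is labelled 1 (error class) when *any* organ channel disagrees
    between the proposed segmentation and the gold standard, covering both
    under- and over-segmentation. Symmetric in its arguments.
    """
    if pred.channels.shape != gs.channels.shape:
        raise ShapeError(
            f"channel stacks differ: {pred.channels.shape} vs {gs.channels.shape}"
        )
    diff = np.abs(pred.channels.astype(np.int16) - gs.channels.astype(np.int16))
    return D2GSMask(diff.max(axis=0).astype(np.uint8))


def masks_to_labelmap(masks: OARMaskSet) -> np.ndarray:
    """Collapse a disjoint mask set to an integer label map (0 = background)."""
    lab = np.zeros(masks.shape, dtype=np.int64)
    for c in range(masks.n_channels):
        lab[masks.channels[c] == 1] = c + 1
    return lab


def labelmap_to_masks(labels: np.ndarray, n_organs: int, names=None) -> OARMaskSet:
    """Expand an integer label map (0 = background) to K binary channels."""
    channels = np.stack(
        [(labels == c + 1).astype(np.uint8) for c in range(n_organs)], axis=0
    )
    return OARMaskSet(channels, list(names) if names else [])


def softmax_to_masks(seg: SoftmaxSeg, names=None) -> OARMaskSet:
    """Binarize a softmax segmentation by per-voxel argmax.

    The background class yields 0 in all organ channels. Exact probability
    ties are broken toward the lowest class index (argmax convention), so a
    fully uniform softmax produces empty masks.
    """
    labels = np.argmax(seg.probs, axis=0)
    return labelmap_to_masks(labels, seg.n_classes - 1, names)


def dsc(pred_channel: np.ndarray, gs_channel: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` of two binary grids.

    Returns ``nan`` (the undefined marker, excluded from averages) when both
    masks are empty — 0/0 would otherwise silently score as perfect.
    """
    a = np.asarray(pred_channel).astype(bool)
    b = np.asarray(gs_channel).astype(bool)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def confusion_map(pred_error: np.ndarray, d2gs: D2GSMask) -> ConfusionMap:
    """Label every voxel TP/FP/FN/TN against the d2GS error reference.

    ``pred_error`` is the binarized error prediction (1 = flagged as error).
    TP: flagged and truly an error; FP: flagged but correct; FN: missed
    error; TN: correctly unflagged.
    """
    pred = np.asarray(pred_error)
    if not np.all(np.isin(np.unique(pred), (0, 1))):
        raise ValueError("pred_error must be binary {0, 1}")
    pred = pred.astype(bool)
    ref = d2gs.values.astype(bool)
    if pred.shape != ref.shape:
        raise ShapeError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    labels = np.full(pred.shape, TN, dtype=np.uint8)
    labels[pred & ref] = TP
    labels[pred & ~ref] = FP
    labels[~pred & ref] = FN
    return ConfusionMap(labels)


def confusion_counts(cm: ConfusionMap, region: np.ndarray | None = None):
    """(tp, tn, fp, fn) voxel counts, optionally restricted to a region mask."""
    lab = cm.labels
    if region is not None:
        region = np.asarray(region).astype(bool)
        if region.shape != lab.shape:
            raise ShapeError("region must match confusion-map shape")
        lab = lab[region]
    return (
        int(np.sum(lab == TP)),
        int(np.sum(lab == TN)),
        int(np.sum(lab == FP)),
        int(np.sum(lab == FN)),
    )
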