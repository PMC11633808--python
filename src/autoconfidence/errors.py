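"""Synthetic segmentation-error injection.

Corrupts organ mask sets with three error families that mimic real-world
auto-segmentation failures:

* **geometric** — rigid rotation/translation plus a smooth non-rigid
  deformation interpolated with thin-plate splines from normally
  distributed displacement vectors on a regular 2 cm control grid
  (a misregistration-like error applied to all channels jointly);
* **class perturbation** — relabelling every voxel of one predicted organ
  to its next-most-likely class under the softmax;
* **organ removal** — deleting an entire organ mask.

Used during training to harden the discriminator and at test time, at two
magnitudes, to emulate external auto-segmentation models of low and high
quality. Masks stay binary throughout (nearest-neighbour resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .masks import OARMaskSet, SoftmaxSeg, labelmap_to_masks

__all__ = [
    "ErrorInjectionConfig",
    "apply_rigid",
    "apply_tps",
    "perturb_class",
    "remove_oar",
    "inject",
]


@dataclass
class ErrorInjectionConfig:
    """Per-slice application probabilities and magnitudes.

    ``tps_grid_spacing`` is in mm (default 20 mm = 2 cm, i.e. 20 voxels at
    the fixed 1 mm in-plane spacing); ``tps_sigma`` is the standard
    deviation of the control-point displacement vectors in mm.
    ``magnitude_scale`` multiplies rotation, translation and tps_sigma,
    distinguishing low-quality-like from high-quality-like corruption.
    """

    p_geometric: float = 0.5
    p_class_perturb: float = 0.3
    p_removal: float = 0.3
    rotation_range: float = 10.0       # degrees, uniform in +-range
    translation_range: float = 4.0     # voxels, uniform in +-range per axis
    tps_grid_spacing: float = 20.0     # mm
    tps_sigma: float = 3.0             # mm
    magnitude_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_geometric", "p_class_perturb", "p_removal"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tps_grid_spacing <= 0:
            raise ValueError("tps_grid_spacing must be > 0")
        if self.tps_sigma < 0:
            raise ValueError("tps_sigma must be >= 0")
        if self.magnitude_scale < 0:
            raise ValueError("magnitude_scale must be >= 0")


def _resample_nearest(channels: np.ndarray, src_y: np.ndarray,
                      src_x: np.ndarray) -> np.ndarray:
    """Backward-warp all channels at once with nearest-neighbour lookup.

    ``src_y``/``src_x`` give, for each output voxel, the (float) source
    coordinate; out-of-bounds voxels become 0.
    """
    h, w = channels.shape[1:]
    iy = np.round(src_y).astype(np.int64)
    ix = np.round(src_x).astype(np.int64)
    valid = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
    iy_c = np.clip(iy, 0, h - 1)
    ix_c = np.clip(ix, 0, w - 1)
    out = channels[:, iy_c, ix_c]
    out[:, ~valid] = 0
    return out.astype(np.uint8)


def apply_rigid(masks: OARMaskSet, rotation: float, translation=(0.0, 0.0),
                seed: int | None = None) -> OARMaskSet:
    """Rotate (degrees, about the image centre) then translate (voxels).

    A voxel at (r, c) moves to (r + translation[0], c + translation[1]);
    positive rotation turns the row axis toward the column axis. All
    channels share the transform; nearest-neighbour keeps masks binary.
    ``seed`` is accepted for interface symmetry; the op itself is
    deterministic.
    """
    h, w = masks.shape
    ty, tx = float(translation[0]), float(translation[1])
    theta = np.deg2rad(rotation)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # invert: undo translation, then rotate back about the centre
    dy = yy - ty - cy
    dx = xx - tx - cx
    ct, st = np.cos(theta), np.sin(theta)
    src_y = ct * dy + st * dx + cy
    src_x = -st * dy + ct * dx + cx
    return OARMaskSet(_resample_nearest(masks.channels, src_y, src_x),
                      list(masks.names))


def apply_tps(masks: OARMaskSet, grid_spacing_mm: float = 20.0,
              sigma_mm: float = 3.0, seed: int = 0,
              spacing_mm: float = 1.0) -> OARMaskSet:
    """Non-rigid deformation via thin-plate-spline interpolated displacements.

    Control points lie on a regular grid of ``grid_spacing_mm`` covering the
    slice (grid extended to the borders, at least 2 points per axis);
    their displacement vectors are drawn i.i.d. Normal(0, sigma_mm). The
    dense field is the thin-plate-spline interpolation of those vectors,
    applied identically to all channels with nearest-neighbour lookup.
    """
    h, w = masks.shape
    if sigma_mm == 0:
        return masks.copy()
    step = grid_spacing_mm / spacing_mm
    ny = max(int(np.floor((h - 1) / step)) + 1, 2)
    nx = max(int(np.floor((w - 1) / step)) + 1, 2)
    gy = np.linspace(0, h - 1, ny)
    gx = np.linspace(0, w - 1, nx)
    if ny < 2 or nx < 2:
        raise ValueError("degenerate control grid")
    pts = np.stack(np.meshgrid(gy, gx, indexing="ij"), axis=-1).reshape(-1, 2)
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma_mm / spacing_mm, size=(pts.shape[0], 2))
    interp = RBFInterpolator(pts, disp, kernel="thin_plate_spline")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    targets = np.stack([yy.ravel(), xx.ravel()], axis=1)
    field = interp(targets).reshape(h, w, 2)
    src_y = yy + field[:, :, 0]
    src_x = xx + field[:, :, 1]
    return OARMaskSet(_resample_nearest(masks.channels, src_y, src_x),
                      list(masks.names))


def perturb_class(softmax: SoftmaxSeg, target_channel: int,
                  names=None) -> OARMaskSet:
    """Relabel one predicted organ to its next-most-likely softmax class.

    Every voxel whose argmax class is organ ``target_channel`` is assigned
    its second-highest-probability class; all other voxels keep their
    argmax label. Returns the binarized mask set. If the target organ is
    empty under argmax, warns and returns the unperturbed argmax masks.
    """
    k = softmax.n_classes - 1
    if not 0 <= target_channel < k:
        raise IndexError(f"target_channel {target_channel} out of range for K={k}")
    order = np.argsort(-softmax.probs, axis=0, kind="stable")
    labels = order[0]
    second = order[1]
    target_class = target_channel + 1
    sel = labels == target_class
    if not np.any(sel):
        warnings.warn(f"target channel {target_channel} empty under argmax; no-op",
                      RuntimeWarning, stacklevel=2)
        return labelmap_to_masks(labels, k, names)
    new_labels = labels.copy()
    new_labels[sel] = second[sel]
    return labelmap_to_masks(new_labels, k, names)


def remove_oar(masks: OARMaskSet, channel: int) -> OARMaskSet:
    """Zero one organ channel, leaving every other channel bit-identical."""
    if not 0 <= channel < masks.n_channels:
        raise IndexError(f"channel {channel} out of range for K={masks.n_channels}")
    out = masks.copy()
    out.channels[channel] = 0
    return out


def inject(seg_masks: OARMaskSet, softmax: SoftmaxSeg | None,
           config: ErrorInjectionConfig) -> tuple[OARMaskSet, list[dict]]:
    """Apply each error family independently with its probability.

    Families are drawn and parameterized from ``config.seed`` so the
    corrupted set and its log are reproducible. The returned log records,
    per applied family, its parameters and the channels affected.
    """
    if config.p_class_perturb > 0 and softmax is None:
        raise ValueError("class perturbation requires the softmax segmentation")
    rng = np.random.default_rng(config.seed)
    out = seg_masks.copy()
    log: list[dict] = []
    scale = config.magnitude_scale

    if rng.random() < config.p_class_perturb:
        channel = int(rng.integers(out.n_channels))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = perturb_class(softmax, channel, names=out.names)
        log.append({"family": "class_perturb", "channel": channel})

    if rng.random() < config.p_geometric:
        rot = float(rng.uniform(-1, 1) * config.rotation_range * scale)
        ty = float(rng.uniform(-1, 1) * config.translation_range * scale)
        tx = float(rng.uniform(-1, 1) * config.translation_range * scale)
        tps_seed = int(rng.integers(2 ** 31))
        out = apply_rigid(out, rot, (ty, tx))
        if config.tps_sigma * scale > 0:
            out = apply_tps(out, config.tps_grid_spacing,
                            config.tps_sigma * scale, seed=tps_seed)
        log.append({"family": "geometric", "rotation_deg": rot,
                    "translation": (ty, tx),
                    "tps_sigma": config.tps_sigma * scale,
                    "tps_seed": tps_seed, "channels": "all"})

    if rng.random() < config.p_removal:
        nonempty = [c for c in range(out.n_channels) if out.channels[c].any()]
        if nonempty:
            channel = int(nonempty[rng.integers(len(nonempty))])
            out = remove_oar(out, channel)
            log.append({"family": "removal", "channel": channel})

    return out, log
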