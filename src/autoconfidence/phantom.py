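"""Synthetic 2D "MRI-like" phantom slices with gold-standard organ masks.

The clinical training data for this kind of segmentation-QA model (T1w brain
MRI with expert organ-at-risk contours) cannot be shipped, so this module
generates slices that reproduce its statistical difficulties instead:

* several non-overlapping soft-boundary elliptical "organs" of varying size,
  including, when requested, a tiny structure of fewer than 10 voxels (the
  lens-like case) and an organ whose contrast does not exceed the noise
  level (the near-invisible-boundary case);
* a smooth multiplicative shading field standing in for coil/bias-field
  texture, giving the discriminator image structure to correlate with;
* additive i.i.d. Gaussian noise.

The in-plane spacing is fixed at 1 mm/voxel so that physical error-injection
scales (e.g. a 2 cm deformation grid) map to 20 voxels.

Everything is reproducible from ``PhantomConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .masks import ImageSlice, OARMaskSet

__all__ = ["PhantomConfig", "PlacementError", "generate_phantom", "generate_slices"]


class PlacementError(RuntimeError):
    """Raised when organs cannot be placed without overlap after bounded retries."""


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    organ_size_range : (min, max) equivalent radius in voxels.
    contrast_levels  : organ-to-background intensity offsets in [0, 1],
                       cycled if shorter than ``n_organs``.
    noise_sigma      : standard deviation of the additive Gaussian noise.
    include_tiny_organ : force the last organ to have area < 10 voxels.
    include_low_contrast_organ : force one organ's contrast <= noise_sigma.
    """

    height: int = 64
    width: int = 64
    n_organs: int = 3
    organ_size_range: tuple[float, float] = (3.0, 9.0)
    contrast_levels: tuple[float, ...] = (0.5, 0.3, 0.15)
    noise_sigma: float = 0.05
    include_tiny_organ: bool = True
    include_low_contrast_organ: bool = True
    spacing: float = 1.0
    background: float = 0.3
    shading_amplitude: float = 0.08
    max_place_retries: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom must be at least 32x32 voxels")
        if self.n_organs < 1:
            raise ValueError("need at least one organ")
        lo, hi = self.organ_size_range
        if not (0 < lo <= hi):
            raise ValueError("organ_size_range must satisfy 0 < min <= max")
        if any(not (0 <= c <= 1) for c in self.contrast_levels):
            raise ValueError("contrast levels must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _organ_contrasts(config: PhantomConfig) -> np.ndarray:
    """Per-organ contrast, applying the low-contrast difficulty knob."""
    levels = np.array([config.contrast_levels[i % len(config.contrast_levels)]
                       for i in range(config.n_organs)], dtype=float)
    if config.include_low_contrast_organ:
        # second-to-last organ (or the only one) gets contrast <= noise_sigma
        idx = max(config.n_organs - 2, 0)
        levels[idx] = min(levels[idx], 0.8 * config.noise_sigma) \
            if config.noise_sigma > 0 else 0.0
    return levels


def _organ_mask(h: int, w: int, cy: float, cx: float, a: float, b: float,
                theta: float, wobble: tuple[float, float, float, float]) -> np.ndarray:
    """Rasterize one smooth-boundary ellipse as a binary mask."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    r = np.sqrt(u * u + v * v)
    phi = np.arctan2(v, u)
    amp2, ph2, amp3, ph3 = wobble
    boundary = 1.0 + amp2 * np.sin(2 * phi + ph2) + amp3 * np.sin(3 * phi + ph3)
    return (r <= boundary).astype(np.uint8)


def generate_phantom(config: PhantomConfig) -> tuple[ImageSlice, OARMaskSet]:
    """Generate one slice and its gold-standard mask set.

    Organs are placed sequentially with rejection sampling; masks are
    pairwise disjoint (with a one-voxel separation band) and fully inside
    the image. Raises :class:`PlacementError` when placement fails after
    bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    contrasts = _organ_contrasts(config)

    radii = rng.uniform(*config.organ_size_range, size=config.n_organs)
    if config.include_tiny_organ:
        radii[-1] = rng.uniform(1.2, 1.6)  # area ~ 4-8 voxels

    channels = np.zeros((config.n_organs, h, w), dtype=np.uint8)
    occupied = np.zeros((h, w), dtype=bool)
    # place big organs first so small ones can fit in the gaps
    order = np.argsort(-radii)
    for organ in order:
        r = radii[organ]
        tiny = config.include_tiny_organ and organ == config.n_organs - 1
        placed = False
        for _ in range(config.max_place_retries):
            aspect = rng.uniform(0.75, 1.3)
            a, b = r * aspect, r / aspect
            theta = rng.uniform(0, np.pi)
            wobble = ((0.0, 0.0, 0.0, 0.0) if tiny else
                      (rng.uniform(0, 0.15), rng.uniform(0, 2 * np.pi),
                       rng.uniform(0, 0.10), rng.uniform(0, 2 * np.pi)))
            margin = max(a, b) * 1.3 + 2
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            mask = _organ_mask(h, w, cy, cx, a, b, theta, wobble)
            if mask.sum() == 0:
                continue
            if tiny and mask.sum() >= 10:
                continue
            grown = ndimage.binary_dilation(mask, np.ones((3, 3)))
            if np.any(grown & occupied):
                continue
            channels[organ] = mask
            occupied |= grown.astype(bool)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place organ {organ} (radius {r:.1f}) without overlap "
                f"after {config.max_place_retries} retries")

    # smooth multiplicative shading: low-frequency bias-field-like texture
    rough = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(rough, sigma=min(h, w) / 4.0)
    peak = np.abs(smooth).max()
    shading = 1.0 + config.shading_amplitude * (smooth / peak if peak > 0 else smooth)

    base = np.full((h, w), config.background, dtype=float)
    for c in range(config.n_organs):
        base += contrasts[c] * channels[c]
    img = shading * base
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    names = [f"organ_{i:02d}" for i in range(config.n_organs)]
    return ImageSlice(img.astype(np.float32), spacing=config.spacing), \
        OARMaskSet(channels, names)


def generate_slices(n_slices: int, config: PhantomConfig
                    ) -> list[tuple[ImageSlice, OARMaskSet]]:
    """Generate ``n_slices`` independent phantoms, seeded from the config.

    Per-slice seeds are spawned deterministically from ``config.seed``, so
    the whole set is reproducible bit-for-bit.
    """
    seeds = slice_seeds(config.seed, n_slices)
    return [generate_phantom(replace(config, seed=int(s))) for s in seeds]


def slice_seeds(master_seed: int, n_slices: int) -> np.ndarray:
    """Deterministic per-slice seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([c.generate_state(1)[0] % (2 ** 31) for c in ss.spawn(n_slices)],
                    dtype=np.int64)


def generate_dataset(n_slices: int, config: PhantomConfig, out_dir) -> "pd.DataFrame":
    """Write ``n_slices`` image/mask NIfTI pairs plus a CSV manifest.

    Returns the manifest frame (also written to ``out_dir/manifest.csv``)
    listing file paths, per-slice seeds and organ names. Two runs with the
    same config produce identical data and manifests.
    """
    import pandas as pd
    from pathlib import Path
    from . import io as acio

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    seeds = slice_seeds(config.seed, n_slices)
    rows = []
    for i, s in enumerate(seeds):
        image, masks = generate_phantom(replace(config, seed=int(s)))
        img_name = f"slice_{i:04d}_image.nii.gz"
        msk_name = f"slice_{i:04d}_masks.nii.gz"
        try:
            acio.write_image(out_dir / img_name, image)
            acio.write_masks(out_dir / msk_name, masks)
        except OSError as exc:
            raise OSError(f"failed writing slice {i} under {out_dir}: {exc}") from exc
        rows.append({"index": i, "image_path": img_name, "mask_path": msk_name,
                     "seed": int(s), "organ_names": ";".join(masks.names)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
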