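"""Reading and writing slices, mask stacks, manifests and run artifacts.

Images and masks travel as NIfTI (2D slices stored as single-slice volumes
so affine semantics stay intact; mask sets as one multi-channel volume with
a JSON sidecar preserving channel names/order). PNG is accepted for small
2D fixtures. Binary masks round-trip losslessly in both formats.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .masks import ImageSlice, OARMaskSet, ShapeError

__all__ = [
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "read_masks",
    "write_masks",
    "read_manifest",
    "load_dataset",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _affine(spacing: float) -> np.ndarray:
    return np.diag([spacing, spacing, 1.0, 1.0])


def write_image(path, image: ImageSlice) -> None:
    path = Path(path)
    if _is_nifti(path):
        data = image.values.astype(np.float32)[:, :, None]
        nib.save(nib.Nifti1Image(data, _affine(image.spacing)), str(path))
    elif path.suffix.lower() == ".png":
        # 8-bit quantization; adequate for visual fixtures only
        iio.imwrite(path, np.round(image.values * 255).astype(np.uint8))
    else:
        raise ValueError(f"unknown image format: {path}")


def read_image(path) -> ImageSlice:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if _is_nifti(path):
        vol = nib.load(str(path))
        data = np.asanyarray(vol.dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ShapeError(f"expected a single 2D slice in {path}, got {data.shape}")
        spacing = float(vol.header.get_zooms()[0])
        return ImageSlice(np.clip(data.astype(np.float32), 0, 1), spacing=spacing)
    if path.suffix.lower() == ".png":
        data = iio.imread(path)
        if data.ndim == 3:
            data = data[..., 0]
        return ImageSlice(data.astype(np.float32) / 255.0)
    raise ValueError(f"unknown image format: {path}")


def _names_sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".png"):
        if name.lower().endswith(suf):
            return path.with_name(name[: -len(suf)] + ".names.json")
    return path.with_suffix(".names.json")


def write_masks(path, masks: OARMaskSet) -> None:
    """Write a mask set as a (H, W, 1, K) uint8 NIfTI plus a name sidecar."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError("mask stacks are written as NIfTI; use write_image for "
                         "single-channel PNG fixtures")
    data = masks.channels.transpose(1, 2, 0)[:, :, None, :].astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(1.0)), str(path))
    _names_sidecar(path).write_text(json.dumps({"names": masks.names}))


def read_masks(path) -> OARMaskSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim == 4 and data.shape[2] == 1:
        channels = data[:, :, 0, :].transpose(2, 0, 1)
    elif data.ndim == 3:
        channels = data.transpose(2, 0, 1)
    else:
        raise ShapeError(f"expected (H, W, 1, K) mask stack in {path}, got {data.shape}")
    sidecar = _names_sidecar(path)
    names = json.loads(sidecar.read_text())["names"] if sidecar.exists() else []
    return OARMaskSet((channels > 0).astype(np.uint8), names)


def write_volume(path, obj) -> None:
    """Dispatch on object type: ImageSlice or OARMaskSet."""
    if isinstance(obj, ImageSlice):
        write_image(path, obj)
    elif isinstance(obj, OARMaskSet):
        write_masks(path, obj)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_volume(path, kind: str = "image"):
    if kind == "image":
        return read_image(path)
    if kind == "masks":
        return read_masks(path)
    raise ValueError("kind must be 'image' or 'masks'")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"index", "image_path", "mask_path", "seed", "organ_names"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def load_dataset(manifest_path) -> list[tuple[ImageSlice, OARMaskSet]]:
    """Load all (image, gold-standard masks) pairs listed in a manifest.

    Relative paths are resolved against the manifest's directory. Paired
    files must agree in spatial shape.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    out = []
    for _, row in df.iterrows():
        img = read_image(root / str(row["image_path"]))
        masks = read_masks(root / str(row["mask_path"]))
        if img.shape != masks.shape:
            raise ShapeError(
                f"image/mask shape mismatch for row {row['index']}: "
                f"{img.shape} vs {masks.shape}")
        out.append((img, masks))
    return out
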