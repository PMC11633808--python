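"""Segmentation generator (2D U-net) and confidence discriminator (U-ResNet).

The generator maps a grayscale slice to a per-voxel softmax over background
plus K organ classes through eight convolutional layers (seven 3x3 plus a
1x1 classifier) arranged as a one-pool U-net with batch normalization,
dropout and ReLU activations.

The discriminator extends a patch-wise discriminator to a shallow
encoder-decoder with residual blocks: it takes the K organ masks with the
image as the final channel and emits a per-voxel two-class softmax
(error / correct); the error-class channel is the confidence map's
complement. Both networks are fully convolutional, so any even spatial size
works.

Exact filter counts, kernel sizes and dropout rates follow scaled-down
defaults chosen for CPU training; all are overridable through the specs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .masks import ImageSlice, OARMaskSet, SoftmaxSeg, ShapeError
from . import nn

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "ConfidenceMap",
    "UNetGenerator",
    "UResNetDiscriminator",
    "build_generator",
    "build_discriminator",
    "save_model",
    "load_model",
]

CHECKPOINT_VERSION = 1


@dataclass
class GeneratorSpec:
    """Architecture of the segmentation generator.

    ``out_classes`` is K+1 (background + K organs). ``n_conv_layers`` is
    fixed at 8 (seven 3x3 convolutions and a 1x1 classifier).
    """

    in_channels: int = 1
    out_classes: int = 4
    n_conv_layers: int = 8
    base_filters: int = 16
    dropout_rate: float = 0.2
    norm: bool = True

    def __post_init__(self) -> None:
        if self.n_conv_layers != 8:
            raise ValueError("the generator architecture has 8 convolutional layers")
        if self.out_classes < 2:
            raise ValueError("need at least background + one organ class")


@dataclass
class DiscriminatorSpec:
    """Architecture of the confidence discriminator.

    ``in_channels`` is K+1: one binary mask channel per organ plus the image
    as the final channel. ``depth`` is the number of encoder-decoder levels
    (kept shallow) with ``n_residual_blocks`` residual blocks per level.
    """

    in_channels: int = 4
    out_classes: int = 2
    n_residual_blocks: int = 2
    depth: int = 2
    base_filters: int = 16

    def __post_init__(self) -> None:
        if self.out_classes != 2:
            raise ValueError("discriminator output is the two-class error/correct softmax")
        if self.depth != 2:
            raise ValueError("only the shallow 2-level encoder-decoder is implemented")


@dataclass
class ConfidenceMap:
    """Per-voxel probability of the error class.

    The confidence presented to an operator is ``1 - p_error``; internally
    everything works with the error-class probability.
    """

    p_error: np.ndarray

    def __post_init__(self) -> None:
        self.p_error = np.asarray(self.p_error, dtype=np.float32)
        if self.p_error.ndim != 2:
            raise ShapeError(f"confidence map must be 2D, got {self.p_error.shape}")
        if self.p_error.min() < -1e-6 or self.p_error.max() > 1 + 1e-6:
            raise ValueError("p_error must lie in [0, 1]")
        self.p_error = np.clip(self.p_error, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_error.shape

    def binarize(self, threshold: float = 0.5) -> np.ndarray:
        """Thresholded error prediction (p_error >= threshold -> 1)."""
        return (self.p_error >= threshold).astype(np.uint8)


def _check_even(x: np.ndarray) -> None:
    if x.shape[1] % 2 or x.shape[2] % 2:
        raise ShapeError(
            f"spatial size {x.shape[1:3]} must be divisible by the 2x downsampling")


class _ConvBNRelu:
    def __init__(self, cin, cout, k, rng, norm=True):
        self.conv = nn.Conv2d(cin, cout, k, rng)
        self.bn = nn.BatchNorm2d(cout) if norm else None
        self.relu = nn.ReLU()

    def forward(self, x, train):
        h = self.conv.forward(x, train)
        if self.bn is not None:
            h = self.bn.forward(h, train)
        return self.relu.forward(h, train)

    def backward(self, d):
        d = self.relu.backward(d)
        if self.bn is not None:
            d = self.bn.backward(d)
        return self.conv.backward(d)

    def layers(self):
        return [self.conv] + ([self.bn] if self.bn is not None else [])


class _ResBlock:
    """Pre-activation-free residual block: relu(x + bn(conv(relu(bn(conv(x))))))."""

    def __init__(self, channels, rng):
        self.c1 = nn.Conv2d(channels, channels, 3, rng)
        self.b1 = nn.BatchNorm2d(channels)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(channels, channels, 3, rng)
        self.b2 = nn.BatchNorm2d(channels)
        self.r2 = nn.ReLU()

    def forward(self, x, train):
        h = self.r1.forward(self.b1.forward(self.c1.forward(x, train), train), train)
        h = self.b2.forward(self.c2.forward(h, train), train)
        return self.r2.forward(x + h, train)

    def backward(self, d):
        d = self.r2.backward(d)
        dh = self.c1.backward(self.b1.backward(self.r1.backward(
            self.c2.backward(self.b2.backward(d)))))
        return d + dh

    def layers(self):
        return [self.c1, self.b1, self.c2, self.b2]


class _Model:
    """Shared parameter/serialization plumbing."""

    def _all_layers(self) -> list:
        raise NotImplementedError

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._all_layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        arrs = []
        for layer in self._all_layers():
            for p in layer.params():
                arrs.append(p.value)
            if isinstance(layer, nn.BatchNorm2d):
                arrs.append(layer.running_mean)
                arrs.append(layer.running_var)
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        it = iter(arrs)
        for layer in self._all_layers():
            for p in layer.params():
                a = next(it)
                if a.shape != p.value.shape:
                    raise ValueError("checkpoint does not match architecture")
                p.value = a.astype(nn.DTYPE).copy()
                p.grad = np.zeros_like(p.value)
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = next(it).astype(nn.DTYPE).copy()
                layer.running_var = next(it).astype(nn.DTYPE).copy()


class UNetGenerator(_Model):
    """Eight-convolution U-net emitting a per-voxel softmax segmentation."""

    kind = "generator"

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        norm = spec.norm
        self.enc1 = _ConvBNRelu(spec.in_channels, f, 3, rng, norm)
        self.enc2 = _ConvBNRelu(f, f, 3, rng, norm)
        self.pool = nn.MaxPool2x()
        self.bot1 = _ConvBNRelu(f, 2 * f, 3, rng, norm)
        self.drop = nn.Dropout(spec.dropout_rate, rng)
        self.bot2 = _ConvBNRelu(2 * f, 2 * f, 3, rng, norm)
        self.up = nn.Upsample2x()
        self.dec1 = _ConvBNRelu(3 * f, f, 3, rng, norm)
        self.dec2 = _ConvBNRelu(f, f, 3, rng, norm)
        self.dec3 = _ConvBNRelu(f, f, 3, rng, norm)
        self.head = nn.Conv2d(f, spec.out_classes, 1, rng)
        self._f = f

    def _all_layers(self):
        blocks = [self.enc1, self.enc2, self.bot1, self.bot2,
                  self.dec1, self.dec2, self.dec3]
        layers = []
        for b in blocks:
            layers.extend(b.layers())
        layers.append(self.head)
        return layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, 1) image -> (N, H, W, K+1) softmax probabilities."""
        _check_even(x)
        h1 = self.enc1.forward(x, train)
        h2 = self.enc2.forward(h1, train)
        p = self.pool.forward(h2, train)
        b = self.bot1.forward(p, train)
        b = self.drop.forward(b, train)
        b = self.bot2.forward(b, train)
        u = self.up.forward(b, train)
        cat = np.concatenate([u, h2], axis=-1)
        d = self.dec1.forward(cat, train)
        d = self.dec2.forward(d, train)
        d = self.dec3.forward(d, train)
        z = self.head.forward(d, train)
        self._probs = nn.softmax(z, axis=-1)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        d = self.dec3.backward(d)
        d = self.dec2.backward(d)
        dcat = self.dec1.backward(d)
        du, dh2_skip = dcat[..., :2 * self._f], dcat[..., 2 * self._f:]
        db = self.up.backward(du)
        db = self.bot2.backward(db)
        db = self.drop.backward(db)
        dp = self.bot1.backward(db)
        dh2 = self.pool.backward(dp) + dh2_skip
        dh1 = self.enc2.backward(dh2)
        return self.enc1.backward(dh1)

    def predict(self, image: ImageSlice) -> SoftmaxSeg:
        """Evaluation-mode segmentation of a single slice."""
        x = image.values[None, :, :, None].astype(nn.DTYPE)
        probs = self.forward(x, train=False)
        return SoftmaxSeg(probs[0].transpose(2, 0, 1))


class UResNetDiscriminator(_Model):
    """Shallow residual encoder-decoder giving voxel-wise discrimination.

    Input channel order is (mask_0, ..., mask_{K-1}, image); the error-class
    probability is softmax channel 1.
    """

    kind = "discriminator"

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        nb = spec.n_residual_blocks
        self.stem = _ConvBNRelu(spec.in_channels, f, 3, rng)
        self.level1 = [_ResBlock(f, rng) for _ in range(nb)]
        self.pool = nn.MaxPool2x()
        self.level2 = [_ResBlock(f, rng) for _ in range(nb)]
        self.up = nn.Upsample2x()
        self.fuse = _ConvBNRelu(2 * f, f, 3, rng)
        self.head = nn.Conv2d(f, spec.out_classes, 1, rng)
        self._f = f
        self.ablate: str | None = None  # 'image' | 'masks' | None

    def _all_layers(self):
        layers = list(self.stem.layers())
        for b in self.level1 + self.level2:
            layers.extend(b.layers())
        layers.extend(self.fuse.layers())
        layers.append(self.head)
        return layers

    def _apply_ablation(self, x: np.ndarray) -> np.ndarray:
        if self.ablate is None:
            return x
        x = x.copy()
        if self.ablate == "image":
            x[..., -1] = 0.0
        elif self.ablate == "masks":
            x[..., :-1] = 0.0
        else:
            raise ValueError(f"unknown ablation {self.ablate!r}")
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, K+1) stacked (masks..., image) -> (N, H, W, 2) softmax."""
        if x.shape[-1] != self.spec.in_channels:
            raise ShapeError(
                f"expected {self.spec.in_channels} input channels "
                f"(K masks + image), got {x.shape[-1]}")
        _check_even(x)
        x = self._apply_ablation(x)
        h = self.stem.forward(x, train)
        for b in self.level1:
            h = b.forward(h, train)
        skip = h
        p = self.pool.forward(h, train)
        for b in self.level2:
            p = b.forward(p, train)
        u = self.up.forward(p, train)
        cat = np.concatenate([u, skip], axis=-1)
        g = self.fuse.forward(cat, train)
        z = self.head.forward(g, train)
        self._probs = nn.softmax(z, axis=-1)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        dcat = self.fuse.backward(d)
        du, dskip = dcat[..., :self._f], dcat[..., self._f:]
        dp = self.up.backward(du)
        for b in reversed(self.level2):
            dp = b.backward(dp)
        dh = self.pool.backward(dp) + dskip
        for b in reversed(self.level1):
            dh = b.backward(dh)
        dx = self.stem.backward(dh)
        if self.ablate == "image":
            dx[..., -1] = 0.0
        elif self.ablate == "masks":
            dx[..., :-1] = 0.0
        return dx

    def stack_input(self, masks: OARMaskSet, image: ImageSlice) -> np.ndarray:
        """Assemble the (1, H, W, K+1) input with the image as final channel."""
        if masks.n_channels != self.spec.in_channels - 1:
            raise ShapeError(
                f"mask set has {masks.n_channels} channels; "
                f"discriminator expects {self.spec.in_channels - 1}")
        if masks.shape != image.shape:
            raise ShapeError("masks and image differ in shape")
        stack = np.concatenate(
            [masks.channels.transpose(1, 2, 0).astype(nn.DTYPE),
             image.values[:, :, None]], axis=-1)
        return stack[None]

    def predict(self, masks: OARMaskSet, image: ImageSlice) -> ConfidenceMap:
        """Evaluation-mode confidence estimate for one (segmentation, image)."""
        probs = self.forward(self.stack_input(masks, image), train=False)
        return ConfidenceMap(probs[0, :, :, 1])


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> UResNetDiscriminator:
    return UResNetDiscriminator(spec, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Save a model to a versioned ``.npz`` checkpoint."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": model.kind,
        "spec": asdict(model.spec),
        "ablate": getattr(model, "ablate", None),
    }
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path):
    """Load a generator or discriminator from a checkpoint."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        keys = sorted(k for k in data.files if k.startswith("arr_"))
        arrays = [data[k] for k in keys]
    if meta["kind"] == "generator":
        model = UNetGenerator(GeneratorSpec(**meta["spec"]))
    elif meta["kind"] == "discriminator":
        model = UResNetDiscriminator(DiscriminatorSpec(**meta["spec"]))
        model.ablate = meta.get("ablate")
    else:
        raise ValueError(f"unknown model kind {meta['kind']!r}")
    model.load_state_arrays(arrays)
    return model
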