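"""Alternating adversarial training of the segmentation generator and the
confidence discriminator, plus inference entry points.

Each batch performs exactly one discriminator and one generator update:

1. the generator segments the batch images (softmax, then argmax-binarized);
   optionally the binarized predictions are corrupted with synthetic errors;
2. the discriminator takes one combined step on gold-standard inputs
   (labelled all-correct, d2GS = 0 everywhere) *and* on the generated /
   corrupted predictions (labelled with their computed d2GS), with focal
   loss;
3. the generator takes one step on
   ``L_gen = alpha * FL_G + beta * (1 - FL_D)`` where FL_D is the
   discriminator's focal loss on the (uncorrupted) generated sample —
   minimizing L_gen maximizes FL_D, the min-max adversarial coupling.
   The binarization feeding the discriminator is not differentiable, so the
   adversarial gradient reaches the generator through a straight-through
   estimator (hard masks forward, softmax probabilities backward).

A sequential (non-adversarial) baseline and input-channel ablations are
provided for the standard control experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .errors import ErrorInjectionConfig, inject
from .losses import LossParams, focal_loss_from_probs, focal_softmax_grad
from .masks import (ImageSlice, OARMaskSet, ShapeError, SoftmaxSeg,
                    confusion_map, D2GSMask)
from .networks import (ConfidenceMap, DiscriminatorSpec, GeneratorSpec,
                       UNetGenerator, UResNetDiscriminator, build_discriminator,
                       build_generator, load_model, save_model)

__all__ = [
    "TrainConfig",
    "TrainingDivergence",
    "train",
    "train_sequential_baseline",
    "predict_confidence",
    "predict_segmentation",
    "corrupt_cases",
    "evaluate_error_detection",
]


class TrainingDivergence(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    """Training hyperparameters and toggles.

    ``ablate`` zeros the discriminator's image channel (``'image'``) or all
    mask channels (``'masks'``) at training *and* inference time; the flag
    is stored with the discriminator so inference stays consistent.
    ``val_fraction`` > 0 holds out that fraction of cases and keeps the
    weights with the best held-out error-detection MCC.
    ``epochs_discriminator`` applies only to the sequential baseline's
    second phase (``None`` reuses ``epochs``); adversarial training always
    updates both networks every batch.
    """

    epochs: int = 12
    epochs_discriminator: int | None = None
    batch_size: int = 8
    lr_generator: float = 2e-4
    lr_discriminator: float = 2e-4
    loss_params: LossParams = field(default_factory=LossParams)
    use_synthetic_errors: bool = True
    error_config: ErrorInjectionConfig = field(default_factory=ErrorInjectionConfig)
    base_filters: int = 8
    dropout_rate: float = 0.2
    ablate: str | None = None
    val_fraction: float = 0.0
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.epochs_discriminator is not None and self.epochs_discriminator < 0:
            raise ValueError("epochs_discriminator must be >= 0")
        if self.ablate not in (None, "image", "masks"):
            raise ValueError("ablate must be None, 'image' or 'masks'")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")


def _as_cases(dataset):
    """Accept an in-memory case list or a manifest path."""
    if isinstance(dataset, (str, Path)):
        from .io import load_dataset
        return load_dataset(dataset)
    return list(dataset)


def _stack_images(cases) -> np.ndarray:
    return np.stack([c[0].values for c in cases])[..., None].astype(nn.DTYPE)


def _gs_labelmaps(cases) -> np.ndarray:
    labs = []
    for _, masks in cases:
        lab = np.zeros(masks.shape, dtype=np.int64)
        for c in range(masks.n_channels):
            lab[masks.channels[c] == 1] = c + 1
        labs.append(lab)
    return np.stack(labs)


def _build_models(cases, config: TrainConfig):
    k = cases[0][1].n_channels
    gen = build_generator(
        GeneratorSpec(out_classes=k + 1, base_filters=config.base_filters,
                      dropout_rate=config.dropout_rate),
        seed=config.seed)
    disc = build_discriminator(
        DiscriminatorSpec(in_channels=k + 1, base_filters=config.base_filters),
        seed=config.seed + 1)
    disc.ablate = config.ablate
    return gen, disc


def _check_finite(name: str, value: float, epoch: int) -> None:
    if not np.isfinite(value):
        raise TrainingDivergence(
            f"{name} became non-finite ({value}) at epoch {epoch}")


def _binarize_batch(probs: np.ndarray) -> np.ndarray:
    """(N, H, W, K+1) softmax -> (N, H, W, K) hard argmax organ masks."""
    labels = probs.argmax(axis=-1)
    k = probs.shape[-1] - 1
    return np.stack([(labels == c + 1) for c in range(k)], axis=-1).astype(nn.DTYPE)


def _maybe_corrupt(hard_masks: np.ndarray, probs: np.ndarray, names,
                   config: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Inject synthetic errors per sample into binarized predictions."""
    if not config.use_synthetic_errors:
        return hard_masks
    out = np.empty_like(hard_masks)
    for i in range(hard_masks.shape[0]):
        mask_set = OARMaskSet(
            hard_masks[i].transpose(2, 0, 1).astype(np.uint8), list(names))
        seg = SoftmaxSeg(probs[i].transpose(2, 0, 1))
        cfg = replace(config.error_config, seed=int(rng.integers(2 ** 31)))
        corrupted, _ = inject(mask_set, seg, cfg)
        out[i] = corrupted.channels.transpose(1, 2, 0).astype(nn.DTYPE)
    return out


def _disc_step(disc, opt_d, images, gs_masks, gen_masks, gen_d2gs, params):
    """One combined discriminator update on GS + generated samples."""
    x_gs = np.concatenate([gs_masks, images], axis=-1)
    x_gen = np.concatenate([gen_masks, images], axis=-1)
    x = np.concatenate([x_gs, x_gen], axis=0)
    n, h, w = images.shape[0], images.shape[1], images.shape[2]
    target = np.concatenate(
        [np.zeros((n, h, w), dtype=np.int64), gen_d2gs.astype(np.int64)], axis=0)
    probs = disc.forward(x, train=True)
    fl_d = focal_loss_from_probs(probs, target, params)
    disc.backward(focal_softmax_grad(probs, target, params))
    opt_d.step()
    return fl_d


def _gen_adversarial_grad(disc, images, hard_masks, d2gs, gen_probs, params):
    """Adversarial gradient w.r.t. generator logits via straight-through.

    Returns (fl_d_on_generated, dlogits of +FL_D). The caller subtracts
    beta times this gradient (L_gen carries 1 - FL_D).
    """
    x = np.concatenate([hard_masks, images], axis=-1)
    probs_d = disc.forward(x, train=False)
    fl_d_gen = focal_loss_from_probs(probs_d, d2gs.astype(np.int64), params)
    dx = disc.backward(focal_softmax_grad(probs_d, d2gs.astype(np.int64), params))
    disc.zero_grad()  # discriminator parameters are not updated here
    k = hard_masks.shape[-1]
    dprobs = np.zeros_like(gen_probs)
    dprobs[..., 1:k + 1] = dx[..., :k]  # straight-through past the argmax
    dz = nn.softmax_backward(gen_probs, dprobs)
    return fl_d_gen, dz


def _val_mcc(disc, val_corrupted, threshold: float = 0.5) -> float:
    """Pooled error-detection MCC over held-out corrupted cases."""
    tp = tn = fp = fn = 0
    for image, pred_seg, gs_seg in val_corrupted:
        conf = disc.predict(pred_seg, image)
        pred = conf.binarize(threshold).astype(bool)
        from .masks import compute_d2gs
        ref = compute_d2gs(pred_seg, gs_seg).values.astype(bool)
        tp += int(np.sum(pred & ref))
        tn += int(np.sum(~pred & ~ref))
        fp += int(np.sum(pred & ~ref))
        fn += int(np.sum(~pred & ref))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else float("nan")


def _split_validation(cases, config: TrainConfig):
    n_val = int(round(config.val_fraction * len(cases)))
    if n_val == 0:
        return cases, []
    return cases[:-n_val], cases[-n_val:]


def train(dataset, config: TrainConfig):
    """Adversarial training; returns ``(generator, discriminator, history)``.

    ``dataset`` is a manifest path or a sequence of (ImageSlice, OARMaskSet)
    pairs with gold-standard masks. With ``epochs=0`` the freshly
    initialized models and an empty history are returned.
    """
    cases = _as_cases(dataset)
    if not cases:
        raise ValueError("dataset is empty")
    train_cases, val_cases = _split_validation(cases, config)
    gen, disc = _build_models(cases, config)
    history = {"fl_g": [], "fl_d": [], "fl_d_gen": [], "l_gen": [], "val_mcc": []}
    if config.epochs == 0:
        return gen, disc, history

    params = config.loss_params
    rng = np.random.default_rng(config.seed)
    images_all = _stack_images(train_cases)
    labels_all = _gs_labelmaps(train_cases)
    gs_masks_all = np.stack(
        [c[1].channels.transpose(1, 2, 0) for c in train_cases]).astype(nn.DTYPE)
    names = train_cases[0][1].names
    opt_g = nn.Adam(gen.params(), lr=config.lr_generator)
    opt_d = nn.Adam(disc.params(), lr=config.lr_discriminator)

    val_corrupted = corrupt_cases(val_cases, config.error_config,
                                  seed=config.seed + 9973) if val_cases else []
    best = {"mcc": -np.inf, "gen": None, "disc": None}

    n = len(train_cases)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep = {"fl_g": [], "fl_d": [], "fl_d_gen": [], "l_gen": []}
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            images = images_all[idx]
            gs_labels = labels_all[idx]
            gs_masks = gs_masks_all[idx]

            # (1) generate and optionally corrupt
            probs = gen.forward(images, train=True)
            hard = _binarize_batch(probs)
            disc_input_masks = _maybe_corrupt(hard, probs, names, config, rng)
            d2gs_corr = (np.abs(disc_input_masks - gs_masks)).max(axis=-1) > 0.5

            # (2) one discriminator update on GS + generated samples
            fl_d = _disc_step(disc, opt_d, images, gs_masks, disc_input_masks,
                              d2gs_corr, params)

            # (3) one generator update
            fl_g = focal_loss_from_probs(probs, gs_labels, params)
            dz_sup = focal_softmax_grad(probs, gs_labels, params)
            d2gs_gen = (np.abs(hard - gs_masks)).max(axis=-1) > 0.5
            fl_d_gen, dz_adv = _gen_adversarial_grad(
                disc, images, hard, d2gs_gen, probs, params)
            l_gen = params.alpha * fl_g + params.beta * (1.0 - fl_d_gen)
            gen.backward(params.alpha * dz_sup - params.beta * dz_adv)
            opt_g.step()

            for k, v in (("fl_g", fl_g), ("fl_d", fl_d),
                         ("fl_d_gen", fl_d_gen), ("l_gen", l_gen)):
                _check_finite(k, v, epoch)
                ep[k].append(v)

        for k in ep:
            history[k].append(float(np.mean(ep[k])))
        if val_corrupted:
            mcc = _val_mcc(disc, val_corrupted)
            history["val_mcc"].append(float(mcc))
            if np.isfinite(mcc) and mcc > best["mcc"]:
                best.update(mcc=mcc, gen=gen.state_arrays(),
                            disc=disc.state_arrays())
                best["gen"] = [a.copy() for a in best["gen"]]
                best["disc"] = [a.copy() for a in best["disc"]]

    if best["gen"] is not None:
        gen.load_state_arrays(best["gen"])
        disc.load_state_arrays(best["disc"])

    if config.checkpoint_dir:
        ckdir = Path(config.checkpoint_dir)
        ckdir.mkdir(parents=True, exist_ok=True)
        save_model(gen, ckdir / "generator.npz")
        save_model(disc, ckdir / "discriminator.npz")
    return gen, disc, history


def train_sequential_baseline(dataset, config: TrainConfig):
    """Non-adversarial control: generator first, then the discriminator.

    The generator is trained to convergence with the supervised focal loss
    alone, then frozen; the discriminator is subsequently trained on the
    frozen generator's own outputs (no synthetic errors, no adversarial
    pressure). Serves as the ablation comparator for adversarial training.
    """
    cases = _as_cases(dataset)
    if not cases:
        raise ValueError("dataset is empty")
    train_cases, val_cases = _split_validation(cases, config)
    gen, disc = _build_models(cases, config)
    params = config.loss_params
    rng = np.random.default_rng(config.seed)
    images_all = _stack_images(train_cases)
    labels_all = _gs_labelmaps(train_cases)
    gs_masks_all = np.stack(
        [c[1].channels.transpose(1, 2, 0) for c in train_cases]).astype(nn.DTYPE)
    opt_g = nn.Adam(gen.params(), lr=config.lr_generator)
    history = {"fl_g": [], "fl_d": [], "val_mcc": []}
    n = len(train_cases)

    # phase 1: supervised generator only
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = gen.forward(images_all[idx], train=True)
            fl_g = focal_loss_from_probs(probs, labels_all[idx], params)
            _check_finite("fl_g", fl_g, epoch)
            gen.backward(focal_softmax_grad(probs, labels_all[idx], params))
            opt_g.step()
            losses.append(fl_g)
        history["fl_g"].append(float(np.mean(losses)))

    # phase 2: discriminator on the frozen generator's outputs
    opt_d = nn.Adam(disc.params(), lr=config.lr_discriminator)
    val_corrupted = corrupt_cases(val_cases, config.error_config,
                                  seed=config.seed + 9973) if val_cases else []
    best = {"mcc": -np.inf, "disc": None}
    n_disc_epochs = (config.epochs_discriminator
                     if config.epochs_discriminator is not None
                     else config.epochs)
    for epoch in range(n_disc_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            images = images_all[idx]
            probs = gen.forward(images, train=False)
            hard = _binarize_batch(probs)
            d2gs = (np.abs(hard - gs_masks_all[idx])).max(axis=-1) > 0.5
            fl_d = _disc_step(disc, opt_d, images, gs_masks_all[idx], hard,
                              d2gs, params)
            _check_finite("fl_d", fl_d, epoch)
            losses.append(fl_d)
        history["fl_d"].append(float(np.mean(losses)))
        if val_corrupted:
            mcc = _val_mcc(disc, val_corrupted)
            history["val_mcc"].append(float(mcc))
            if np.isfinite(mcc) and mcc > best["mcc"]:
                best.update(mcc=mcc, disc=[a.copy() for a in disc.state_arrays()])
    if best["disc"] is not None:
        disc.load_state_arrays(best["disc"])
    return gen, disc, history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_confidence(image: ImageSlice, seg: OARMaskSet,
                       discriminator) -> ConfidenceMap:
    """Confidence estimate for a segmentation from *any* source.

    No gold standard is needed; the discriminator judges the
    (masks..., image) stack alone. ``discriminator`` may be a model or a
    checkpoint path.
    """
    if isinstance(discriminator, (str, Path)):
        discriminator = load_model(discriminator)
    if not isinstance(discriminator, UResNetDiscriminator):
        raise TypeError("expected a discriminator model or checkpoint")
    return discriminator.predict(seg, image)


def predict_segmentation(image: ImageSlice, generator) -> SoftmaxSeg:
    """Softmax segmentation of one slice from trained generator weights."""
    if isinstance(generator, (str, Path)):
        generator = load_model(generator)
    if not isinstance(generator, UNetGenerator):
        raise TypeError("expected a generator model or checkpoint")
    return generator.predict(image)


# ---------------------------------------------------------------------------
# error-detection benchmarking helpers
# ---------------------------------------------------------------------------

def corrupt_cases(cases, error_config: ErrorInjectionConfig, seed: int):
    """Emulate an external segmentation model on held-out cases.

    Corrupts each case's gold-standard masks with geometric and removal
    errors (class perturbation needs a softmax, which external masks lack)
    and returns (image, corrupted_seg, gold_seg) triples.
    """
    from .phantom import slice_seeds
    seeds = slice_seeds(seed, len(cases))
    out = []
    for (image, gs), s in zip(cases, seeds):
        cfg = replace(error_config, p_class_perturb=0.0, seed=int(s))
        corrupted, _ = inject(gs, None, cfg)
        out.append((image, corrupted, gs))
    return out


def evaluate_error_detection(discriminator, corrupted_cases, options=None):
    """Score a discriminator's error maps against d2GS on corrupted cases.

    Returns (per_case_results, summary); the summary holds nan-excluded
    means of the overall MCC/FPR/FNR plus the count of defined cases.
    """
    from .evaluation import EvalOptions, evaluate_case

    options = options or EvalOptions()
    per_case = []
    for image, pred_seg, gs_seg in corrupted_cases:
        conf = predict_confidence(image, pred_seg, discriminator)
        per_case.append(evaluate_case(conf, pred_seg, gs_seg, options))
    mccs = np.array([r["overall"].mcc for r in per_case])
    fprs = np.array([r["overall"].fpr for r in per_case])
    fnrs = np.array([r["overall"].fnr for r in per_case])
    defined = np.isfinite(mccs)
    summary = {
        "mean_mcc": float(np.nanmean(mccs)) if defined.any() else float("nan"),
        "mean_fpr": float(np.nanmean(fprs)) if np.isfinite(fprs).any() else float("nan"),
        "mean_fnr": float(np.nanmean(fnrs)) if np.isfinite(fnrs).any() else float("nan"),
        "n_defined": int(defined.sum()),
        "n_cases": len(per_case),
    }
    return per_case, summary
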