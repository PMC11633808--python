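"""Confusion-count metrics, per-organ reporting and four-colour maps.

All metrics compare the *predicted error map* (the thresholded confidence
map) against the d2GS gold-standard error map — not segmentations against
each other. The positive class is the error voxel.

Degenerate denominators yield ``nan`` (the undefined marker); averages over
cases exclude undefined records, mirroring how tiny structures with no
error voxels would otherwise poison summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import (ConfusionMap, D2GSMask, ImageSlice, OARMaskSet, ShapeError,
                    TP, TN, FP, FN, compute_d2gs, confusion_counts, confusion_map,
                    dsc)
from .networks import ConfidenceMap
from .postprocess import GDCParams, IERParams, geometric_distance_correction, \
    intelligent_edge_removal

__all__ = [
    "MetricRecord",
    "EvalOptions",
    "compute_metrics",
    "evaluate_case",
    "evaluate_all_configurations",
    "render_four_colour_map",
    "records_to_frame",
]

CONFIGURATIONS = ("baseline", "ier", "gdc", "ier_gdc")


@dataclass
class MetricRecord:
    """Voxel counts and derived scores for one evaluation unit."""

    tp: int
    tn: int
    fp: int
    fn: int
    mcc: float = field(init=False)
    fpr: float = field(init=False)
    fnr: float = field(init=False)
    fp_fn_ratio: float = field(init=False)
    dsc: float = math.nan

    def __post_init__(self) -> None:
        tp, tn, fp, fn = self.tp, self.tn, self.fp, self.fn
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        self.mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else math.nan
        self.fpr = fp / (fp + tn) if (fp + tn) > 0 else math.nan
        self.fnr = fn / (fn + tp) if (fn + tp) > 0 else math.nan
        self.fp_fn_ratio = fp / fn if fn > 0 else math.nan

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalOptions:
    """Pipeline switches for :func:`evaluate_case`.

    ``per_oar_margin`` bounds the per-organ evaluation region: the union of
    the organ's predicted and gold-standard masks dilated by this Euclidean
    radius (keeps true-negative counts local so class imbalance stays
    comparable across organ sizes). ``None`` evaluates the whole slice.
    """

    ier: bool = False
    gdc: bool = False
    threshold: float = 0.5
    ier_params: IERParams = field(default_factory=IERParams)
    gdc_params: GDCParams = field(default_factory=GDCParams)
    per_oar_margin: float | None = 10.0


def compute_metrics(cm: ConfusionMap, region: np.ndarray | None = None,
                    seg_dsc: float = math.nan) -> MetricRecord:
    """MCC, FPR, FNR and FP/FN from a confusion map (optionally regional)."""
    tp, tn, fp, fn = confusion_counts(cm, region)
    rec = MetricRecord(tp, tn, fp, fn)
    rec.dsc = seg_dsc
    return rec


def _pipeline(pred_error: np.ndarray, reference: D2GSMask, seg: OARMaskSet,
              options: EvalOptions) -> ConfusionMap:
    """binarized error map + reference -> (IER) -> confusion -> (GDC)."""
    err = pred_error
    ref = reference
    if options.ier:
        err = intelligent_edge_removal(err, seg, options.ier_params)
        ref = D2GSMask(intelligent_edge_removal(ref.values, seg, options.ier_params))
    cm = confusion_map(err, ref)
    if options.gdc:
        cm = geometric_distance_correction(cm, options.gdc_params)
    return cm


def evaluate_case(conf: ConfidenceMap, pred_seg: OARMaskSet, gs_seg: OARMaskSet,
                  options: EvalOptions | None = None) -> dict[str, MetricRecord]:
    """Score one case overall and per organ.

    The confidence map is binarized at ``options.threshold``; the overall
    record uses the full-slice d2GS, each per-organ record that organ's
    single-channel difference within its local evaluation region. Per-organ
    records also carry the segmentation Dice for context.
    """
    options = options or EvalOptions()
    if conf.shape != pred_seg.shape or pred_seg.shape != gs_seg.shape:
        raise ShapeError("confidence map, prediction and gold standard must align")
    if pred_seg.n_channels != gs_seg.n_channels:
        raise ShapeError("prediction and gold standard differ in channel count")

    pred_error = conf.binarize(options.threshold)
    results: dict[str, MetricRecord] = {}

    overall_ref = compute_d2gs(pred_seg, gs_seg)
    results["overall"] = compute_metrics(
        _pipeline(pred_error, overall_ref, pred_seg, options))

    for c, name in enumerate(gs_seg.names):
        ref_c = D2GSMask(np.abs(pred_seg.channels[c].astype(np.int16)
                                - gs_seg.channels[c].astype(np.int16)).astype(np.uint8))
        cm = _pipeline(pred_error, ref_c, pred_seg, options)
        region = None
        if options.per_oar_margin is not None:
            union = (pred_seg.channels[c] | gs_seg.channels[c]).astype(bool)
            if union.any():
                region = ndimage.distance_transform_edt(~union) <= options.per_oar_margin
            else:
                region = union  # empty organ: empty region, all counts zero
        results[name] = compute_metrics(
            cm, region, seg_dsc=dsc(pred_seg.channels[c], gs_seg.channels[c]))
    return results


def evaluate_all_configurations(conf, pred_seg, gs_seg,
                                options: EvalOptions | None = None):
    """Run baseline, IER-only, GDC-only and IER+GDC, mirroring the usual
    pre/post-correction comparison. Returns {configuration: results}."""
    base = options or EvalOptions()
    out = {}
    for name in CONFIGURATIONS:
        opts = EvalOptions(ier="ier" in name, gdc="gdc" in name,
                           threshold=base.threshold, ier_params=base.ier_params,
                           gdc_params=base.gdc_params,
                           per_oar_margin=base.per_oar_margin)
        out[name] = evaluate_case(conf, pred_seg, gs_seg, opts)
    return out


# four-colour map palette (RGB, 0-255)
_COLOURS = {
    TP: (0, 200, 0),        # green
    FP: (255, 105, 180),    # pink
    FN: (30, 100, 255),     # blue (the fourth colour; only three are canonical)
}
_GDC_COLOUR = (255, 220, 0)  # yellow


def render_four_colour_map(cm: ConfusionMap, image: ImageSlice) -> np.ndarray:
    """Overlay TP (green), FP (pink), FN (blue) and GDC-modified (yellow)
    voxels on the grayscale slice. TN voxels stay grayscale; every labelled
    voxel gets exactly one colour, GDC-modified taking precedence."""
    if cm.shape != image.shape:
        raise ShapeError("confusion map and image must share shape")
    gray = np.round(image.values * 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for code, colour in _COLOURS.items():
        rgb[cm.labels == code] = colour
    rgb[cm.gdc_modified] = _GDC_COLOUR
    return rgb


def records_to_frame(per_case: list[dict]):
    """Tidy frame (case, oar, configuration, metric, value) from nested
    {configuration: {unit: MetricRecord}} dicts, one per case."""
    import pandas as pd

    rows = []
    for case_idx, configs in enumerate(per_case):
        for config_name, units in configs.items():
            for unit, rec in units.items():
                for metric in ("tp", "tn", "fp", "fn", "mcc", "fpr", "fnr",
                               "fp_fn_ratio", "dsc"):
                    rows.append({"case": case_idx, "oar": unit,
                                 "configuration": config_name, "metric": metric,
                                 "value": getattr(rec, metric)})
    return pd.DataFrame(rows)
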