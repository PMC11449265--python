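"""Classification, weakly-supervised segmentation, and compute accounting.

Classification is scored as ROC AUC at two granularities: per image, and
grouped — predictions averaged within a group of views of the same
subject before scoring (the way paired screening views of one breast are
combined).  Localization is scored against voxel ground truth with the
Dice similarity coefficient and pixel average precision (PxAP), both
computed after max-projecting saliency and truth along depth so scores
are comparable across stacks with different slice counts.  Compute is
accounted analytically in multiply-accumulate operations (MACs) without
executing any network.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.measure import block_reduce
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["EvalRecord", "auc", "grouped_auc", "max_project", "dice", "pxap",
           "downsample_mask", "dice_sweep", "count_macs", "patch_coverage",
           "bootstrap_ci", "operating_point"]


@dataclasses.dataclass(frozen=True)
class EvalRecord:
    id: str
    group_id: int
    scores: tuple[float, float]
    labels: tuple[int, int]


def auc(scores, labels) -> float:
    """ROC AUC; equals the normalized Mann-Whitney U with ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def grouped_auc(records: list[EvalRecord], class_index: int = 1) -> float:
    """AUC on within-group mean scores (one point per group)."""
    groups: dict[int, list[EvalRecord]] = {}
    for r in records:
        groups.setdefault(r.group_id, []).append(r)
    scores, labels = [], []
    for gid, rs in sorted(groups.items()):
        lab = {r.labels[class_index] for r in rs}
        if len(lab) > 1:
            raise ValueError(f"group {gid} has inconsistent labels")
        scores.append(np.mean([r.scores[class_index] for r in rs]))
        labels.append(lab.pop())
    return auc(scores, labels)


def max_project(plane: np.ndarray) -> np.ndarray:
    """Collapse an (h, w, D) stack to (h, w) by elementwise max over depth."""
    plane = np.asarray(plane)
    if plane.ndim != 3 or plane.shape[2] < 1:
        raise ValueError(f"expected (h, w, D) with D >= 1, got {plane.shape}")
    return plane.max(axis=2)


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Dice similarity 2|P & T| / (|P| + |T|); truth must be non-empty."""
    p = np.asarray(pred_mask, dtype=bool)
    t = np.asarray(truth_mask, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("empty truth mask; exclude such records upstream")
    denom = p.sum() + t.sum()
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def pxap(saliency_plane: np.ndarray, truth_mask: np.ndarray) -> float:
    """Pixel average precision of the saliency ranking against binary truth.

    Step-wise exact AP: the precision-recall curve is evaluated at every
    distinct score, with tied scores grouped.
    """
    s = np.asarray(saliency_plane, dtype=float).ravel()
    t = np.asarray(truth_mask).astype(bool).ravel()
    if s.shape != t.shape:
        raise ValueError("saliency and truth must have the same number of pixels")
    if not t.any():
        raise ValueError("empty truth mask; exclude such records upstream")
    return float(average_precision_score(t, s))


def downsample_mask(truth_mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-max downsampling of a (H, W[, D]) mask to the saliency grid:
    any truth voxel inside a block marks the cell (small objects survive)."""
    block = (factor, factor) + (1,) * (truth_mask.ndim - 2)
    return block_reduce(np.asarray(truth_mask), block, np.max)


def dice_sweep(saliency_2d: np.ndarray, truth_2d: np.ndarray,
               thresholds: np.ndarray | None = None) -> dict:
    """Dice over a fixed threshold sweep on min-max normalized saliency.

    Returns the full sweep plus the best threshold and its Dice.  Used
    because the projected saliency has no canonical calibration; the
    sweep is deterministic and logged in full.
    """
    from .retrieval import minmax_normalize

    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.951, 0.05), 2)
    norm = minmax_normalize(saliency_2d)
    sweep = {float(th): dice(norm >= th, truth_2d) for th in thresholds}
    best_th = max(sweep, key=sweep.get)
    return {"sweep": sweep, "best_threshold": best_th, "best_dice": sweep[best_th]}


# -- analytic compute accounting -----------------------------------------------------


def count_macs(layer_spec: list[dict], input_shape: tuple) -> int:
    """Analytic multiply-accumulate count for a feed-forward layer stack.

    ``layer_spec`` entries: {"type": "conv2d"|"conv3d", "c_out", "kernel",
    "stride" (default 1), "padding" (default 0)} or {"type": "linear",
    "c_in", "c_out"}.  ``input_shape`` is (C, H, W) or (C, H, W, D) for
    convolutional stacks; shapes are propagated, nothing is executed.
    """
    shape = tuple(input_shape)
    total = 0
    for layer in layer_spec:
        kind = layer["type"]
        if kind in ("conv2d", "conv3d"):
            nd = 2 if kind == "conv2d" else 3
            if len(shape) != nd + 1:
                raise ValueError(f"{kind} expects a {nd + 1}-D input shape, "
                                 f"got {shape}")
            c_in, spatial = shape[0], shape[1:]
            kernel = layer["kernel"]
            kernel = (kernel,) * nd if np.isscalar(kernel) else tuple(kernel)
            stride = layer.get("stride", 1)
            stride = (stride,) * nd if np.isscalar(stride) else tuple(stride)
            padding = layer.get("padding", 0)
            padding = (padding,) * nd if np.isscalar(padding) else tuple(padding)
            out_spatial = tuple(
                (s + 2 * p - k) // st + 1
                for s, k, st, p in zip(spatial, kernel, stride, padding))
            if any(s < 1 for s in out_spatial):
                raise ValueError(f"layer {layer} collapses spatial dims {spatial}")
            total += (int(np.prod(out_spatial)) * c_in * layer["c_out"]
                      * int(np.prod(kernel)))
            shape = (layer["c_out"],) + out_spatial
        elif kind == "linear":
            c_in = layer.get("c_in", shape[0] if len(shape) == 1 else None)
            if c_in is None:
                raise ValueError("linear layer needs c_in or a flat input shape")
            total += int(c_in) * int(layer["c_out"])
            shape = (layer["c_out"],)
        else:
            raise ValueError(f"unknown layer type {kind!r}")
    return total


def patch_coverage(image_shape: tuple, K: int, patch_size: tuple[int, int] = (256, 256),
                   ) -> tuple[float, float]:
    """Percent of the image processed by K patches: (raw, rounded-2dp)."""
    if any(s <= 0 for s in image_shape):
        raise ValueError("image dimensions must be positive")
    raw = 100.0 * K * patch_size[0] * patch_size[1] / float(np.prod(image_shape))
    return raw, round(raw, 2)


# -- generic utilities ----------------------------------------------------------------


def bootstrap_ci(metric_fn, scores, labels, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap CI of a metric over (scores, labels) resamples."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    point = metric_fn(scores, labels)
    stats = []
    n = len(scores)
    while len(stats) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(metric_fn(scores[idx], labels[idx]))
        except ValueError:  # single-class resample
            continue
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(point), float(lo), float(hi)


def operating_point(scores, labels, sensitivity: float | None = None,
                    specificity: float | None = None) -> dict:
    """Threshold achieving a target sensitivity or specificity, with the
    complementary rate at that threshold."""
    if (sensitivity is None) == (specificity is None):
        raise ValueError("specify exactly one of sensitivity / specificity")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores)
    s, lab = scores[order], labels[order]
    pos, neg = lab.sum(), (~lab).sum()
    tps = np.cumsum(lab)
    fps = np.cumsum(~lab)
    sens = tps / pos
    spec = 1.0 - fps / neg
    if sensitivity is not None:
        k = int(np.argmax(sens >= sensitivity))
        return {"threshold": float(s[k]), "sensitivity": float(sens[k]),
                "specificity": float(spec[k])}
    ok = np.where(spec >= specificity)[0]
    k = int(ok[-1]) if len(ok) else 0
    return {"threshold": float(s[k]), "sensitivity": float(sens[k]),
            "specificity": float(spec[k])}
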