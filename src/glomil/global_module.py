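"""Global module: per-slice features, the saliency head, and top-t% pooling.

The global stage applies a cheap 2D encoder to every slice of the stack
independently, turns the per-slice hidden representation into a two-class
saliency map through a 1x1 convolution followed by ReLU(tanh(x)), and
pools the top t% of saliency values into a per-class probability.

The pooling percentage t is defined *with respect to a single slice*:
the number of pooled cells is t/100 of one slice's (h x w) grid, so it
does not grow with the slice count D.  With t = 200% the pool covers
2*h*w cells — 4% of an (h, w, 50) map but 2.5% of an (h, w, 80) map —
while staying a fixed-size subset however many slices the stack has.

The 1x1 layer is initialized with a single positive constant ``omega``
(zero bias): whichever encoder channels respond to small salient
structures, their activation reaches the saliency map with a positive
weight, so top-t% pooling starts out pooling from genuinely active
regions rather than from whichever regions random signs happen to favor.
ReLU(tanh(x)) maps the near-zero background logits to exactly zero while
keeping its steepest slope at zero, which is what makes the constant
start workable (a sigmoid would put the background at 0.5 instead).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor
from .io import Volume
from .nn import SliceEncoder

__all__ = ["FeatureStack", "SegmentationLayer", "relu_tanh", "sigmoid",
           "init_segmentation_layer", "compute_saliency", "pooled_count",
           "aggregate_top_t", "global_predict", "extract_slice_features",
           "export_saliency"]


@dataclasses.dataclass
class FeatureStack:
    """Per-slice hidden representations, shape (D, h, w, c)."""

    values: np.ndarray
    downsample_factor: int

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError(f"feature stack must be (D, h, w, c), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature stack contains non-finite values")
        if self.values.shape[3] % 8:
            raise ValueError("channel count must be divisible by 8")


@dataclasses.dataclass
class SegmentationLayer:
    """1x1 convolution mapping c channels to 2 class logits."""

    weights: np.ndarray  # (c, 2)
    bias: np.ndarray     # (2,)

    def __post_init__(self):
        if self.weights.ndim != 2 or self.weights.shape[1] != 2:
            raise ValueError(f"weights must be (c, 2), got {self.weights.shape}")
        if self.bias.shape != (2,):
            raise ValueError(f"bias must be (2,), got {self.bias.shape}")


def relu_tanh(v):
    """max(0, tanh(v)) — maps reals to [0, 1], exactly 0 for v <= 0."""
    return np.maximum(0.0, np.tanh(v))


def sigmoid(v):
    """Logistic function; available as an alternative saliency nonlinearity."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def init_segmentation_layer(c: int, omega: float) -> SegmentationLayer:
    """Constant positive init: every weight = omega, bias = 0."""
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    return SegmentationLayer(weights=np.full((c, 2), float(omega)),
                             bias=np.zeros(2))


def compute_saliency(features: FeatureStack, layer: SegmentationLayer,
                     nonlinearity: str = "relu_tanh") -> np.ndarray:
    """Saliency map A[i, j, d, k] = f_n(sum_m h[d, i, j, m] w[m, k] + b[k]).

    Returns (h, w, D, 2) with every entry in [0, 1].
    """
    h = features.values
    if h.shape[3] != layer.weights.shape[0]:
        raise ValueError(
            f"channel mismatch: features have {h.shape[3]} channels, "
            f"segmentation layer expects {layer.weights.shape[0]}")
    logits = h @ layer.weights + layer.bias  # (D, h, w, 2)
    fn = relu_tanh if nonlinearity == "relu_tanh" else sigmoid
    return np.ascontiguousarray(np.moveaxis(fn(logits), 0, 2))  # (h, w, D, 2)


def pooled_count(h: int, w: int, depth: int, t: float) -> int:
    """Number of pooled saliency cells: round(t/100 * h * w), floored at 1,
    capped at the plane size h*w*depth.  Depends on D only through the cap.

    Rounding is half-away-from-zero so the count is stable across platforms.
    """
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    n = int(np.floor(t / 100.0 * h * w + 0.5))
    return min(max(1, n), h * w * depth)


def aggregate_top_t(class_plane: np.ndarray, t: float) -> float:
    """Mean of the top t%-of-one-slice saliency values of an (h, w, D) plane."""
    plane = np.asarray(class_plane, dtype=float)
    if plane.ndim != 3 or plane.size == 0:
        raise ValueError(f"class plane must be a non-empty (h, w, D) array, "
                         f"got shape {plane.shape}")
    h, w, depth = plane.shape
    n = pooled_count(h, w, depth, t)
    flat = plane.ravel()
    if n == flat.size:
        top = np.sort(flat)
    else:
        # partition then sort the selected block: the pooled values are
        # summed in ascending order, independent of their layout in the
        # plane, so the result is bit-identical to a full-sort reference
        top = np.sort(np.partition(flat, flat.size - n)[flat.size - n:])
    return float(top.mean())


def global_predict(saliency: np.ndarray, t: float) -> tuple[float, float]:
    """Apply top-t% pooling per class: (p_global_benign, p_global_malignant)."""
    if saliency.ndim != 4 or saliency.shape[3] != 2:
        raise ValueError(f"saliency must be (h, w, D, 2), got {saliency.shape}")
    return tuple(aggregate_top_t(saliency[..., c], t) for c in range(2))


def export_saliency(saliency: np.ndarray, path_prefix) -> list:
    """Write one NIfTI stack per class ("benign", "malignant").

    Each file holds the (h, w, D) class plane on the saliency grid; the
    grid aligns to the input image through the encoder's downsample
    factor.  Returns the written paths.
    """
    from pathlib import Path

    from .io import write_volume

    if saliency.ndim != 4 or saliency.shape[3] != 2:
        raise ValueError(f"saliency must be (h, w, D, 2), got {saliency.shape}")
    prefix = Path(path_prefix)
    paths = []
    for c, name in enumerate(("benign", "malignant")):
        path = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        write_volume(path, saliency[..., c])
        paths.append(path)
    return paths


def extract_slice_features(volume: Volume | np.ndarray,
                           backbone: SliceEncoder) -> FeatureStack:
    """Run the slice encoder on every slice independently.

    The encoder uses group normalization, so batching the D slices
    together is purely an implementation detail: each slice's features
    equal what the encoder would produce for that slice alone.
    """
    values = volume.values if isinstance(volume, Volume) else np.asarray(volume)
    if values.ndim != 3:
        raise ValueError(f"expected (H, W, D) volume, got shape {values.shape}")
    if values.shape[2] == 0:
        raise ValueError("volume has zero slices")
    if not np.isfinite(values).all():
        raise ValueError("volume contains non-finite values")
    batch = np.moveaxis(values, -1, 0)[:, np.newaxis]  # (D, 1, H, W)
    was_training = backbone.training
    backbone.eval()
    feats = backbone(Tensor(batch)).data  # (D, c, h, w)
    backbone.train(was_training)
    return FeatureStack(values=np.moveaxis(feats, 1, -1),
                        downsample_factor=backbone.downsample)
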