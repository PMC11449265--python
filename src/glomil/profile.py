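"""Analytic compute accounting for a full model configuration.

Builds the layer specifications of the configured encoders and counts
multiply-accumulates with :func:`glomil.evaluation.count_macs`.  The
global stage is per-slice, so its cost scales linearly in the slice
count D; the local stage processes K fixed-size patches, so its cost is
constant in D — the asymmetry that makes the architecture cheap on deep
stacks.
"""

from __future__ import annotations

import numpy as np

from .evaluation import count_macs
from .io import RunConfig
from .nn import _stage_widths

__all__ = ["slice_encoder_spec", "patch_encoder_spec", "model_mac_table"]


def slice_encoder_spec(cfg: RunConfig) -> list[dict]:
    """Layer stack of the per-slice encoder + 1x1 segmentation layer."""
    n_stages = int(np.log2(cfg.backbone_downsample))
    widths = _stage_widths(cfg.backbone_width, n_stages)
    spec = [{"type": "conv2d", "c_out": c, "kernel": 3, "stride": 2, "padding": 1}
            for c in widths]
    final = widths[-1]
    spec += [{"type": "conv2d", "c_out": final, "kernel": 3, "padding": 1}] * 2
    spec.append({"type": "conv2d", "c_out": 2, "kernel": 1})
    return spec


def patch_encoder_spec(cfg: RunConfig) -> list[dict]:
    """Layer stack of the patch encoder + projection + attention + head."""
    n_stages = max(1, int(np.log2(cfg.patch_size // 4)))
    widths = _stage_widths(cfg.patch_width, n_stages)
    spec = [{"type": "conv2d", "c_out": c, "kernel": 3, "stride": 2, "padding": 1}
            for c in widths]
    final = widths[-1]
    spec += [{"type": "conv2d", "c_out": final, "kernel": 3, "padding": 1}] * 2
    return spec


def model_mac_table(cfg: RunConfig, image_shape: tuple[int, int, int]) -> dict:
    """MACs per stage for one volume of shape (H, W, D)."""
    H, W, D = image_shape
    per_slice = count_macs(slice_encoder_spec(cfg), (1, H, W))
    per_patch = count_macs(patch_encoder_spec(cfg),
                           (1, cfg.patch_size, cfg.patch_size))
    S, L = cfg.feature_dim, cfg.attention_dim
    n_stages = max(1, int(np.log2(cfg.patch_size // 4)))
    final = _stage_widths(cfg.patch_width, n_stages)[-1]
    per_patch += count_macs([{"type": "linear", "c_in": final, "c_out": S}], (final,))
    attention = cfg.K * (2 * L * S + L)      # V, U gates + score per patch
    head = S * 2
    table = {
        "global (per slice)": per_slice,
        f"global x D={D} slices": per_slice * D,
        "local (per patch)": per_patch,
        f"local x K={cfg.K} patches": per_patch * cfg.K,
        "gated attention": attention,
        "local head": head,
        "total": per_slice * D + per_patch * cfg.K + attention + head,
    }
    return table
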