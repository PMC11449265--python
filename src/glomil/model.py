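"""Full two-stage network: forward pass, loss, augmentation, TTA, training.

The forward pass chains the two stages: the per-slice encoder and 1x1
segmentation head produce the saliency stack and (via top-t% pooling)
p_global; the greedy retrieval crops K full-resolution patches which the
patch encoder, gated attention and sigmoid head turn into p_local; the
final prediction is the arithmetic mean of the two.  Patch selection is
treated as a non-differentiable step: no gradient flows from the local
loss into the global stage through patch coordinates — each stage is
trained by its own binary cross-entropy term, plus an L1 sparsity
penalty on the saliency maps:

    L = sum_c [ BCE(y_c, p_local_c) + BCE(y_c, p_global_c) + beta * |A_c|_1 ]

The two BCE terms are kept separate on purpose: a single BCE on the
averaged prediction lets one stage free-ride on the other (a constant
output from one module can be compensated by the other), which the
separate terms rule out.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import zoom as _ndzoom

from . import evaluation
from .autodiff import Adam, Tensor, conv2d, topk_mean
from .global_module import pooled_count
from .io import RunConfig, Volume
from .nn import Module, PatchEncoder, SliceEncoder
from .retrieval import (PatchLocation, RetrievalConfig, combine_class_maps,
                        extract_patch, retrieve_roi_from_3d_image)

__all__ = ["ModelOutput", "GlobalLocalNet", "saliency_l1", "bce", "total_loss",
           "augment", "tta_predict", "train"]

_EPS = 1e-7  # probability clamp inside the BCE


@dataclasses.dataclass
class ModelOutput:
    p_global: np.ndarray          # (2,) probabilities (benign, malignant)
    p_local: np.ndarray           # (2,)
    p_final: np.ndarray           # (2,) elementwise mean of the two
    saliency: np.ndarray          # (h, w, D, 2) in [0, 1]
    locations: list[PatchLocation]
    alpha: np.ndarray             # (K,) attention weights


class GlobalLocalNet(Module):
    """The assembled two-stage classifier (all learnable state lives here)."""

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        self.backbone = SliceEncoder(config.backbone_width,
                                     config.backbone_downsample, rng=rng)
        c = self.backbone.out_channels
        # constant positive init of the 1x1 segmentation layer, zero bias
        self.seg_weight = Tensor(np.full((2, c, 1, 1), config.omega),
                                 requires_grad=True)
        self.seg_bias = Tensor(np.zeros(2), requires_grad=True)
        self.patch_encoder = PatchEncoder(config.patch_size, config.patch_width,
                                          config.feature_dim, rng=rng)
        S, L = config.feature_dim, config.attention_dim
        self.att_w = Tensor(rng.normal(0, 1 / np.sqrt(L), (L, 1)), requires_grad=True)
        self.att_V = Tensor(rng.normal(0, 1 / np.sqrt(S), (L, S)), requires_grad=True)
        self.att_U = Tensor(rng.normal(0, 1 / np.sqrt(S), (L, S)), requires_grad=True)
        self.head_w = Tensor(rng.normal(0, 1 / np.sqrt(S), (S, 2)), requires_grad=True)

    # -- pieces ----------------------------------------------------------------
    def saliency_tensor(self, volume_values: np.ndarray) -> Tensor:
        """(H, W, D) -> differentiable saliency stack (D, 2, h, w)."""
        batch = np.moveaxis(volume_values, -1, 0)[:, np.newaxis]
        feats = self.backbone(Tensor(np.asarray(batch, dtype=np.float64)))
        logits = conv2d(feats, self.seg_weight, self.seg_bias)
        if self.config.saliency_nonlinearity == "relu_tanh":
            return logits.tanh().relu()
        return logits.sigmoid()

    def global_probability(self, saliency: Tensor, class_index: int) -> Tensor:
        d, _, h, w = saliency.shape
        n = pooled_count(h, w, d, self.config.t)
        return topk_mean(saliency[:, class_index], n)

    def local_probability(self, patches: np.ndarray) -> tuple[Tensor, np.ndarray]:
        """(K, p, p) patches -> (sigmoid probabilities (2,), attention (K,))."""
        x = Tensor(np.asarray(patches, dtype=np.float64)[:, np.newaxis])
        feats = self.patch_encoder(x)                       # (K, S)
        gate = (self.att_V @ feats.transpose(1, 0)).tanh() \
            * (self.att_U @ feats.transpose(1, 0)).sigmoid()
        scores = (self.att_w.transpose(1, 0) @ gate).reshape(-1)  # (K,)
        shifted = scores - float(scores.data.max())
        e = shifted.exp()
        alpha = e / e.sum()
        z = alpha.reshape(1, -1) @ feats                    # (1, S)
        p = (z @ self.head_w).reshape(-1).sigmoid()         # (2,)
        return p, alpha.data.copy()

    # -- full pass ----------------------------------------------------------------
    def forward(self, volume: Volume | np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                ) -> tuple[ModelOutput, dict]:
        """Run the pipeline; returns the output plus the differentiable nodes.

        The second element maps {"p_global": [Tensor, Tensor],
        "p_local": Tensor, "saliency": Tensor} for use by the loss.
        """
        values = volume.values if isinstance(volume, Volume) else np.asarray(volume)
        if values.ndim != 3 or values.shape[2] == 0:
            raise ValueError(f"expected a (H, W, D) volume, got {values.shape}")
        self.train(training)
        sal = self.saliency_tensor(values)                  # (D, 2, h, w)
        pg = [self.global_probability(sal, c) for c in range(2)]

        sal_np = np.moveaxis(sal.data, (0, 1), (2, 3))      # (h, w, D, 2)
        rcfg = RetrievalConfig(K=self.config.K, zeta=self.config.zeta,
                               patch_size=(self.config.patch_size,) * 2)
        locations = retrieve_roi_from_3d_image(
            sal_np, rcfg, values.shape, training=training, rng=rng)
        patches = np.stack([extract_patch(values, loc) for loc in locations])
        pl, alpha = self.local_probability(patches)

        p_global = np.array([t.item() for t in pg])
        p_local = pl.data.copy()
        out = ModelOutput(p_global=p_global, p_local=p_local,
                          p_final=(p_global + p_local) / 2.0,
                          saliency=sal_np, locations=locations, alpha=alpha)
        return out, {"p_global": pg, "p_local": pl, "saliency": sal}

    def loss_tensor(self, y: tuple[int, int], nodes: dict) -> Tensor:
        """Differentiable training loss for one volume."""
        _check_labels(y)
        loss = None
        for c in range(2):
            for p in (nodes["p_local"][c], nodes["p_global"][c]):
                term = _bce_tensor(y[c], p)
                loss = term if loss is None else loss + term
        reg = nodes["saliency"].sum() * self.config.beta
        return loss + reg

    def predict(self, volume, rng: np.random.Generator | None = None) -> ModelOutput:
        out, _ = self.forward(volume, training=False, rng=rng)
        return out


def _check_labels(y):
    if any(int(v) not in (0, 1) for v in y):
        raise ValueError(f"labels must be in {{0, 1}}, got {y}")


def _bce_tensor(y: int, p: Tensor) -> Tensor:
    pc = p.clip(_EPS, 1.0 - _EPS)
    if int(y) == 1:
        return -pc.log()
    return -(1.0 - pc).log()


# -- numpy-facing loss API ------------------------------------------------------------


def saliency_l1(class_plane: np.ndarray) -> float:
    """L1 mass of one class's saliency plane (entries are >= 0)."""
    return float(np.abs(np.asarray(class_plane, dtype=float)).sum())


def bce(y: int, p: float) -> float:
    p = min(max(float(p), _EPS), 1.0 - _EPS)
    return -np.log(p) if int(y) == 1 else -np.log(1.0 - p)


def total_loss(y: tuple[int, int], output: ModelOutput, beta: float) -> float:
    """Per-class BCE on the local and global predictions, kept separate,
    plus beta times the saliency L1 — evaluated from a ModelOutput."""
    _check_labels(y)
    loss = 0.0
    for c in range(2):
        loss += bce(y[c], output.p_local[c]) + bce(y[c], output.p_global[c])
        loss += beta * saliency_l1(output.saliency[..., c])
    return loss


# -- augmentation and test-time averaging ----------------------------------------------


def augment(volume: np.ndarray, rng: np.random.Generator, max_shift: int,
            max_rescale: float = 0.0) -> np.ndarray:
    """Random integer shift (zero padding) and mild rescale, identical on
    every slice.  ``max_shift = 0`` and ``max_rescale = 0`` is the identity."""
    values = np.asarray(volume)
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    h, w, _ = values.shape
    if max_rescale > 0:
        s = float(rng.uniform(1.0 - max_rescale, 1.0 + max_rescale))
        if abs(s - 1.0) > 1e-9:
            values = _rescale_stack(values, s)
    dr = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    dc = int(rng.integers(-max_shift, max_shift + 1)) if max_shift else 0
    return _shift_stack(values, dr, dc)


def _shift_stack(values: np.ndarray, dr: int, dc: int) -> np.ndarray:
    if dr == 0 and dc == 0:
        return values.copy()
    h, w, _ = values.shape
    out = np.zeros_like(values)
    rs, re = max(dr, 0), min(h + dr, h)
    cs, ce = max(dc, 0), min(w + dc, w)
    out[rs:re, cs:ce] = values[rs - dr:re - dr, cs - dc:ce - dc]
    return out


def _rescale_stack(values: np.ndarray, s: float) -> np.ndarray:
    h, w, d = values.shape
    scaled = _ndzoom(values, (s, s, 1.0), order=1)
    out = np.zeros_like(values)
    sh, sw = scaled.shape[:2]
    # center crop or zero-pad back to (h, w)
    r0, c0 = max(0, (sh - h) // 2), max(0, (sw - w) // 2)
    rr, cc = min(h, sh), min(w, sw)
    t0, l0 = (h - rr) // 2, (w - cc) // 2
    out[t0:t0 + rr, l0:l0 + cc] = scaled[r0:r0 + rr, c0:c0 + cc]
    return out


def tta_predict(volume, net: GlobalLocalNet, n_aug: int,
                rng: np.random.Generator, max_shift: int | None = None,
                max_rescale: float | None = None) -> np.ndarray:
    """Mean p_final over ``n_aug`` randomly augmented evaluation passes."""
    if n_aug < 1:
        raise ValueError("n_aug must be >= 1")
    values = volume.values if isinstance(volume, Volume) else np.asarray(volume)
    if max_shift is None:
        max_shift = net.config.max_shift
    if max_rescale is None:
        max_rescale = net.config.max_rescale
    preds = []
    for _ in range(n_aug):
        aug = augment(values, rng, max_shift, max_rescale)
        preds.append(net.predict(aug).p_final)
    return np.mean(preds, axis=0)


# -- training loop ---------------------------------------------------------------------


@dataclasses.dataclass
class TrainResult:
    net: GlobalLocalNet
    log: list[dict]
    best_epoch: int
    best_val_auc: float


def train(volumes: list[np.ndarray], labels: np.ndarray, splits: list[str],
          config: RunConfig, verbose: bool = False) -> TrainResult:
    """Desk-scale training loop with Adam and early stopping.

    ``volumes`` are (H, W, D) arrays, ``labels`` an (n, 2) binary array,
    ``splits`` "train"/"val" per sample.  Gradients are accumulated over
    ``config.batch_size`` volumes per update.  After each epoch the
    validation AUC for the malignant class is computed; the state with
    the best malignant AUC is kept and training stops after
    ``early_stop_patience`` epochs without improvement.  Fully
    reproducible for a given ``config.seed``.
    """
    labels = np.asarray(labels)
    train_idx = [i for i, s in enumerate(splits) if s == "train"]
    val_idx = [i for i, s in enumerate(splits) if s == "val"]
    if not train_idx or not val_idx:
        raise ValueError("need non-empty train and val splits")
    if len(np.unique(labels[val_idx, 1])) < 2:
        raise ValueError("validation split must contain both malignant classes")

    rng = np.random.default_rng(config.seed)
    net = GlobalLocalNet(config, rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)

    log: list[dict] = []
    best_auc, best_epoch, best_state = -np.inf, -1, None
    since_best = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        total, count = 0.0, 0
        opt.zero_grad()
        for j, i in enumerate(order):
            vol = augment(volumes[i], rng, config.max_shift, config.max_rescale)
            _, nodes = net.forward(vol, training=True, rng=rng)
            loss = net.loss_tensor(tuple(labels[i]), nodes)
            total += loss.item()
            count += 1
            (loss * (1.0 / config.batch_size)).backward()
            if (j + 1) % config.batch_size == 0 or j == len(order) - 1:
                opt.step()
                opt.zero_grad()
        val_scores = np.array([net.predict(volumes[i]).p_final for i in val_idx])
        auc_m = evaluation.auc(val_scores[:, 1], labels[val_idx, 1])
        auc_b = (evaluation.auc(val_scores[:, 0], labels[val_idx, 0])
                 if len(np.unique(labels[val_idx, 0])) == 2 else float("nan"))
        row = {"epoch": epoch, "train_loss": total / count,
               "val_auc_malignant": auc_m, "val_auc_benign": auc_b}
        log.append(row)
        if verbose:
            print(f"epoch {epoch}: loss {row['train_loss']:.4f} "
                  f"val AUC(m) {auc_m:.3f} AUC(b) {auc_b:.3f}")
        if auc_m > best_auc:
            best_auc, best_epoch, since_best = auc_m, epoch, 0
            best_state = net.state_dict()
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return TrainResult(net=net, log=log, best_epoch=best_epoch,
                       best_val_auc=float(best_auc))
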