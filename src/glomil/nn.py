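"""Neural-network layers and the two reference encoders.

Two encoders back the classifier:

* ``SliceEncoder`` — the low-capacity per-slice 2D encoder used by the
  global module.  It normalizes with group normalization (8 groups), so
  its statistics are computed per sample: features for a slice never
  depend on which other slices share the batch.
* ``PatchEncoder`` — the higher-capacity patch network of the local
  module, a residual stack with batch normalization over the union of
  patches in a step, ending in global average pooling and a projection
  to an S-dimensional feature vector.

Both are compact residual designs whose only contract is their
input/output geometry: the classifier never depends on their internals.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module", "Conv2d", "Linear", "GroupNorm", "BatchNorm2d",
    "ResidualBlock", "SliceEncoder", "PatchEncoder",
]


class Module:
    """Minimal parameter container with train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data.copy()
            elif isinstance(v, np.ndarray):
                state[key] = v.copy()
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for idx, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{idx}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = state[key].copy()
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = state[key].copy()
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for idx, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{idx}.")


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (c_in, c_out), c_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm(Module):
    """Group normalization over (channels-in-group, H, W), per sample."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels ({channels}) must be divisible by groups ({groups})")
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        norm = (xg - mu) / ((var + self.eps) ** 0.5)
        norm = norm.reshape(n, c, h, w)
        return norm * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class BatchNorm2d(Module):
    """Batch normalization with running statistics for evaluation mode.

    In training mode statistics are computed over the whole batch passed
    in — for the local module that batch is the union of the K patches of
    a step, which is the single-device realization of sharing statistics
    across every patch in the update.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.training:
            xt = x.transpose(1, 0, 2, 3).reshape(c, -1)
            mu = xt.mean(axis=1, keepdims=True)
            var = ((xt - mu) ** 2).mean(axis=1, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            norm = (xt - mu) / ((var + self.eps) ** 0.5)
            norm = norm.reshape(c, n, h, w).transpose(1, 0, 2, 3)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            norm = (x - mu) * (1.0 / sd)
        return norm * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ResidualBlock(Module):
    """Two 3x3 convs with an identity skip; norm chosen by the caller."""

    def __init__(self, channels: int, norm: str, *, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, padding=1, bias=False, rng=rng)
        self.norm1 = GroupNorm(channels) if norm == "group" else BatchNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, bias=False, rng=rng)
        self.norm2 = GroupNorm(channels) if norm == "group" else BatchNorm2d(channels)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.norm1(self.conv1(x)).relu()
        y = self.norm2(self.conv2(y))
        return (x + y).relu()


def _stage_widths(width: int, n_stages: int) -> list[int]:
    # widen once after the stem, then hold; all widths stay multiples of 8
    return [min(width * (2 ** min(i, 1)), 4 * width) for i in range(n_stages)]


class SliceEncoder(Module):
    """Per-slice 2D encoder: strided conv stages + one residual block.

    Group normalization (8 groups) keeps every statistic per-sample, so a
    batch of slices produces exactly the features each slice would get on
    its own.  ``downsample`` must be a power of two; output channels =
    ``out_channels`` (divisible by 8).
    """

    def __init__(self, width: int = 16, downsample: int = 16, *,
                 rng: np.random.Generator):
        super().__init__()
        if width % 8:
            raise ValueError("width must be a multiple of 8 (group norm with 8 groups)")
        n_stages = int(np.log2(downsample))
        if 2 ** n_stages != downsample:
            raise ValueError("downsample must be a power of two")
        widths = _stage_widths(width, n_stages)
        self.downsample = downsample
        self.stages: list[Module] = []
        c_prev = 1
        for c in widths:
            self.stages.append(Conv2d(c_prev, c, 3, stride=2, padding=1,
                                      bias=False, rng=rng))
            self.stages.append(GroupNorm(c))
            c_prev = c
        self.block = ResidualBlock(c_prev, "group", rng=rng)
        self.out_channels = c_prev

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, c, H/downsample, W/downsample)."""
        for i in range(0, len(self.stages), 2):
            x = self.stages[i + 1](self.stages[i](x)).relu()
        return self.block(x)


class PatchEncoder(Module):
    """Patch network: residual conv stack -> GAP -> S-dim feature vector."""

    def __init__(self, patch_size: int = 256, width: int = 16, feature_dim: int = 512,
                 n_stages: int | None = None, *, rng: np.random.Generator):
        super().__init__()
        if n_stages is None:
            # downsample until the spatial grid is ~4x4
            n_stages = max(1, int(np.log2(patch_size // 4)))
        widths = _stage_widths(width, n_stages)
        self.stages: list[Module] = []
        c_prev = 1
        for c in widths:
            self.stages.append(Conv2d(c_prev, c, 3, stride=2, padding=1,
                                      bias=False, rng=rng))
            self.stages.append(BatchNorm2d(c))
            c_prev = c
        self.block = ResidualBlock(c_prev, "batch", rng=rng)
        self.proj = Linear(c_prev, feature_dim, rng=rng)
        self.feature_dim = feature_dim

    def __call__(self, x: Tensor) -> Tensor:
        """(K, 1, p, p) -> (K, S) patch features."""
        for i in range(0, len(self.stages), 2):
            x = self.stages[i + 1](self.stages[i](x)).relu()
        x = self.block(x)
        pooled = x.mean(axis=(2, 3))  # global average pool
        return self.proj(pooled).relu()
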