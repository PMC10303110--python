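"""Layer abstractions over the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor
from . import functional as F

__all__ = [
    "Module",
    "Conv1d",
    "SpatialCollapse",
    "BatchNorm",
    "Linear",
    "AvgPool1d",
    "Dropout",
    "ELU",
    "glorot_uniform",
]

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Base class with parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{path}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}"
                )
            p.data = state[name].astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    """1-D convolution [B, C_in, T] -> [B, C_out, T_out], stride 1.

    ``padding``: 'same' (zero-pad symmetrically so T_out == T),
    'causal' (left-pad only, so outputs never see the future),
    or 'valid'.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        if kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = padding
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.weight = Parameter(
            glorot_uniform(rng, (out_channels, in_channels, kernel_size), fan_in, fan_out)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        span = (self.kernel_size - 1) * self.dilation + 1
        if self.padding == "same":
            total = span - 1
            pl, pr = total // 2, total - total // 2
        elif self.padding == "causal":
            pl, pr = span - 1, 0
        elif self.padding == "valid":
            pl = pr = 0
        else:
            raise ValueError(f"unknown padding mode {self.padding!r}")
        return F.conv1d(x, self.weight, self.bias, dilation=self.dilation, pad_left=pl, pad_right=pr)


class SpatialCollapse(Module):
    """Depthwise convolution over the spatial-channel axis.

    Maps [B, F, C, T] -> [B, F*multiplier, T]; each output feature is a
    learned linear combination across all C channels of one input
    feature map (kernel spanning the full channel axis).
    """

    def __init__(
        self,
        n_features: int,
        n_channels: int,
        multiplier: int = 1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.n_features = n_features
        self.n_channels = n_channels
        self.multiplier = multiplier
        self.weight = Parameter(
            glorot_uniform(rng, (n_features, multiplier, n_channels), n_channels, multiplier)
        )

    def forward(self, x: Tensor) -> Tensor:
        return F.spatial_collapse(x, self.weight)


class BatchNorm(Module):
    """Batch normalization over axis 1 (features), pooling all other axes.

    Training mode uses batch statistics and updates running statistics
    with exponential moving averages; eval mode uses the running ones.
    """

    def __init__(self, num_features: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=DTYPE))
        self.beta = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _bshape(self, ndim: int):
        return (1, self.num_features) + (1,) * (ndim - 2)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.num_features:
            raise ValueError(
                f"BatchNorm expected {self.num_features} features on axis 1, got {x.data.shape[1]}"
            )
        axes = (0,) + tuple(range(2, x.data.ndim))
        shape = self._bshape(x.data.ndim)
        if self.training:
            out, mu, var = F.batch_norm_train(
                x, self.gamma.reshape(shape), self.beta.reshape(shape), axes, self.eps
            )
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.astype(DTYPE)
            self.running_var = m * self.running_var + (1 - m) * var.astype(DTYPE)
            return out
        # eval path: affine in the parameters too, so gradients still flow
        sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
        xhat = (x - Tensor(self.running_mean.reshape(shape))) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    """Dense map on the last axis: [..., in] -> [..., out]."""

    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        if zero_init:
            w = np.zeros((in_features, out_features), dtype=DTYPE)
        else:
            w = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class AvgPool1d(Module):
    def __init__(self, length: int, stride: int | None = None):
        super().__init__()
        self.length = length
        self.stride = length if stride is None else stride

    def forward(self, x: Tensor) -> Tensor:
        return F.avg_pool1d(x, self.length, self.stride)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class ELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.elu()
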