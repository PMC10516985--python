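"""Neural building blocks for the gated-fusion transformer.

All modules operate on NCHW tensors (batch, channel, row, col) except the
attention internals, which flatten windows to token sequences. Parameter
initialisation is seeded through a shared ``numpy`` generator so a fixed
seed yields bit-identical models.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "BatchNorm2d", "LayerNorm",
    "WindowAttention", "SwinLayer", "pixel_shuffle", "gelu",
]


class Parameter(Tensor):
    """A tensor registered as trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter traversal + train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self.named_buffers()})
        return state

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown entry in state dict: {name}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    inner = 0.7978845608028654 * (x + 0.044715 * x * x * x)
    return 0.5 * x * (1.0 + inner.tanh())


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalisation over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mean.data - self.running_mean)
            self.running_var += self.momentum * (var.data - self.running_var)
        else:
            mean = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    """Normalisation over the trailing (channel) axis of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mean) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping windows.

    Input tokens: (B_windows, T, C) with T = window_size**2. Softmax over the
    key axis, so each query's attention weights sum to one.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, return_attn: bool = False):
        bw, t, c = x.shape

        def split_heads(y: Tensor) -> Tensor:
            return y.reshape(bw, t, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

        q = split_heads(self.q(x)) * (self.head_dim ** -0.5)
        k = split_heads(self.k(x))
        v = split_heads(self.v(x))
        attn = (q @ k.transpose(0, 1, 3, 2)).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bw, t, c)
        out = self.proj(out)
        if return_attn:
            return out, attn
        return out


def _window_partition(x: Tensor, ws: int) -> tuple[Tensor, tuple[int, int, int]]:
    """(N, C, H, W) -> (N * nWindows, ws*ws, C)."""
    n, c, h, w = x.shape
    if h % ws or w % ws:
        raise ValueError(f"spatial size {h}x{w} not divisible by window size {ws}")
    x = x.transpose(0, 2, 3, 1)                                   # N,H,W,C
    x = x.reshape(n, h // ws, ws, w // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)                             # N,nh,nw,ws,ws,C
    tokens = x.reshape(n * (h // ws) * (w // ws), ws * ws, c)
    return tokens, (n, h, w)


def _window_merge(tokens: Tensor, ws: int, dims: tuple[int, int, int],
                  c: int) -> Tensor:
    n, h, w = dims
    x = tokens.reshape(n, h // ws, w // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)
    return x.transpose(0, 3, 1, 2)


class SwinLayer(Module):
    """One Swin-style transformer layer on NCHW feature maps.

    Pre-norm window attention plus a GELU MLP, each with a residual
    connection. Alternate layers cyclically shift the feature map by half a
    window before partitioning (periodic boundary; no attention mask), which
    lets information cross window borders.
    """

    def __init__(self, dim: int, window_size: int, n_heads: int,
                 mlp_ratio: float, shifted: bool, rng: np.random.Generator):
        super().__init__()
        self.window_size = window_size
        self.shifted = shifted
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        ws = self.window_size
        shift = ws // 2 if self.shifted else 0
        y = x.roll((-shift, -shift), (2, 3)) if shift else x
        tokens, dims = _window_partition(y, ws)
        c = x.shape[1]
        attended = tokens + self.attn(self.norm1(tokens))
        attended = attended + self.fc2(gelu(self.fc1(self.norm2(attended))))
        y = _window_merge(attended, ws, dims, c)
        return y.roll((shift, shift), (2, 3)) if shift else y


def pixel_shuffle(x: Tensor, scale: int) -> Tensor:
    """Sub-pixel rearrangement: (N, C*s^2, H, W) -> (N, C, s*H, s*W)."""
    n, c, h, w = x.shape
    s = scale
    if c % (s * s):
        raise ValueError(f"channels {c} not divisible by scale^2 ({s * s})")
    co = c // (s * s)
    x = x.reshape(n, co, s, s, h, w)
    x = x.transpose(0, 1, 4, 2, 5, 3)  # N, co, H, s, W, s
    return x.reshape(n, co, h * s, w * s)
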