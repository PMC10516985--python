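"""The gated-fusion transformer for joint SPAD denoising and super-resolution.

Architecture (three stages):

1. **Shallow feature extraction** — a small convolution / batch-norm /
   activation stack lifting the normalized low-bit image ``I_LQ`` (h, w,
   c_in) to low-frequency features ``F_0`` (h, w, c).
2. **Deep feature fusion** — ``n`` densely connected Swin-transformer blocks
   (DCSTB): block ``i`` sees the channel-concatenation of ``F_0 .. F_{i-1}``
   (projected back to ``c`` by a 1x1 convolution) and refines it with
   window-attention layers, shifting windows on alternate layers. A gated
   fusion layer then combines the block outputs with learnable scalar gates:
   ``F_DF = w_1 F_1 + ... + w_n F_n``.
3. **Reconstruction** — ``I_R = H_REC(F_0 + F_DF)``, where the long skip
   re-injects low-frequency content and ``H_REC`` upsamples by sub-pixel
   convolution (pixel shuffle) to the super-resolution scale ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .layers import (
    BatchNorm2d, Conv2d, Module, Parameter, SwinLayer, gelu, pixel_shuffle,
)

__all__ = [
    "NetworkConfig", "ShallowExtractor", "DCSTB", "GatedFusion",
    "Reconstructor", "GatedFusionTransformer", "build_model",
]

_ALLOWED_SCALES = (1, 2, 4)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults are deliberately small so the model trains in minutes on a CPU;
    every width/depth is exposed because the design scales by configuration
    alone.
    """

    embed_dim: int = 16
    n_blocks: int = 2
    layers_per_block: int = 2
    window_size: int = 4
    n_heads: int = 2
    mlp_ratio: float = 2.0
    sr_scale: int = 2
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.sr_scale not in _ALLOWED_SCALES:
            raise ValueError(f"sr_scale must be one of {_ALLOWED_SCALES}, "
                             f"got {self.sr_scale}")
        for name in ("embed_dim", "n_blocks", "layers_per_block",
                     "window_size", "n_heads", "in_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class ShallowExtractor(Module):
    """Conv -> batch-norm -> GELU -> conv: I_LQ (c_in) -> F_0 (c)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cfg.in_channels, cfg.embed_dim, 3, rng)
        self.bn = BatchNorm2d(cfg.embed_dim)
        self.conv2 = Conv2d(cfg.embed_dim, cfg.embed_dim, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(gelu(self.bn(self.conv1(x))))


class DCSTB(Module):
    """Densely connected Swin-transformer block.

    Receives the feature maps of *all* earlier stages, concatenates them on
    the channel axis, projects back to the embed dim with a 1x1 convolution,
    and applies ``layers_per_block`` Swin layers (windows shifted on odd
    layers).
    """

    def __init__(self, n_inputs: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.fuse = Conv2d(n_inputs * cfg.embed_dim, cfg.embed_dim, 1, rng,
                           padding=0)
        self.swin_layers = [
            SwinLayer(cfg.embed_dim, cfg.window_size, cfg.n_heads,
                      cfg.mlp_ratio, shifted=(j % 2 == 1), rng=rng)
            for j in range(cfg.layers_per_block)
        ]

    def __call__(self, features: list[Tensor]) -> Tensor:
        x = features[0] if len(features) == 1 else concat(features, axis=1)
        x = self.fuse(x)
        for layer in self.swin_layers:
            x = layer(x)
        return x


class GatedFusion(Module):
    """Learnable scalar-weighted sum of block outputs: F_DF = sum_i w_i F_i.

    Gates are unconstrained scalars initialised to 1/n so the initial fusion
    is a plain average; backpropagation re-weights the feature levels.
    """

    def __init__(self, n_blocks: int):
        super().__init__()
        self.gates = [Parameter(np.float64(1.0 / n_blocks))
                      for _ in range(n_blocks)]

    @property
    def gate_values(self) -> np.ndarray:
        return np.array([float(g.data) for g in self.gates])

    def set_gates(self, weights) -> None:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (len(self.gates),):
            raise ValueError(f"expected {len(self.gates)} gate weights, "
                             f"got shape {weights.shape}")
        for g, w in zip(self.gates, weights):
            g.data = np.asarray(w, dtype=np.float64)

    def __call__(self, features: list[Tensor]) -> Tensor:
        if len(features) != len(self.gates):
            raise ValueError(
                f"gated fusion expects {len(self.gates)} feature maps, "
                f"got {len(features)}"
            )
        out = None
        for gate, f in zip(self.gates, features):
            contrib = f * gate
            out = contrib if out is None else out + contrib
        return out


class Reconstructor(Module):
    """Sub-pixel convolution upsampler: F_0 + F_DF -> I_R at scale s."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.scale = cfg.sr_scale
        c = cfg.embed_dim
        self.pre = Conv2d(c, c, 3, rng)
        self.up_convs = []
        s = self.scale
        while s > 1:  # each stage doubles resolution via pixel shuffle
            self.up_convs.append(Conv2d(c, 4 * c, 3, rng))
            s //= 2
        self.out_conv = Conv2d(c, cfg.in_channels, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = gelu(self.pre(x))
        for conv in self.up_convs:
            x = gelu(pixel_shuffle(conv(x), 2))
        return self.out_conv(x)


class GatedFusionTransformer(Module):
    """Full network: shallow extraction -> dense Swin blocks -> gated fusion
    -> reconstruction. Input and output are NCHW tensors in [0, 1]."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.shallow = ShallowExtractor(cfg, rng)
        self.blocks = [DCSTB(i + 1, cfg, rng) for i in range(cfg.n_blocks)]
        self.fusion = GatedFusion(cfg.n_blocks)
        self.reconstructor = Reconstructor(cfg, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channel(s), got {x.shape[1]}"
            )
        if x.shape[2] % self.cfg.window_size or x.shape[3] % self.cfg.window_size:
            raise ValueError(
                f"input sides {x.shape[2]}x{x.shape[3]} must be divisible by "
                f"window_size={self.cfg.window_size}"
            )
        f0 = self.shallow(x)
        feats = [f0]
        for block in self.blocks:
            feats.append(block(feats))
        f_df = self.fusion(feats[1:])
        return self.reconstructor(f0 + f_df)


def build_model(cfg: NetworkConfig, seed: int = 0) -> GatedFusionTransformer:
    return GatedFusionTransformer(cfg, seed=seed)
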