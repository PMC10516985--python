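"""Hybrid training loss: L1 + perceptual + structural (SSIM) terms.

``Loss = alpha * L1 + beta * Loss_PER + gamma * (1 - SSIM)`` with default
weights alpha=0.1, beta=10, gamma=100. The L1 term anchors pixelwise
intensity, the perceptual term compares feature-space responses of a fixed
convolutional extractor, and the SSIM term regularises local structure
(luminance/contrast/covariance within an 11x11 Gaussian window).

The perceptual extractor is pluggable. The default is a fixed-seed random
convolutional stack: random convolutional features are a well-studied
stand-in for trained ones as a perceptual distance, and they require no
pretrained weights. Any callable mapping an NCHW tensor to a feature tensor
(e.g. an adapter around VGG19 pool-3 activations, when such weights are
available) can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .autodiff import Tensor, conv2d
from .layers import gelu

__all__ = [
    "LossConfig", "RandomConvFeatures", "l1_loss", "perceptual_loss",
    "ssim", "ssim_loss", "hybrid_loss", "gaussian_kernel",
]


def gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalised 2-D Gaussian window (the standard SSIM weighting)."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


class RandomConvFeatures:
    """Fixed-seed random convolutional feature extractor.

    Two 3x3 convolution layers (1 -> channels -> channels) with GELU
    in between; weights are frozen at construction, so the extractor is a
    deterministic function phi(.) with gradients flowing to its *input* only.
    """

    def __init__(self, channels: int = 8, seed: int = 7):
        rng = np.random.default_rng(seed)
        scale1 = np.sqrt(2.0 / 9.0)
        scale2 = np.sqrt(2.0 / (9.0 * channels))
        self.w1 = Tensor(rng.normal(0.0, scale1, (channels, 1, 3, 3)))
        self.w2 = Tensor(rng.normal(0.0, scale2, (channels, channels, 3, 3)))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != 1:
            x = x.reshape(n * c, 1, h, w)
        y = gelu(conv2d(x, self.w1, padding=1))
        return conv2d(y, self.w2, padding=1)


@dataclass
class LossConfig:
    """Weights of the hybrid loss and the pluggable perceptual extractor."""

    alpha: float = 0.1
    beta: float = 10.0
    gamma: float = 100.0
    perceptual_extractor: Callable[[Tensor], Tensor] | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == 0 and self.beta == 0 and self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")

    def with_default_extractor(self, seed: int = 7) -> "LossConfig":
        """Return a copy whose perceptual extractor is the fixed-seed random
        convolutional stack (no-op if an extractor is already set or beta=0)."""
        if self.perceptual_extractor is not None or self.beta == 0:
            return self
        return LossConfig(self.alpha, self.beta, self.gamma,
                          RandomConvFeatures(seed=seed))


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Mean absolute deviation between two images."""
    return (pred - target).abs().mean()


def perceptual_loss(pred: Tensor, target: Tensor,
                    extractor: Callable[[Tensor], Tensor]) -> Tensor:
    """Size-normalised L2 distance between feature maps: ||phi(a)-phi(b)||_2
    divided by sqrt(#features) (so the value is resolution-independent)."""
    fa = extractor(pred)
    fb = extractor(target)
    return (((fa - fb) ** 2.0).mean()) ** 0.5


def ssim(a: Tensor, b: Tensor, data_range: float = 1.0,
         window_size: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03) -> Tensor:
    """Differentiable mean structural similarity over Gaussian windows.

    Local means/variances/covariance are computed by valid-mode convolution
    with an 11x11 Gaussian (sigma 1.5); the SSIM map is averaged over all
    fully supported window positions (matching the reference convention of
    cropping half a window at each border).
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n, c, h, w = a.shape
    if h < window_size or w < window_size:
        raise ValueError(
            f"images ({h}x{w}) smaller than the SSIM window ({window_size})"
        )
    kern = Tensor(gaussian_kernel(window_size, sigma)[None, None])
    if c != 1:
        a = a.reshape(n * c, 1, h, w)
        b = b.reshape(n * c, 1, h, w)

    mu_a = conv2d(a, kern)
    mu_b = conv2d(b, kern)
    mu_aa = mu_a * mu_a
    mu_bb = mu_b * mu_b
    mu_ab = mu_a * mu_b
    var_a = conv2d(a * a, kern) - mu_aa
    var_b = conv2d(b * b, kern) - mu_bb
    cov = conv2d(a * b, kern) - mu_ab

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2.0 * mu_ab + c1) * (2.0 * cov + c2)
    den = (mu_aa + mu_bb + c1) * (var_a + var_b + c2)
    return (num / den).mean()


def ssim_loss(pred: Tensor, target: Tensor, data_range: float = 1.0) -> Tensor:
    return 1.0 - ssim(pred, target, data_range=data_range)


def hybrid_loss(pred: Tensor, target: Tensor, cfg: LossConfig) -> Tensor:
    """alpha * L1 + beta * perceptual + gamma * (1 - SSIM)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    total = None

    def _add(term):
        nonlocal total
        total = term if total is None else total + term

    if cfg.alpha > 0:
        _add(cfg.alpha * l1_loss(pred, target))
    if cfg.beta > 0:
        if cfg.perceptual_extractor is None:
            raise ValueError("beta > 0 requires a perceptual extractor "
                             "(see LossConfig.with_default_extractor)")
        _add(cfg.beta * perceptual_loss(pred, target, cfg.perceptual_extractor))
    if cfg.gamma > 0:
        _add(cfg.gamma * ssim_loss(pred, target))
    return total
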