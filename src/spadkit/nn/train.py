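"""Seeded training loop, Adam optimiser, checkpointing and inference.

The recipe mirrors the intended full-scale setup at whatever scale the
caller configures: Adam with beta1=0.5, beta2=0.999, weight decay 5e-5,
initial learning rate 3e-4 decayed by 10% every 100 epochs, batch size 24.
At desk scale the same loop runs on tiny phantoms in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad
from .losses import LossConfig, hybrid_loss
from .model import GatedFusionTransformer, NetworkConfig, build_model

__all__ = [
    "OptimizerConfig", "Adam", "learning_rate_at_epoch", "train",
    "save_checkpoint", "load_checkpoint", "enhance", "TrainResult",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam hyperparameters (defaults follow the training recipe)."""

    learning_rate: float = 3e-4
    beta1: float = 0.5
    beta2: float = 0.999
    weight_decay: float = 5e-5
    lr_decay: float = 0.1        # fractional decrease ...
    lr_decay_every: int = 100    # ... applied every this many epochs
    batch_size: int = 24


def learning_rate_at_epoch(cfg: OptimizerConfig, epoch: int) -> float:
    """Stepwise schedule: lr * (1 - decay)^(epoch // every)."""
    return cfg.learning_rate * (1.0 - cfg.lr_decay) ** (epoch // cfg.lr_decay_every)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, cfg: OptimizerConfig):
        self.params = list(params)
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        cfg = self.cfg
        lr = cfg.learning_rate if lr is None else lr
        self.t += 1
        b1c = 1.0 - cfg.beta1 ** self.t
        b2c = 1.0 - cfg.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad + cfg.weight_decay * p.data
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * g * g
            p.data -= lr * (m / b1c) / (np.sqrt(v / b2c) + 1e-8)


@dataclass
class TrainResult:
    model: GatedFusionTransformer
    log: list[dict]
    initial_loss: float
    final_loss: float


def _load_pairs(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """Accept in-memory (lq, hr) pairs or a dataset manifest path."""
    if isinstance(dataset, (str, Path)):
        from ..io import load_manifest_pairs
        return load_manifest_pairs(dataset)
    return list(dataset)


def _to_batch(arrs: list[np.ndarray]) -> Tensor:
    data = np.stack([np.atleast_2d(a)[None] if a.ndim == 2 else a for a in arrs])
    return Tensor(data)


def train(
    dataset,
    net_cfg: NetworkConfig,
    loss_cfg: LossConfig | None = None,
    opt_cfg: OptimizerConfig | None = None,
    seed: int = 0,
    n_steps: int = 200,
    model: GatedFusionTransformer | None = None,
    log_every: int = 10,
) -> TrainResult:
    """Train a gated-fusion transformer on (low-bit, high-res) pairs.

    Parameters
    ----------
    dataset : manifest path or sequence of (lq, hr) pairs
        ``lq`` is the normalized low-bit image in [0, 1] (2-D), ``hr`` the
        ground truth at ``sr_scale`` times the resolution.
    n_steps : int
        Number of optimiser steps; an epoch is one pass over the pairs, and
        the learning-rate schedule advances per epoch.

    Raises
    ------
    ValueError on an empty dataset; RuntimeError (with the offending step and
    learning rate) if the loss becomes non-finite.
    """
    pairs = _load_pairs(dataset)
    if not pairs:
        raise ValueError("training dataset is empty")
    loss_cfg = (loss_cfg or LossConfig()).with_default_extractor(seed=7)
    opt_cfg = opt_cfg or OptimizerConfig()
    rng = np.random.default_rng(seed)
    if model is None:
        model = build_model(net_cfg, seed=int(rng.integers(2 ** 31)))
    model.train()
    opt = Adam(model.parameters(), opt_cfg)

    n = len(pairs)
    batch = min(opt_cfg.batch_size, n)
    steps_per_epoch = max(1, n // batch)
    order = rng.permutation(n)
    pos = 0
    epoch = 0
    log: list[dict] = []
    initial_loss = None
    for step in range(n_steps):
        if pos + batch > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos:pos + batch]
        pos += batch
        epoch = step // steps_per_epoch
        lr = learning_rate_at_epoch(opt_cfg, epoch)

        lq = _to_batch([pairs[i][0] for i in idx])
        hr = _to_batch([pairs[i][1] for i in idx])
        pred = model(lq)
        loss = hybrid_loss(pred, hr, loss_cfg)
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss ({value}) at step {step} (lr={lr:.3g}); "
                "aborting — inspect the data normalisation and learning rate"
            )
        if initial_loss is None:
            initial_loss = value
        opt.zero_grad()
        loss.backward()
        opt.step(lr)
        if step % log_every == 0 or step == n_steps - 1:
            log.append({"step": step, "epoch": epoch, "lr": lr, "loss": value})
    model.eval()
    return TrainResult(model=model, log=log,
                       initial_loss=float(initial_loss),
                       final_loss=float(log[-1]["loss"]))


def save_checkpoint(model: GatedFusionTransformer, path,
                    extra: dict | None = None) -> None:
    """Write parameters (npz) plus a JSON echo of the architecture config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    meta = {"network": model.cfg.to_dict()}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> GatedFusionTransformer:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig.from_dict(meta["network"])
    model = build_model(cfg, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    model.eval()
    return model


def enhance(low_bit, model: GatedFusionTransformer) -> np.ndarray:
    """Denoise and upscale a low-bit SPAD image.

    ``low_bit`` may be a :class:`~spadkit.noise_model.LowBitImage` (counts are
    normalized by 2**bit_depth) or an already-normalized 2-D array in [0, 1].
    Returns a 2-D array in [0, 1] at ``sr_scale`` times the input resolution,
    deterministic for fixed weights.
    """
    from ..noise_model import LowBitImage

    if isinstance(low_bit, LowBitImage):
        img = low_bit.normalized()
    else:
        img = np.asarray(low_bit, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D image")
    ws = model.cfg.window_size
    if img.shape[0] % ws or img.shape[1] % ws:
        raise ValueError(
            f"input sides {img.shape} must be divisible by window_size={ws}; "
            "pad or crop the image first"
        )
    model.eval()
    with no_grad():
        out = model(Tensor(img[None, None]))
    return np.clip(out.data[0, 0], 0.0, 1.0)
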