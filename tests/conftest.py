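"""Shared fixtures: small sensors, dark stacks, and one toy training run.

The toy training run (8 phantom pairs, 200 optimiser steps) is the most
expensive fixture, so it is session-scoped and shared by the convergence and
enhancement tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import spadkit as sk
from spadkit.nn import NetworkConfig, TrainResult, train


def brute_force_classify(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Naive triple-loop event classifier (the independent oracle).

    Marks afterpulse where a pixel fires in two consecutive frames, and
    crosstalk where a firing pixel has a firing 4-neighbour in the same
    frame and was not already marked afterpulse.
    """
    n, h, w = frames.shape
    i_ap = np.zeros_like(frames)
    i_ct = np.zeros_like(frames)
    for t in range(n):
        for y in range(h):
            for x in range(w):
                if frames[t, y, x] != 1:
                    continue
                if t >= 1 and frames[t - 1, y, x] == 1:
                    i_ap[t, y, x] = 1
                    continue
                for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and frames[t, yy, xx] == 1:
                        i_ct[t, y, x] = 1
                        break
    return i_ap, i_ct


TOY_NET_CONFIG = NetworkConfig(embed_dim=16, n_blocks=2, layers_per_block=2,
                               window_size=4, n_heads=2, sr_scale=2)


def make_toy_pairs(n_scenes: int = 8, lr_side: int = 16, scale: int = 2,
                   bit_depth: int = 4, phi: float = 0.5, seed: int = 3):
    """Noisy low-flux training pairs on procedural phantoms.

    Conditions mirror the dimmest illumination rung and the lowest bit depth
    of the dataset grid — the regime where enhancement matters most.
    """
    phantoms = sk.generate_phantoms(n_scenes, size=lr_side * scale, seed=seed)
    calib = sk.SensorCalibration(pde=1.0, dcr=0.005, p_ap=0.08, p_ct=0.01,
                                 shape=(lr_side, lr_side))
    pairs = []
    for i, hr in enumerate(phantoms):
        pair = sk.synthesize_pair(hr, scale, calib, bit_depth=bit_depth,
                                  phi=phi, seed=100 + i)
        pairs.append((pair.measurement.normalized(), hr))
    return pairs


@pytest.fixture(scope="session")
def toy_pairs():
    return make_toy_pairs()


@pytest.fixture(scope="session")
def toy_training(toy_pairs) -> TrainResult:
    """One 200-step training run of the tiny gated-fusion model."""
    return train(toy_pairs, TOY_NET_CONFIG, seed=0, n_steps=200)


@pytest.fixture()
def small_calib() -> sk.SensorCalibration:
    return sk.SensorCalibration(pde=1.0, dcr=0.005, p_ap=0.08, p_ct=0.01,
                                shape=(16, 16))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
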