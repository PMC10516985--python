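"""Forward simulation of the multi-source SPAD noise model.

A SPAD (single-photon avalanche diode) array pixel emits a binary value per
integration window: 1 if at least one avalanche was triggered, 0 otherwise.
Avalanches are triggered by several sources:

* **Shot noise** — photon arrivals are Poisson with per-window expectation
  ``chi``; with photon detection efficiency (PDE) ``eta`` acting as binomial
  thinning, the probability of at least one detected photon is
  ``1 - exp(-eta * chi)``.
* **Dark counts** — thermally generated avalanches, Poisson with per-frame
  expectation ``lambda_dcr``; on a 1-bit sensor this yields a per-frame event
  with probability ``1 - exp(-lambda_dcr)``.
* **Afterpulsing** — carriers trapped during a previous avalanche re-trigger
  the same pixel in the *next* frame with fixed probability ``p_ap``
  (one-frame memory; frame 0 has no afterpulse).
* **Crosstalk** — photons emitted during a neighbour's avalanche trigger the
  pixel within the *same* frame: each firing 4-connected neighbour
  independently triggers the receiving pixel with its probability ``p_ct``;
  contributions combine by OR.
* **Deadtime** — quenching interval; eliminated by timing configuration and
  therefore never simulated as an event source (see :func:`validate_timing`).

Frames are stored ``(n, row, col)`` with row=y, col=x, origin top-left,
0-based, frames indexed from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "FluxImage",
    "SensorCalibration",
    "TimingConfig",
    "BinaryFrameStack",
    "LowBitImage",
    "detection_probability",
    "simulate_frames",
    "simulate_dark_frames",
    "accumulate",
    "validate_timing",
]

_NEIGHBOR_SHIFTS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGHBOR_SHIFTS_8 = _NEIGHBOR_SHIFTS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def neighbor_shifts(connectivity: int) -> tuple[tuple[int, int], ...]:
    """Row/col offsets of the crosstalk neighbourhood (4- or 8-connected)."""
    if connectivity == 4:
        return _NEIGHBOR_SHIFTS_4
    if connectivity == 8:
        return _NEIGHBOR_SHIFTS_8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a 2-D array by (dy, dx), zero-filling at the borders."""
    out = np.zeros_like(a)
    h, w = a.shape
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = a[ys_src, xs_src]
    return out


@dataclass(frozen=True)
class FluxImage:
    """Latent photon-flux expectation per pixel per integration window.

    ``chi`` is the expected number of incident photons at each pixel during
    one integration window — the latent light signal the enhancement network
    ultimately tries to recover.
    """

    chi: np.ndarray

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=np.float64)
        if chi.ndim != 2:
            raise ValueError(f"chi must be 2-D, got shape {chi.shape}")
        if not np.all(np.isfinite(chi)):
            raise ValueError("chi must be finite")
        if np.any(chi < 0):
            raise ValueError("chi must be non-negative")
        object.__setattr__(self, "chi", chi)

    @property
    def shape(self) -> tuple[int, int]:
        return self.chi.shape

    @property
    def height(self) -> int:
        return self.chi.shape[0]

    @property
    def width(self) -> int:
        return self.chi.shape[1]

    @classmethod
    def zeros(cls, shape: tuple[int, int]) -> "FluxImage":
        return cls(np.zeros(shape, dtype=np.float64))


def _as_map(value, shape, name: str, lo: float = 0.0, hi: float | None = 1.0) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(shape, float(arr))
    if arr.shape != tuple(shape):
        raise ValueError(f"{name} shape {arr.shape} does not match sensor shape {tuple(shape)}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < lo) or (hi is not None and np.any(arr > hi)):
        bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
        raise ValueError(f"{name} values must lie in {bound}")
    return arr


@dataclass(frozen=True)
class SensorCalibration:
    """Per-pixel noise-parameter maps of a SPAD array.

    Parameters
    ----------
    pde : array or scalar
        Photon detection efficiency map, in [0, 1] (the fixed-pattern noise
        source: each pixel detects an incident photon with this probability).
    dcr : array or scalar
        Dark-count expectation per frame (Poisson rate), >= 0.
    p_ap : array or scalar
        Afterpulse probability map, in [0, 1].
    p_ct : array or scalar
        Crosstalk probability map, in [0, 1].
    shape : tuple
        Sensor shape (height, width); scalars are broadcast to it.
    connectivity : {4, 8}
        Crosstalk neighbourhood used in simulation and calibration.
    """

    pde: np.ndarray
    dcr: np.ndarray
    p_ap: np.ndarray
    p_ct: np.ndarray
    shape: tuple[int, int] = None  # type: ignore[assignment]
    connectivity: Literal[4, 8] = 4

    def __post_init__(self) -> None:
        shape = self.shape
        if shape is None:
            for cand in (self.pde, self.dcr, self.p_ap, self.p_ct):
                arr = np.asarray(cand)
                if arr.ndim == 2:
                    shape = arr.shape
                    break
            else:
                raise ValueError("shape must be given when all maps are scalars")
        shape = (int(shape[0]), int(shape[1]))
        neighbor_shifts(self.connectivity)  # validates
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "pde", _as_map(self.pde, shape, "pde"))
        object.__setattr__(self, "dcr", _as_map(self.dcr, shape, "dcr", hi=None))
        object.__setattr__(self, "p_ap", _as_map(self.p_ap, shape, "p_ap"))
        object.__setattr__(self, "p_ct", _as_map(self.p_ct, shape, "p_ct"))

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    @classmethod
    def ideal(cls, shape: tuple[int, int], connectivity: int = 4) -> "SensorCalibration":
        """Noise-free sensor: unit PDE, zero DCR/afterpulse/crosstalk."""
        return cls(pde=1.0, dcr=0.0, p_ap=0.0, p_ct=0.0, shape=shape,
                   connectivity=connectivity)

    def summary(self) -> dict:
        return {
            "shape": list(self.shape),
            "connectivity": int(self.connectivity),
            "pde_mean": float(self.pde.mean()),
            "dcr_mean": float(self.dcr.mean()),
            "p_ap_mean": float(self.p_ap.mean()),
            "p_ct_mean": float(self.p_ct.mean()),
        }


@dataclass(frozen=True)
class TimingConfig:
    """SPAD frame timing in nanoseconds.

    The default mirrors a typical fast-gated configuration: 20 ns integration,
    60 ns dead time, 80 ns readout, with the frame period covering integration
    plus dead time so quenching never bleeds into the next window.
    """

    integration_ns: float = 20.0
    dead_ns: float = 60.0
    readout_ns: float = 80.0
    frame_period_ns: float = 160.0

    def __post_init__(self) -> None:
        for name in ("integration_ns", "dead_ns", "readout_ns", "frame_period_ns"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def validate_timing(t: TimingConfig) -> list[str]:
    """Check that deadtime cannot overlap the next integration window.

    Returns an empty list when ``frame_period >= integration + dead`` (the
    regime in which deadtime contributes no events and is safely excluded from
    the noise model); otherwise returns a warning string.
    """
    warnings: list[str] = []
    if t.frame_period_ns < t.integration_ns + t.dead_ns:
        warnings.append(
            "frame_period_ns ({:.6g}) < integration_ns + dead_ns ({:.6g}): "
            "deadtime overlaps the next integration window, so the zero-deadtime "
            "assumption of the noise model is violated".format(
                t.frame_period_ns, t.integration_ns + t.dead_ns
            )
        )
    return warnings


@dataclass(frozen=True)
class BinaryFrameStack:
    """An ordered stack of 1-bit SPAD frames, shape ``(n_frames, h, w)``."""

    frames: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, h, w), got shape {frames.shape}")
        if frames.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if frames.dtype != np.uint8:
            if not np.isin(frames, (0, 1)).all():
                raise ValueError("frame values must be 0 or 1")
            frames = frames.astype(np.uint8)
        elif frames.max(initial=0) > 1:
            raise ValueError("frame values must be 0 or 1")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def sensor_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def firing_rate(self) -> np.ndarray:
        """Per-pixel empirical firing probability."""
        return self.frames.mean(axis=0)


@dataclass(frozen=True)
class LowBitImage:
    """Integer accumulation of ``2**bit_depth`` binary subframes."""

    counts: np.ndarray
    bit_depth: int
    n_subframes: int
    illumination: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if not 1 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in 1..16")
        if self.n_subframes != 2 ** self.bit_depth:
            raise ValueError(
                f"n_subframes ({self.n_subframes}) must equal 2**bit_depth "
                f"({2 ** self.bit_depth})"
            )
        if counts.min(initial=0) < 0 or counts.max(initial=0) > self.n_subframes:
            raise ValueError("counts must lie in [0, n_subframes]")
        object.__setattr__(self, "counts", counts)

    def normalized(self) -> np.ndarray:
        """Counts mapped to [0, 1] by the subframe count."""
        return self.counts.astype(np.float64) / self.n_subframes


def detection_probability(chi: FluxImage, calib: SensorCalibration) -> np.ndarray:
    """Per-frame probability that shot noise triggers a pixel.

    Photon arrivals are Poisson(chi); PDE thins them binomially, so detected
    arrivals are Poisson(eta * chi) and the 1-bit detection probability is
    ``p_det = 1 - exp(-eta * chi)``, monotone in both eta and chi.
    """
    if chi.shape != calib.shape:
        raise ValueError(
            f"flux shape {chi.shape} does not match calibration shape {calib.shape}"
        )
    return -np.expm1(-calib.pde * chi.chi)


def _frame_rng(seed: int, frame: int) -> np.random.Generator:
    # counter-derived substream: one Philox stream per (seed, frame)
    return np.random.Generator(np.random.Philox(key=[seed & 0xFFFFFFFF, frame]))


def simulate_frames(
    chi: FluxImage,
    calib: SensorCalibration,
    n_frames: int,
    seed: int,
) -> BinaryFrameStack:
    """Simulate a stack of binary SPAD frames under the multi-source model.

    Per frame, per pixel, events compose in a fixed order:

    1. *primary* — Bernoulli(``1 - exp(-eta*chi)``) OR Bernoulli(``1 - exp(-dcr)``);
    2. *afterpulse* — Bernoulli(``p_ap``) if the same pixel fired in the
       previous frame (frame 0 has none);
    3. *crosstalk* — each neighbouring pixel whose primary/afterpulse event
       fired in this frame independently triggers the receiving pixel with
       probability ``p_ct`` (single pass: crosstalk does not re-seed
       crosstalk).

    The frame value is the OR of all events. Fully reproducible for a fixed
    seed; frame ``n`` consumes an independent counter-derived RNG substream so
    stacks are bit-identical across runs and platforms.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    p_det = detection_probability(chi, calib)
    p_dark = -np.expm1(-calib.dcr)
    shifts = neighbor_shifts(calib.connectivity)
    h, w = calib.shape
    has_flux = bool(np.any(p_det > 0))
    has_ap = bool(np.any(calib.p_ap > 0))
    has_ct = bool(np.any(calib.p_ct > 0))

    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    prev = np.zeros((h, w), dtype=bool)
    for n in range(n_frames):
        rng = _frame_rng(seed, n)
        primary = rng.random((h, w)) < p_dark
        if has_flux:
            primary |= rng.random((h, w)) < p_det
        if has_ap and n >= 1:
            seed_events = primary | (prev & (rng.random((h, w)) < calib.p_ap))
        else:
            seed_events = primary
        fired = seed_events
        if has_ct:
            fired = seed_events.copy()
            for dy, dx in shifts:
                neighbour_fired = shift2d(seed_events, dy, dx)
                fired |= neighbour_fired & (rng.random((h, w)) < calib.p_ct)
        frames[n] = fired
        prev = fired
    metadata = {
        "seed": int(seed),
        "n_frames": int(n_frames),
        "sensor_shape": [h, w],
        "connectivity": int(calib.connectivity),
    }
    return BinaryFrameStack(frames=frames, metadata=metadata)


def simulate_dark_frames(
    calib: SensorCalibration, n_frames: int, seed: int
) -> BinaryFrameStack:
    """Simulate a dark acquisition (no illumination, ``chi = 0``).

    In darkness shot noise and fixed-pattern noise vanish; the frames are
    generated purely by dark counts, afterpulsing and crosstalk — the regime
    used to calibrate those three parameters.
    """
    stack = simulate_frames(FluxImage.zeros(calib.shape), calib, n_frames, seed)
    stack.metadata["dark"] = True
    return stack


def accumulate(stack: BinaryFrameStack, bit_depth: int) -> LowBitImage:
    """Sum the first ``2**bit_depth`` subframes into a low-bit image.

    A b-bit SPAD image is by convention the sum of ``2**b`` one-bit frames
    (e.g. 1024 subframes for 10-bit depth).
    """
    if not 1 <= bit_depth <= 16:
        raise ValueError("bit_depth must be in 1..16")
    needed = 2 ** bit_depth
    if stack.n_frames < needed:
        raise ValueError(
            f"bit_depth {bit_depth} requires {needed} subframes; "
            f"stack has only {stack.n_frames}"
        )
    counts = stack.frames[:needed].sum(axis=0, dtype=np.int64)
    return LowBitImage(counts=counts, bit_depth=bit_depth, n_subframes=needed)
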