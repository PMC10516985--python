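"""Paired dataset synthesis: clean high-resolution images -> realistic
low-bit, low-resolution SPAD measurements.

Workflow per scene: crop the source image to a square (512 x 512 by
default), downsample by a scale s in {2, 4, 8, 16} with area averaging (a
photon-collection model: a big SPAD pixel integrates the flux of the scene
area it covers), map normalized intensity to photon flux chi with a named
illumination multiplier, simulate ``2**b`` binary frames with the calibrated
noise model, and accumulate them into a b-bit measurement.

A procedural phantom generator (edges, USAF-style bar groups, disks, smooth
gradients) stands in for natural-image corpora so datasets can be built
without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .noise_model import (
    BinaryFrameStack, FluxImage, LowBitImage, SensorCalibration,
    accumulate, simulate_frames,
)

__all__ = [
    "FluxLevelConfig", "ScenePair", "prepare_scene", "intensity_to_flux",
    "synthesize_pair", "build_dataset", "generate_phantoms",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])  # Rec. 709 luminance weights

DEFAULT_FLUX_LEVELS = {"low": 0.5, "mid": 1.0, "high": 2.0}


@dataclass(frozen=True)
class FluxLevelConfig:
    """Named illumination levels: multiplier phi mapping intensity to chi.

    The defaults (0.5 / 1 / 2 photons per window at full intensity) stand in
    for a 10 / 20 / 40 mW laser-power ladder — flux proportional to power,
    with no absolute radiometric calibration.
    """

    levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLUX_LEVELS))

    def __post_init__(self) -> None:
        for name, phi in self.levels.items():
            if not phi > 0:
                raise ValueError(f"flux level {name!r} must be positive, got {phi}")

    def __getitem__(self, name: str) -> float:
        return self.levels[name]


@dataclass(frozen=True)
class ScenePair:
    """One dataset entry: HR ground truth + LR flux + simulated measurement."""

    hr_image: np.ndarray
    lr_flux: FluxImage
    measurement: LowBitImage
    scale: int
    bit_depth: int
    flux_level: str
    seed: int

    def __post_init__(self) -> None:
        h, w = self.hr_image.shape
        lh, lw = self.lr_flux.shape
        if (h, w) != (lh * self.scale, lw * self.scale):
            raise ValueError(
                f"HR shape {(h, w)} must be LR shape {(lh, lw)} x scale {self.scale}"
            )
        if self.measurement.counts.shape != (lh, lw):
            raise ValueError("measurement shape must match the LR flux shape")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3]) image to 2-D via Rec. 709 luminance."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        if image.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {image.shape[2]}")
        image = image[..., :3] @ _LUMA
    return image


def area_downsample(image: np.ndarray, scale: int) -> np.ndarray:
    """Block-average downsampling by an integer factor."""
    h, w = image.shape
    if h % scale or w % scale:
        raise ValueError(f"image shape {image.shape} not divisible by scale {scale}")
    return image.reshape(h // scale, scale, w // scale, scale).mean(axis=(1, 3))


def prepare_scene(
    image: np.ndarray,
    crop_size: int = 512,
    scale: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop + grayscale + area-downsample a source image.

    Returns ``(hr, lr_intensity)``: the HR crop in [0, 1] and its
    area-averaged downsampling by ``scale``. The crop is centred unless a
    seeded ``rng`` is given, in which case the offset is drawn uniformly.
    """
    image = to_grayscale(image)
    h, w = image.shape
    if h < crop_size or w < crop_size:
        raise ValueError(
            f"image ({h}x{w}) smaller than crop_size ({crop_size})"
        )
    if crop_size % scale:
        raise ValueError(f"scale {scale} must divide crop_size {crop_size}")
    if rng is None:
        y0, x0 = (h - crop_size) // 2, (w - crop_size) // 2
    else:
        y0 = int(rng.integers(0, h - crop_size + 1))
        x0 = int(rng.integers(0, w - crop_size + 1))
    hr = image[y0:y0 + crop_size, x0:x0 + crop_size]
    lo, hi = float(hr.min()), float(hr.max())
    if hi > 1.0 or lo < 0.0:  # tolerate 8/16-bit inputs
        hr = (hr - lo) / (hi - lo) if hi > lo else np.zeros_like(hr)
    return hr, area_downsample(hr, scale)


def intensity_to_flux(lr_intensity: np.ndarray, phi: float) -> FluxImage:
    """Linear, zero-preserving map from normalized intensity to photon flux."""
    lr_intensity = np.asarray(lr_intensity, dtype=np.float64)
    if np.any(lr_intensity < 0):
        raise ValueError("intensity must be non-negative")
    if not phi > 0:
        raise ValueError("flux multiplier phi must be positive")
    return FluxImage(phi * lr_intensity)


def synthesize_pair(
    hr: np.ndarray,
    scale: int,
    calib: SensorCalibration,
    bit_depth: int,
    phi: float,
    seed: int,
    flux_level: str = "",
) -> ScenePair:
    """Simulate one (HR ground truth, low-bit SPAD measurement) pair.

    The HR image must already be in [0, 1] with sides divisible by ``scale``
    and its downsampled shape equal to the calibration's sensor shape.
    Reproducible: the same arguments and seed give an identical pair.
    """
    hr = np.asarray(hr, dtype=np.float64)
    lr_intensity = area_downsample(hr, scale)
    if lr_intensity.shape != calib.shape:
        raise ValueError(
            f"downsampled shape {lr_intensity.shape} does not match sensor "
            f"shape {calib.shape}"
        )
    flux = intensity_to_flux(lr_intensity, phi)
    stack = simulate_frames(flux, calib, 2 ** bit_depth, seed)
    measurement = accumulate(stack, bit_depth)
    return ScenePair(hr_image=hr, lr_flux=flux, measurement=measurement,
                     scale=scale, bit_depth=bit_depth,
                     flux_level=flux_level, seed=seed)


# ---------------------------------------------------------------------------
# Procedural phantoms

def _phantom_bars(size: int, rng: np.random.Generator) -> np.ndarray:
    """USAF-style bar groups: triplets of bars at halving widths."""
    img = np.zeros((size, size))
    width = max(size // 8, 2)
    y = size // 16
    while width >= 1 and y + 5 * width < size:
        x0 = size // 16
        for k in range(3):  # horizontal triplet
            y0 = y + 2 * k * width
            img[y0:y0 + width, x0:x0 + 5 * width] = 1.0
        x1 = x0 + 7 * width
        for k in range(3):  # vertical triplet
            img[y:y + 5 * width, x1 + 2 * k * width:x1 + (2 * k + 1) * width] = 1.0
        y += 7 * width
        width //= 2
    return img


def _phantom_disks(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(3, 7)):
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(size / 12, size / 4)
        level = rng.uniform(0.3, 1.0)
        img = np.maximum(img, level * ((yy - cy) ** 2 + (xx - cx) ** 2 < r * r))
    return img


def _phantom_edges(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size))
    for _ in range(rng.integers(2, 5)):
        angle = rng.uniform(0, np.pi)
        offset = rng.uniform(0.25, 0.75) * size
        yy, xx = np.mgrid[0:size, 0:size]
        side = (np.cos(angle) * xx + np.sin(angle) * yy) > offset
        img = np.where(side, rng.uniform(0.4, 1.0), img)
    return img


def _phantom_gradient(size: int, rng: np.random.Generator) -> np.ndarray:
    angle = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    ramp = np.cos(angle) * xx + np.sin(angle) * yy
    ramp = (ramp - ramp.min()) / (ramp.max() - ramp.min())
    freq = rng.uniform(1.0, 3.0)
    return np.clip(0.5 * ramp + 0.5 * np.sin(2 * np.pi * freq * ramp) ** 2, 0, 1)


_PHANTOM_KINDS = (_phantom_bars, _phantom_disks, _phantom_edges,
                  _phantom_gradient)


def generate_phantoms(n: int, size: int = 512, seed: int = 0) -> list[np.ndarray]:
    """Seeded procedural test targets spanning [0, 1].

    Cycles through bar groups (known bar widths by construction), disks,
    straight edges and smooth gradients; a fixed seed reproduces the set
    exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n):
        kind = _PHANTOM_KINDS[i % len(_PHANTOM_KINDS)]
        img = kind(size, rng).astype(np.float64)
        phantoms.append(np.clip(img, 0.0, 1.0))
    return phantoms


def build_dataset(
    out_dir,
    calib: SensorCalibration | None = None,
    source_images: list[np.ndarray] | None = None,
    n_phantoms: int | None = None,
    crop_size: int = 512,
    scales: tuple[int, ...] = (2, 4, 8, 16),
    bit_depths: tuple[int, ...] = (4, 6, 8, 10),
    levels: FluxLevelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Build a full paired dataset and write it with a JSON manifest.

    One pair is produced per (scene, scale, bit depth, flux level). Each
    scale needs its own calibration shape; when ``calib`` is None an ideal
    sensor of the right shape is used per scale (noise-free pairs). Returns
    the manifest dict; arrays are written as .npy beside it.

    The build is a pure function of (sources, configuration, seed): re-runs
    yield byte-identical manifests.
    """
    from .io import write_image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    levels = levels or FluxLevelConfig()
    if source_images is None:
        if not n_phantoms:
            raise ValueError("provide source_images or n_phantoms")
        source_images = generate_phantoms(n_phantoms, size=crop_size, seed=seed)
    if not source_images:
        raise ValueError("no source images given")

    entries = []
    pair_seed_rng = np.random.default_rng(seed)
    for i_scene, src in enumerate(source_images):
        for scale in scales:
            hr, _ = prepare_scene(src, crop_size=crop_size, scale=scale)
            sensor_shape = (crop_size // scale, crop_size // scale)
            scale_calib = calib if calib is not None and calib.shape == sensor_shape \
                else SensorCalibration.ideal(sensor_shape) if calib is None else None
            if scale_calib is None:
                raise ValueError(
                    f"calibration shape {calib.shape} incompatible with scale "
                    f"{scale} (needs {sensor_shape})"
                )
            for b in bit_depths:
                for level_name, phi in levels.levels.items():
                    pair_seed = int(pair_seed_rng.integers(2 ** 31))
                    pair = synthesize_pair(hr, scale, scale_calib, b, phi,
                                           pair_seed, flux_level=level_name)
                    stem = f"scene{i_scene:04d}_s{scale}_b{b}_{level_name}"
                    hr_path = out_dir / f"{stem}_hr.png"
                    lq_path = out_dir / f"{stem}_lq.npy"
                    write_image(hr_path, pair.hr_image)
                    np.save(lq_path, pair.measurement.counts)
                    entries.append({
                        "scene": i_scene, "scale": scale, "bit_depth": b,
                        "flux_level": level_name, "phi": phi,
                        "seed": pair_seed,
                        "hr": hr_path.name, "lq": lq_path.name,
                        "hr_shape": list(pair.hr_image.shape),
                        "lq_shape": list(pair.measurement.counts.shape),
                        "n_subframes": pair.measurement.n_subframes,
                    })
    manifest = {
        "version": 1,
        "seed": int(seed),
        "crop_size": crop_size,
        "scales": list(scales),
        "bit_depths": list(bit_depths),
        "levels": dict(levels.levels),
        "n_scenes": len(source_images),
        "n_pairs": len(entries),
        "pairs": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
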