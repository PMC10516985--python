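"""Readers/writers for frame stacks, images and calibration maps.

Conventions: binary frame stacks are multi-page TIFFs storing one uint8
frame (values 0/1) per page, with a JSON sidecar (same stem, ``.json``)
recording sensor shape, frame count, timing and seed. Images are PNG or
TIFF grayscale, normalized to [0, 1] on read with the original bit depth
recorded. Calibration maps are 32-bit float TIFFs plus a JSON summary.
Coordinates everywhere: (row=y, col=x), 0-based, origin top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .noise_model import BinaryFrameStack, SensorCalibration

__all__ = [
    "read_stack", "write_stack", "read_image", "write_image",
    "write_calibration", "read_calibration", "load_manifest_pairs",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path, stack: BinaryFrameStack) -> None:
    """Write a binary stack as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    sidecar = {
        "sensor_shape": list(stack.sensor_shape),
        "n_frames": int(stack.n_frames),
        **{k: v for k, v in stack.metadata.items()
           if k not in ("sensor_shape", "n_frames")},
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> BinaryFrameStack:
    """Read a multi-page TIFF stack, validating against its JSON sidecar."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if not np.isin(frames, (0, 1)).all():
        raise ValueError(f"{path}: 1-bit stack contains values outside {{0, 1}}")
    metadata: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        metadata = json.loads(sc.read_text())
        if "n_frames" in metadata and metadata["n_frames"] != frames.shape[0]:
            raise ValueError(
                f"{path}: sidecar field 'n_frames' ({metadata['n_frames']}) "
                f"does not match the TIFF page count ({frames.shape[0]})"
            )
        if ("sensor_shape" in metadata
                and tuple(metadata["sensor_shape"]) != frames.shape[1:]):
            raise ValueError(
                f"{path}: sidecar field 'sensor_shape' "
                f"({metadata['sensor_shape']}) does not match the frame shape "
                f"{frames.shape[1:]}"
            )
    return BinaryFrameStack(frames=frames.astype(np.uint8), metadata=metadata)


def write_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] image as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be normalized to [0, 1] before writing")
    if bit_depth == 8:
        data = np.round(image * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(image * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, data)


def read_image(path) -> np.ndarray:
    """Read a grayscale image, normalized to [0, 1] by its storage depth.

    Colour inputs are collapsed with Rec. 709 luminance weights.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        data = iio.imread(path)
    if data.ndim == 3:
        from .synthesis import to_grayscale
        if np.issubdtype(data.dtype, np.integer):
            info = np.iinfo(data.dtype)
            return to_grayscale(data.astype(np.float64) / info.max)
        return to_grayscale(data)
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    raise ValueError(f"{path}: unsupported image dtype {data.dtype}")


def write_calibration(out_dir, calib: SensorCalibration,
                      n_total: int | None = None) -> None:
    """Write per-map float32 TIFFs plus a JSON summary (means, shape, n_total)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("pde", "dcr", "p_ap", "p_ct"):
        tifffile.imwrite(out_dir / f"{name}.tiff",
                         getattr(calib, name).astype(np.float32))
    summary = calib.summary()
    if n_total is not None:
        summary["n_total"] = int(n_total)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def read_calibration(in_dir) -> SensorCalibration:
    in_dir = Path(in_dir)
    maps = {name: tifffile.imread(in_dir / f"{name}.tiff").astype(np.float64)
            for name in ("pde", "dcr", "p_ap", "p_ct")}
    summary = json.loads((in_dir / "summary.json").read_text())
    return SensorCalibration(shape=tuple(summary["shape"]),
                             connectivity=summary.get("connectivity", 4),
                             **maps)


def load_manifest_pairs(manifest_path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load (normalized low-bit, HR ground truth) pairs from a dataset manifest."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    pairs = []
    for entry in manifest["pairs"]:
        counts = np.load(base / entry["lq"])
        lq = counts.astype(np.float64) / entry["n_subframes"]
        hr = read_image(base / entry["hr"])
        pairs.append((lq, hr))
    return pairs
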