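"""Quantitative image-quality metrics and small experiment utilities.

PSNR and SSIM follow the standard conventions (SSIM: 11x11 Gaussian window,
sigma 1.5, K1=0.01, K2=0.03, computed here by scikit-image). For b-bit SPAD
count images, metrics can be taken either on raw counts with
``data_range=2**b`` or — the default convention throughout this package —
after normalising counts to [0, 1] with ``data_range=1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "PSNR_CAP_DB", "MetricReport", "psnr", "ssim", "rad_per_us_to_rpm",
    "evaluate_pairs", "evaluate_manifest", "nearest_neighbor_upsample",
]

#: Sentinel reported when MSE == 0 (identical images; PSNR diverges).
PSNR_CAP_DB = 100.0


def psnr(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, ``10 log10(data_range^2 / MSE)`` in dB.

    Identical images are reported as the capped sentinel ``PSNR_CAP_DB``.
    Jointly rescaling both images and ``data_range`` leaves the value
    unchanged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not data_range > 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return 10.0 * np.log10(data_range ** 2 / mse)


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity with Gaussian weighting (Wang et al. form)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError(f"images {a.shape} smaller than the 11x11 SSIM window")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03,
    ))


def rad_per_us_to_rpm(omega: float, round_to: int = 1000) -> float:
    """Convert an angular rate in rad/us to revolutions per minute.

    ``rpm = omega * 1e6 * 60 / (2 pi)``, rounded to the nearest ``round_to``
    (1000 by default, matching how such speeds are typically quoted).
    """
    if omega < 0:
        raise ValueError("angular rate must be non-negative")
    rpm = omega * 1e6 * 60.0 / (2.0 * np.pi)
    if round_to:
        rpm = round(rpm / round_to) * round_to
    return float(rpm)


def nearest_neighbor_upsample(img: np.ndarray, scale: int) -> np.ndarray:
    """Pixel-replication upsampling (the no-learning baseline)."""
    return np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)


@dataclass
class MetricReport:
    """Per-image PSNR/SSIM rows plus per-condition aggregates."""

    rows: pd.DataFrame
    by_condition: pd.DataFrame

    @property
    def mean_psnr(self) -> float:
        return float(self.rows["psnr_db"].mean())

    @property
    def mean_ssim(self) -> float:
        return float(self.rows["ssim"].mean())

    def to_json(self) -> str:
        return json.dumps({
            "mean_psnr_db": self.mean_psnr,
            "mean_ssim": self.mean_ssim,
            "by_condition": json.loads(
                self.by_condition.reset_index().to_json(orient="records")),
        }, indent=2)


def evaluate_pairs(records: list[dict]) -> MetricReport:
    """Build a report from records with keys prediction, ground_truth and
    optional condition tags (scale, bit_depth, flux_level)."""
    rows = []
    for rec in records:
        pred = np.asarray(rec["prediction"], dtype=np.float64)
        gt = np.asarray(rec["ground_truth"], dtype=np.float64)
        row = {k: rec[k] for k in ("scale", "bit_depth", "flux_level")
               if k in rec}
        row["psnr_db"] = psnr(pred, gt)
        row["ssim"] = ssim(pred, gt)
        rows.append(row)
    df = pd.DataFrame(rows)
    keys = [k for k in ("scale", "bit_depth", "flux_level") if k in df.columns]
    agg = (df.groupby(keys)[["psnr_db", "ssim"]].mean()
           if keys else df[["psnr_db", "ssim"]].mean().to_frame().T)
    return MetricReport(rows=df, by_condition=agg)


def evaluate_manifest(manifest_path, model) -> MetricReport:
    """Enhance every pair in a dataset manifest and tabulate PSNR/SSIM.

    The prediction for each entry is the model output on the normalized
    measurement; missing files are collected and reported in one error.
    """
    from .nn.train import enhance

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    from .io import read_image

    missing = [str(base / e[k]) for e in manifest["pairs"] for k in ("hr", "lq")
               if not (base / e[k]).exists()]
    if missing:
        raise FileNotFoundError("missing dataset files: " + ", ".join(missing))

    records = []
    for entry in manifest["pairs"]:
        gt = read_image(base / entry["hr"])
        counts = np.load(base / entry["lq"])
        lq = counts.astype(np.float64) / entry["n_subframes"]
        pred = enhance(lq, model)
        if pred.shape != gt.shape:
            # model scale need not match the dataset scale; compare at the
            # model's output resolution against an area-matched ground truth
            from .synthesis import area_downsample
            factor = gt.shape[0] // pred.shape[0]
            gt = area_downsample(gt, factor) if factor > 1 else gt
        records.append({
            "prediction": pred, "ground_truth": gt,
            "scale": entry["scale"], "bit_depth": entry["bit_depth"],
            "flux_level": entry["flux_level"],
        })
    return evaluate_pairs(records)
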