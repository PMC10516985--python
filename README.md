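# spadkit

Physics-informed single-photon imaging in Python: a multi-source noise model
for SPAD (single-photon avalanche diode) arrays, dark-frame calibration of
per-pixel noise parameters, paired low-bit/low-resolution dataset synthesis,
and a gated-fusion Swin-style transformer for joint denoising and
super-resolution, with PSNR/SSIM evaluation utilities.

## Who this is for

SPAD arrays detect single photons as one-bit events per integration window,
enabling photon-starved and microsecond-scale imaging — fluorescence
microscopy, microfluidic inspection, high-speed scenes — but commercial
arrays are tiny (thousands of pixels) and their raw frames are dominated by
sensor noise. `spadkit` is for researchers who want to (a) simulate
realistic SPAD measurements from a latent photon-flux image, (b) calibrate
the noise parameters of a real sensor from a dark acquisition, (c) generate
paired training data, and (d) train and evaluate a learned enhancer, all on
an ordinary CPU.

## The model

A pixel's one-bit value per frame is the OR of events from several sources:

- **Shot noise** — photon arrivals are Poisson with expectation χ per
  window; photon detection efficiency η (the fixed-pattern map) thins them,
  so the detection probability is `p_det = 1 − exp(−η·χ)`.
- **Dark counts** — thermal events, Poisson with per-frame expectation
  λ_dcr: per-frame probability `1 − exp(−λ_dcr)`.
- **Afterpulsing** — if a pixel fired in frame *n−1*, it re-fires in frame
  *n* with fixed probability `p_ap` (one-frame memory).
- **Crosstalk** — each firing 4-neighbour independently triggers the pixel
  in the same frame with probability `p_ct`.
- **Deadtime** — excluded by timing design (`validate_timing` checks that
  the frame period covers integration + dead time).

Calibration classifies each detection in a dark stack by its signature —
consecutive fires at a pixel → afterpulse; simultaneous adjacent fires →
crosstalk, with afterpulse taking priority — and estimates per-pixel maps
from event-count ratios, by default passing them through an analytic
moment inversion that removes chance-coincidence and pair-double-counting
bias (see `docs/methods.md`).

A *b*-bit SPAD image is the sum of `2^b` one-bit subframes (1024 subframes
for 10-bit depth). The enhancement network lifts the normalized counts to
features with a shallow convolutional extractor F₀, refines them with *n*
densely connected Swin-transformer blocks Fᵢ = H_DCSTB(F₀, …, Fᵢ₋₁), fuses
the block outputs with learnable scalar gates F_DF = Σ wᵢFᵢ, and
reconstructs I_R = H_REC(F₀ + F_DF) with sub-pixel (pixel-shuffle)
upsampling. Training minimises the hybrid loss
`α·L1 + β·‖φ(I_R) − φ(I_G)‖₂ + γ·(1 − SSIM)` with defaults α=0.1, β=10,
γ=100, using Adam (β₁=0.5, β₂=0.999, weight decay 5·10⁻⁵) at an initial
learning rate 3·10⁻⁴ decayed by 10% every 100 epochs. The network runs on a
compact reverse-mode autodiff core (`spadkit.nn.autodiff`) over numpy, so
there is no deep-learning framework dependency.

## Worked example

`examples/` contains one short script per capability. Calibration
(`examples/calibrate_dark_frames.py`) simulates 20,000 dark frames on a
32×32 sensor with known parameters and recovers them:

```
simulated 20000 dark frames, mean firing rate 0.00564 per pixel per frame
dark-count expectation  true 0.0050  recovered 0.0050
afterpulse probability  true 0.0800  recovered 0.0790
crosstalk probability   true 0.0100  recovered 0.0102
```

The firing rate (0.00564) exceeds the bare dark rate (1 − e^−0.005 ≈
0.00499) because afterpulsing and crosstalk multiply events; the calibration
separates the three sources back out to within about 1% here.

Training (`examples/train_and_enhance.py`) synthesizes noisy 4-bit,
low-flux measurements of 8 phantom scenes and trains the tiny default model
for 200 steps:

```
hybrid loss 98.8 -> 23.5 (76% reduction over 200 steps)
PSNR on training scenes: enhanced 15.2 dB vs nearest-neighbour 10.3 dB
```

The enhanced output beats pixel-replication upsampling by ~5 dB because the
network denoises the 16-subframe quantisation and corrects the dim-flux
intensity scale while doubling resolution.

A thin CLI wraps the same library calls:

```bash
spadkit simulate --shape 64x32 --n-frames 60000 --dcr 0.005 --seed 1 --out dark.tiff
spadkit calibrate --dark dark.tiff --out calib/
spadkit synth --phantoms 4 --scales 2,4 --bits 4,8 --seed 0 --out data/
spadkit train --data data/manifest.json --steps 200 --out ckpt/model
spadkit enhance --in img.png --ckpt ckpt/model --out out.png
spadkit eval --pairs data/manifest.json --ckpt ckpt/model --out report.json
```

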