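# Methods

This note records the models, estimators, numerical choices and known
limitations behind `spadkit`, in the order data flows through the package.

## Forward noise model

A SPAD pixel reports one bit per integration window. The simulator composes
events per frame in a fixed order — primary (shot + dark), afterpulse,
crosstalk — and ORs them into the frame value.

- **Shot noise.** Photon arrivals in a window are Poisson(χ). Detection
  efficiency η acts per incoming photon, i.e. binomial thinning, so detected
  arrivals are Poisson(η·χ) and the one-bit detection probability is
  `p_det = 1 − exp(−η·χ)`. The thinned-Poisson coupling is a modelling
  choice: η is defined as a per-photon probability, and thinning is the
  unique memoryless way to apply it.
- **Dark counts.** Poisson with per-frame expectation λ_dcr; on a one-bit
  sensor this collapses to a Bernoulli event with probability
  `1 − exp(−λ_dcr)` (at most one count per window).
- **Afterpulsing.** Fixed per-pixel probability `p_ap`, conditioned on the
  same pixel's *final* value in the previous frame, with exactly one frame
  of memory; frame 0 has none. Time-decaying afterpulse models
  (power-law/exponential) are deliberately out of scope: the calibration
  target is a fixed probability map.
- **Crosstalk.** Each 4-connected neighbour whose primary or afterpulse
  event fired in the same frame independently triggers the receiving pixel
  with the *receiver's* `p_ct`; contributions combine by OR. Crosstalk is
  single-pass — crosstalk events do not seed further crosstalk — avoiding a
  fixed-point iteration within a frame; at realistic rates the neglected
  chains are second order. The neighbourhood is configurable to
  8-connected, and the classifier always uses the same neighbourhood as the
  simulator for self-consistency.
- **Deadtime.** Never simulated as an event source. `validate_timing`
  enforces the regime `frame_period ≥ integration + dead`, in which
  quenching cannot suppress events in the next window. The reference
  timing (20 ns integration, 60 ns dead, 80 ns readout) satisfies this; the
  frame period is free configuration.

**Reproducibility.** Frame *n* draws from its own counter-derived Philox
substream keyed by `(seed, n)`, in a fixed draw order (dark, shot,
afterpulse, four crosstalk directions). Stacks are therefore bit-identical
across runs and platforms for a fixed seed, and independent of whether
other frames are simulated.

## Dark-frame calibration

Dark stacks contain only dark counts, afterpulsing and crosstalk. Each
detection is classified by signature: `i_ap(x,y,n) = 1` iff the pixel fired
in frames n−1 and n; `i_ct(x,y,n) = 1` iff the pixel fired together with a
4-neighbour in the same frame *and* was not classified afterpulse
(afterpulsing is typically 1–2 orders of magnitude more probable than
crosstalk, so ambiguous events go to the afterpulse class; this priority
rule makes the classes disjoint). The raw per-pixel estimators are
event-count ratios over clean (residual) events:

    p_ap = Σ i_ap / Σ(I − i_ap − i_ct)
    p_ct = Σ i_ct / Σ(I − i_ap − i_ct)
    rate = Σ(I − i_ap − i_ct) / n_total

with 0/0 defined as 0 (a pixel that never fires cleanly gives no evidence),
values clipped to [0,1] with a warning, and `n_total` defaulting to 60,000
frames. The crosstalk denominator is read as the same per-frame sum as the
afterpulse one.

**Bias correction (default).** The raw ratios are biased whenever the true
probabilities are comparable to the per-frame firing rate: two independent
dark counts in consecutive frames mimic an afterpulse (additive bias ≈ the
firing rate), and the crosstalk ratio is worse — chance adjacencies occur
at rate ≈ 4q² while a true pair at per-neighbour probability `p_ct` occurs
at ≈ 4·q·p_ct *and is counted at both pixels*. At q ≈ 0.005 and
p_ct = 0.01 the raw ratio overshoots tenfold. `calibrate_from_dark`
therefore inverts the first-order expectations of the observed rates —
f (any fire), A (afterpulse-classified), C (crosstalk-classified):

    f = d + f·a + c·S            (S: neighbour sum of seed rates)
    A = f·a + f²(1−a)²           (true afterpulse + chance repeat)
    C = (1 − A/f)·(f·F + c·S + s·C′)

where `s = f − c·S` is the seed rate, `F` the neighbour sum of f (chance
adjacency), `c·S` the received and `s·C′` the emitted half of each true
pair, and the leading factor accounts for the afterpulse priority rule.
The per-pixel fixed point is solved with relaxation (damping 0.5, 40
iterations — the emitted-pair coupling has unit gain, so the undamped
iteration oscillates), clipping each map to [0,1]. Simulated recovery at
λ=0.005, p_ap=0.08, p_ct=0.01 with 60,000 frames lands within ~1% on all
three spatial means. `debias=False` returns the raw ratios.

The DCR map is stored as the Poisson expectation `λ = −log(1 − rate)`,
inverting the one-bit Bernoulli conversion, so a recovered calibration can
be fed straight back into the simulator. PDE is unobservable in darkness
and comes from configuration (default all-ones).

## Dataset synthesis

Scenes are cropped to a square (512 default), converted to grayscale with
Rec. 709 luminance weights (SPADs are monochrome), normalized to [0,1], and
downsampled by integer scales (2/4/8/16) with **area averaging** — chosen
over bicubic because a large SPAD pixel integrates the photon flux of the
scene area it covers. Normalized intensity maps to flux linearly,
χ = φ·intensity, with named levels low/mid/high = 0.5/1/2 photons per
window standing in for a 10/20/40 mW illumination ladder (flux proportional
to power; no absolute radiometric calibration is claimed). Each pair then
simulates `2^b` subframes with the calibrated model and accumulates them.
The grid of scales × bit depths × flux levels is configuration; no
canonical dataset size is hard-coded. Procedural phantoms (bar groups with
known widths, disks, edges, smooth gradients) replace natural-image
corpora so everything is generated at run time from a seed.

What the phantoms do *not* emulate: natural-image texture statistics,
coherent speckle from laser illumination, optical blur, and scene motion.
Tests passing on phantoms demonstrate the pipeline's correctness and the
network's trainability, not natural-image restoration quality.

## Enhancement network

Input is the normalized count image (counts / 2^b) in [0,1], NCHW. The
shallow extractor is conv(3×3) → batch-norm → GELU → conv(3×3), lifting
c_in = 1 to the embed dim c. Each densely connected block concatenates all
earlier feature maps on the channel axis and projects back to c with a 1×1
convolution (the merge operator for dense connections), then applies
`layers_per_block` Swin layers: pre-norm window attention (softmax over
keys, per-head scaling 1/√d) plus a GELU MLP, each residual. Odd layers
cyclically shift the map by half a window. Two simplifications relative to
a full Swin stack, adequate at the package's scale and documented as such:
no relative-position bias, and shifted windows attend across the periodic
boundary rather than being masked. Gates are unconstrained scalars
initialized to 1/n (a plain average before training). Reconstruction is
conv → (conv → 2× pixel-shuffle)^log₂(s) → conv; allowed scales are
1, 2, 4. All parameters live in float64 numpy arrays on a small
reverse-mode autodiff core written for this package (tape of closures,
topological-sort backward, im2col convolution); at these model sizes CPU
float64 is cheap and makes gradient checks tight.

**Loss.** `α·L1 + β·perceptual + γ·(1 − SSIM)` with α=0.1, β=10, γ=100.
The perceptual distance is `sqrt(mean((φ(a) − φ(b))²))` — an L2 feature
distance normalized by feature count so it is resolution-independent. The
default φ is a fixed-seed two-layer random convolutional stack (random
features are a serviceable perceptual metric and need no pretrained
weights); any callable extractor can be plugged in, e.g. a VGG19-pool3
adapter where such weights exist. The differentiable SSIM uses the standard
11×11 Gaussian window (σ=1.5, K1=0.01, K2=0.03), valid-mode windows only;
it agrees with scikit-image's implementation to machine precision, which
the tests assert as an independent cross-check.

**Training.** Adam with β₁=0.5, β₂=0.999, L2 weight decay 5·10⁻⁵, batch
size 24 (capped at the dataset size), initial learning rate 3·10⁻⁴ stepped
down 10% every 100 epochs. The loop is fully seeded (parameter init, batch
order); a non-finite loss aborts with the step and learning rate.
Checkpoints are an `.npz` of parameters and running statistics plus a JSON
echo of the architecture.

**Problem sizes.** The default/tested configuration is deliberately small —
embed dim 16, 2 blocks × 2 layers, window 4, 16×16 inputs at scale 2,
8 scenes, 200 steps — the scale at which the training dynamics (≥50% hybrid
loss reduction, and enhanced PSNR above nearest-neighbour upsampling on the
training scenes under dim, 4-bit conditions) are demonstrable in about a
minute. Absolute benchmark quality on natural images requires
corpus-scale training and is expressly not claimed.

## Evaluation

PSNR is `10·log10(data_range²/MSE)`, with identical images reported as a
100 dB sentinel. SSIM is delegated to scikit-image with the same window
settings as the loss. The default convention for b-bit images is to
normalize counts by 2^b and use data_range = 1 (data_range = 2^b on raw
counts is equivalent). Angular rates measured from microsecond frame
sequences convert as `rpm = ω·10⁶·60/(2π)`, rounded to the nearest
thousand by default.

## Coordinates and formats

Arrays are (row = y, col = x), 0-based, origin top-left; stacks are
(frame, row, col) with frames from 0. Stacks are stored as multi-page
TIFF (uint8 0/1) with a JSON sidecar (shape, frame count, seed, timing)
validated on read; calibrations as float32 TIFF maps plus a JSON summary;
datasets as PNG ground truth, `.npy` count images and a JSON manifest
carrying every per-pair seed.

## Known limitations

- No time-stamped (TCSPC) arrival simulation, no wavelength-dependent PDE,
  no coherent speckle.
- The bias-corrected calibration is first-order in the per-frame rates;
  at very high dark rates (≳0.1 per frame) the neglected higher-order
  terms matter.
- The crosstalk neighbourhood is a modelling choice (4-connected default);
  classification must use the same neighbourhood as the data-generating
  sensor for the inversion to be consistent.
- Attention masking for shifted windows and relative-position bias are
  omitted; for large windows on real imagery these refinements are known
  to help.
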