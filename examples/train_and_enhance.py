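"""Train the tiny gated-fusion transformer and enhance a SPAD measurement.

Synthesizes noisy 4-bit, low-flux measurements of 8 phantom scenes at 16x16,
trains a small model for 200 steps with the hybrid L1 + perceptual + SSIM
loss, and compares the enhanced output against plain nearest-neighbour
upsampling on the training scenes.
"""

import numpy as np

import spadkit as sk
from spadkit.metrics import nearest_neighbor_upsample, psnr
from spadkit.nn import NetworkConfig, enhance, train

calib = sk.SensorCalibration(pde=1.0, dcr=0.005, p_ap=0.08, p_ct=0.01,
                             shape=(16, 16))
pairs = []
for i, hr in enumerate(sk.generate_phantoms(8, size=32, seed=3)):
    pair = sk.synthesize_pair(hr, scale=2, calib=calib, bit_depth=4,
                              phi=0.5, seed=100 + i)
    pairs.append((pair.measurement.normalized(), hr))

cfg = NetworkConfig(embed_dim=16, n_blocks=2, layers_per_block=2,
                    window_size=4, n_heads=2, sr_scale=2)
result = train(pairs, cfg, seed=0, n_steps=200)
print(f"hybrid loss {result.initial_loss:.1f} -> {result.final_loss:.1f} "
      f"({100 * (1 - result.final_loss / result.initial_loss):.0f}% reduction "
      f"over 200 steps)")

net = np.mean([psnr(enhance(lq, result.model), hr) for lq, hr in pairs])
base = np.mean([psnr(nearest_neighbor_upsample(lq, 2), hr) for lq, hr in pairs])
print(f"PSNR on training scenes: enhanced {net:.1f} dB vs "
      f"nearest-neighbour {base:.1f} dB")
print("The gain comes from denoising the 16-subframe quantisation and "
      "correcting the dim-flux intensity scale while doubling resolution.")
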