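"""Image-quality metrics and the high-speed angular-rate conversion.

Computes PSNR and SSIM between a clean phantom and a noisy copy, and
converts a rotation rate measured from microsecond-interval SPAD frames
(rad/us) into revolutions per minute.
"""

import numpy as np

import spadkit as sk
from spadkit.metrics import psnr, rad_per_us_to_rpm, ssim

clean = sk.generate_phantoms(1, size=64, seed=1)[0]
noisy = np.clip(clean + np.random.default_rng(0).normal(0, 0.1, clean.shape),
                0, 1)
print(f"PSNR(noisy, clean) = {psnr(noisy, clean):.2f} dB "
      "(10 dB per factor-10 drop in mean squared error)")
print(f"SSIM(noisy, clean) = {ssim(noisy, clean):.3f} "
      "(1.0 means structurally identical)")

omega = 0.0107  # rad/us, e.g. a fan blade tracked across microsecond frames
print(f"{omega} rad/us = {rad_per_us_to_rpm(omega):,.0f} RPM "
      "(rounded to the nearest thousand)")
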