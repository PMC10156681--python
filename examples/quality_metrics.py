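"""The six-metric quality suite on a controlled pair of images.

Compares a phantom with a noisy copy of itself, per RGB channel and
channel-averaged, illustrating how each metric responds to pure noise.
"""

import numpy as np

from retilume import generate, report, spec_for_preset

image, _ = generate(spec_for_preset("red", seed=3))
rng = np.random.default_rng(0)
noisy = np.clip(image.astype(float) + rng.normal(0, 15, image.shape), 0, 255).astype(np.uint8)

rep = report(image, noisy, image_id="noise_sigma_15")
print("metric      R        G        B        mean")
for name in ("mse", "psnr", "ssim", "pearson_r1", "uqi"):
    r, g, b = rep.per_channel[name]
    print(f"{name:<10s} {r:8.3f} {g:8.3f} {b:8.3f} {getattr(rep, name):9.3f}")
print(f"entropy: input {rep.entropy_input:.3f} bits, noisy {rep.entropy_output:.3f} bits")
print()
print("Additive sigma=15 noise costs ~200 MSE per channel (~25 dB PSNR; clipping at")
print("0/255 trims the nominal 225); correlation stays high, and entropy rises")
print("because the noise spreads the histogram.")
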