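# retilume

Color-dominance-driven enhancement of retinal fundus photographs.

Fundus images straddle two color regimes: red-dominant retinas (healthy,
hemorrhagic, pigmented) and pale ones (media haze, myopia, optic-disc
pallor). Enhancing a fixed channel — the usual green-channel or
luminosity-channel CLAHE — throws away chromatic detail in whichever regime
it was not tuned for. `retilume` instead measures the population variance of
the blue channel,

σ² = (1/mn) · ΣᵢΣⱼ [X(i,j) − μ]²,

and picks the CIELAB chroma plane to equalize: red-dominant images
(σ² ≤ θ, default θ = 1500) carry little blue signal and are enhanced on the
a\* (red–green) axis; pale images (σ² > θ) on the b\* (yellow–blue) axis.
The full pipeline is

1. **Crop** the square retinal field of view (luminance-threshold mask).
2. **Stage 1** — convert to CIELAB via the fixed RGB↔XYZ matrices, apply
   contrast-limited adaptive histogram equalization (CLAHE) to the selected
   chroma plane only, convert back.
3. **Stage 2** — CLAHE on the green channel, edge-preserving bilateral
   denoising with weights
   w(i,j) = exp(−‖pᵢ−pⱼ‖²/2σ_d²) · exp(−(Xᵢ−Xⱼ)²/2σ_r²),
   then an automatic brightness/contrast stretch out = clamp(α·in + β).

The package also ships the six-metric full-reference quality suite used to
evaluate such pipelines — MSE, PSNR, SSIM, Pearson r₁, Shannon entropy and
the universal quality index (UQI), each computed per RGB channel and
averaged — and a seeded synthetic fundus phantom generator so every stage
is testable without any image downloads.

## Worked example

```sh
python examples/enhance_phantom.py
```

```
dominance: sigma^2 = 365.5 (theta = 1500) -> a_star
crop: side 256 px at offset (0, 0)

MSE         2226.38   (mean squared change, gray-level^2)
PSNR          18.57   (dB; lower = stronger modification)
SSIM          0.699   (structural similarity retained)
Pearson       0.958   (linear correlation with the input)
UQI           0.811   (correlation x luminance x contrast)
entropy   5.513 -> 5.735 bits (information content increases)
```

The phantom's blue variance (365.5) is below θ, so it is classified
red-dominant and the a\* plane is equalized. The metrics compare the
cropped input against the final output: high Pearson correlation and UQI
say the enhancement preserved structure and luminance relationships, while
the entropy rise from 5.51 to 5.74 bits quantifies the contrast gained.
The other scripts in `examples/` demonstrate the dominance rule on the
observed variance continuum, phantom generation in both regimes, and the
metric suite's per-channel behaviour under controlled noise.

The same pipeline is scriptable from the shell:

```sh
retilume phantom --preset red --n 10 --seed 7 --out phantoms/
retilume enhance --in 'phantoms/*.png' --out enhanced/ --report report.csv
retilume metrics --ref phantoms/ --test enhanced/ --report m.csv
```

`enhance` writes one `<stem>.enhanced.png` per input plus a CSV with the
per-image dominance decision and metrics, and a final mean row.

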