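# Methods

## The dominance rule

The decision statistic is the population variance of the blue channel of
the cropped image, on the 0–255 scale with divisor mn (not mn−1).
Red-dominant fundus images concentrate energy in the red channel and carry
little blue signal, so their blue variance is low; pale fundi (media haze,
myopia, pallor) reflect much more blue and score high. The threshold
θ = 1500 separates the regimes; it is exposed in `EnhanceConfig.theta`
because it is an empirical constant for fundus photographs and other
camera/dataset combinations may need retuning. The boundary σ² = θ is
classified red-dominant (the rule is a non-strict ≤), selecting a\*.
Variance is computed on the square crop *including* its residual dark
corners — the corners are part of what makes the statistic discriminative,
since they contribute a bimodal component proportional to the square of
the field-of-view's blue level.

## Color space

The RGB↔XYZ transforms use one fixed matrix pair (and its inverse)
applied to channel values linearly scaled to [0, 1]; no sRGB gamma
companding is applied by default, so the matrices alone define the
transform (a `gamma=True` flag applies sRGB companding for users who want
colorimetric sRGB behaviour). The Lab transform uses the CIE piecewise
function f(t) = t^⅓ for t > (6/29)³ and 4/29 + t·(29/6)²/3 otherwise.
The reference white defaults to the row sums of the forward matrix,
(0.950456, 1.000000, 1.088754) — numerically the D65 white — which
guarantees that RGB white maps exactly to (L, a\*, b\*) = (100, 0, 0) and
every gray is exactly achromatic. Out-of-gamut values produced when
enhanced chroma is converted back to RGB are clamped silently (enhancement
legitimately pushes chroma outside the cube); the clamp count is emitted on
the module logger at DEBUG level.

For CLAHE the real-valued chroma planes are embedded into 8 bits by the
+128 offset convention (clamped to [0, 255], rounded half away from zero)
and restored by the exact inverse after equalization. The embedding
quantizes chroma to one gray step; near black this single step can move
Lab coordinates by a few units because f is steep there, which is why
plane-preservation checks are stated in RGB (bit-exact composition) rather
than as a uniform Lab tolerance.

## CLAHE

Implemented from first principles on 8-bit planes: the plane is
reflect-padded to a multiple of the tile size, per-tile histograms are
computed on `bins` bins, clipped at `clip_limit × tile_pixels / bins` with
the excess redistributed uniformly over all bins, and each tile's
equalization mapping is gray → 255·cdf(gray). Output pixels bilinearly
interpolate the four surrounding tile mappings, which removes tile seams.
Defaults are clip_limit 2.0, 8×8 tiles, 256 bins for both stages — the
ubiquitous convention; all are exposed in `ClaheParams`. Two consequences
of the plain-cdf mapping worth knowing: a constant plane maps to a
constant plane whose level may shift by up to ⌈255·clip/bins⌉+1 gray
levels (the clipped spike still advances the cdf), and with one tile and
an unbounded clip the mapping reduces to global histogram equalization.

## Bilateral filter

The filter is the textbook normalized weighted mean over a
(2·radius+1)² neighborhood with weights
exp(−‖pᵢ−pⱼ‖²/2σ_d²)·exp(−(Xᵢ−Xⱼ)²/2σ_r²), computed per RGB channel with
reflected borders. Defaults σ_d = 3 px, σ_r = 50 gray levels, radius = 4
(9×9 window) give mid-strength denoising that preserves vessel edges.
Applying it per channel (rather than on a joint color distance) is a
documented choice; the per-channel form is what the weight definition
describes for scalar intensities. The implementation is a vectorized
shift-and-accumulate; tests pin it to a literal double-loop evaluation to
1e−9 and to its σ_r→∞ Gaussian limit to 1e−3.

## Automatic brightness/contrast

The gain α and bias β are derived by percentile histogram clipping on the
channel-mean gray image: the lowest (lo) and highest (hi) gray levels
whose cumulative/tail mass exceeds `clip_percent` (default 0.01 per tail)
define the stretch α = 255/(hi − lo), β = −α·lo, applied identically to
all channels with clamping. This is the standard "auto brightness and
contrast" construction and is a declared stand-in: the gain/bias step of
the pipeline is specified only descriptively, so the percentile-clipping
form was adopted as the conventional realization. A constant image yields
the identity mapping with a logged warning.

Stage-2 order is fixed as green-CLAHE → merge → bilateral → gain/bias.

## Metrics

All pairwise metrics use population moments, consistent with the variance
statistic. PSNR's peak defaults to R = 255 (the standard reading that
keeps values comparable across images; per-image `peak` is a parameter).
SSIM internals: 8×8 uniform sliding window, stride 1, K1 = 0.01,
K2 = 0.03, dynamic range 255, mean-pooled over fully contained windows.
UQI is the global single-window three-factor product (correlation ×
luminance distortion × contrast distortion), not the sliding-window
variant. Entropy is reported once per image on the rounded channel-mean
gray plane, giving one H value per image. Degenerate inputs return
sentinels rather than raising: PSNR of identical planes is +inf, Pearson
and UQI of constant planes are NaN with a warning.

## Synthetic phantoms

The generator emulates exactly the features the pipeline responds to: a
bright circular field of view inscribed in a dark square (so the crop and
the corner-driven variance statistic are exercised), a base color on the
red-to-pale continuum, a bright elliptical optic disc, a dark vessel tree
grown by seeded recursive midpoint-displacement branching with width
decay, optional bright/dark lesion disks, a multiplicative radial
illumination falloff and additive Gaussian pixel noise. One
`numpy.random.default_rng(seed)` instance drives everything, so a spec is
a complete, reproducible recipe and the ground-truth record (FOV and disc
geometry) can regenerate the FOV mask exactly.

Preset study conditions (fixed once): 256×256 phantoms; red preset base
RGB (175, 70, 38) with illumination amplitude 0.25; pale preset
(235, 205, 150) with amplitude 0.30; background (8, 8, 8); noise σ = 3;
6 vessels of depth 3; 3 lesions. Dominance is controlled by the blue
contrast between the field of view and the dark corners — the red base
yields blue variances of roughly 350–390 (inside the observed red-dominant
range), the pale base roughly 2650–2710, comfortably above θ. The narrow
dynamic range of both bases is what makes the phantoms low-contrast, so
the pipeline's entropy-raising direction is testable on them.

What the phantoms are not: hemodynamically plausible vasculature,
pathology-specific lesion morphology, camera PSF/vignetting models, or
look-alikes of any real dataset. Passing tests on phantoms demonstrates
the pipeline's contracts (channel selection, plane isolation, determinism,
entropy direction), not clinical image quality; absolute metric values on
real fundus photographs will differ, and CLAHE/crop parameters may need
dataset-specific tuning.

## Numerical choices

- 8-bit quantization rounds half away from zero everywhere.
- All intermediate arithmetic is float64; images are uint8 at stage
  boundaries.
- `bilateral_filter` preserves float input unrounded (for oracle
  comparisons) and rounds integer input back to uint8.
- Cropping slides the square window inside the image borders; for
  elongated images whose mask cannot fit a square, the window is centred
  on the mask and capped at min(height, width).
- Acceptance-scale problem sizes: 10,000 random pixels for round-trip
  checks, fifty 4×4 planes for the bilateral oracle, twenty 8×8 plane
  pairs for metric oracles, fifty 256×256 phantoms for the pipeline-level
  entropy direction. These sizes make the whole verification suite run in
  well under a minute while keeping every check statistically meaningful.

## Known limitations

- The equalization mapping's constant-plane level shift (above) means
  CLAHE is near-identity, not identity, on flat regions.
- The gamut clamp after Stage 1 perturbs all three Lab planes at clamped
  pixels; the untouched-plane guarantee is exact only up to that clamp and
  8-bit quantization.
- θ = 1500 is an empirical constant for fundus photography; no automatic
  calibration is provided.
- The gain/bias construction is a conventional stand-in for a step that is
  specified only descriptively (see above).
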