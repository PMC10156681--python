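"""The two-stage fundus enhancement pipeline.

Stage 1 selects the CIELAB chroma plane by the blue-variance dominance rule
(a* for red-dominant images, b* otherwise) and applies contrast-limited
adaptive histogram equalization (CLAHE) to that plane only; the other two
Lab planes are untouched.  Stage 2 works on the resulting RGB image: CLAHE
on the green channel (the channel most proportional to lightness), an
edge-preserving bilateral filter for noise removal, and an automatic
gain/bias brightness–contrast stretch.

CLAHE and the bilateral filter are implemented here rather than delegated,
because the pipeline's contracts pin their exact conventions: per-tile
histograms clipped at ``clip_limit × tile_pixels / bins`` with uniform
redistribution of the excess and bilinear interpolation of the tile
mappings, and the textbook bilateral weight
``exp(−‖p_i−p_j‖²/2σ_d²)·exp(−(X[i]−X[j])²/2σ_r²)`` with reflected borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import colorspace
from .colorspace import D65_WHITE, WhitePoint
from .dominance import (
    A_STAR,
    DEFAULT_THETA,
    CropResult,
    DominanceResult,
    blue_channel_variance,
    crop_square_retina,
    select_chroma_channel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClaheParams",
    "BilateralParams",
    "BrightnessContrastParams",
    "EnhanceConfig",
    "EnhanceResult",
    "clahe",
    "stage1_enhance",
    "bilateral_filter",
    "compute_gain_bias",
    "apply_gain_bias",
    "stage2_enhance",
    "enhance_image",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE tunables.

    clip_limit
        Histogram clip level as a multiple of the uniform bin count
        ``tile_pixels / bins``.
    tile_grid
        (rows, cols) of the tile lattice.
    bins
        Histogram bin count (256 = one bin per 8-bit gray level).
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)
    bins: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if min(self.tile_grid) < 1:
            raise ValueError("tile grid dimensions must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


@dataclass(frozen=True)
class BilateralParams:
    """Bilateral-filter tunables: spatial σ_d (pixels), range σ_r (gray
    levels) and neighborhood half-width ``radius`` ((2r+1)² window)."""

    sigma_d: float = 3.0
    sigma_r: float = 50.0
    radius: int = 4

    def __post_init__(self) -> None:
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_d and sigma_r must be positive")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


@dataclass(frozen=True)
class BrightnessContrastParams:
    """Affine brightness/contrast mapping out = clamp(alpha·in + beta)."""

    alpha: float
    beta: float
    clip_percent: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha (gain) must be positive")


@dataclass(frozen=True)
class EnhanceConfig:
    """Every tunable of the two-stage pipeline."""

    theta: float = DEFAULT_THETA
    crop_luminance_threshold: float = 0.04
    stage1_clahe: ClaheParams = field(default_factory=ClaheParams)
    stage2_clahe: ClaheParams = field(default_factory=ClaheParams)
    bilateral: BilateralParams = field(default_factory=BilateralParams)
    clip_percent: float = 0.01
    white: WhitePoint = D65_WHITE
    keep_intermediates: bool = False


@dataclass(frozen=True)
class EnhanceResult:
    """Final image plus provenance of one pipeline run."""

    image: np.ndarray
    dominance: DominanceResult
    crop: CropResult
    intermediates: dict[str, np.ndarray] | None = None


# --------------------------------------------------------------------------
# CLAHE
# --------------------------------------------------------------------------


def clahe(plane: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one 8-bit plane.

    Per tile: histogram on ``bins`` bins, clipped at
    ``clip_limit × tile_pixels / bins`` with the excess redistributed
    uniformly over all bins, then the equalization mapping
    ``gray → 255 · cdf(gray)``.  Pixel values are produced by bilinear
    interpolation of the four surrounding tile mappings, so tile seams are
    invisible.  The plane is reflect-padded up to a multiple of the tile
    size before tiling.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError(f"expected a 2-D plane, got shape {plane.shape}")
    if plane.min() < 0 or plane.max() > 255:
        raise ValueError("plane values must lie in [0, 255]")
    h, w = plane.shape
    tr, tc = params.tile_grid
    if h < tr or w < tc:
        raise ValueError(f"plane {plane.shape} smaller than tile grid {params.tile_grid}")

    bins = params.bins
    th = -(-h // tr)  # ceil
    tw = -(-w // tc)
    padded = np.pad(
        plane.astype(np.int64), ((0, th * tr - h), (0, tw * tc - w)), mode="reflect"
    )
    bin_idx = padded * bins // 256
    tile_pixels = th * tw

    # per-tile histograms in one bincount
    tile_row = np.repeat(np.arange(tr), th)[:, None]
    tile_col = np.repeat(np.arange(tc), tw)[None, :]
    tile_id = tile_row * tc + tile_col
    flat = (tile_id * bins + bin_idx).ravel()
    hist = np.bincount(flat, minlength=tr * tc * bins).reshape(tr, tc, bins).astype(float)

    limit = params.clip_limit * tile_pixels / bins
    excess = np.clip(hist - limit, 0.0, None).sum(axis=2, keepdims=True)
    hist = np.minimum(hist, limit) + excess / bins

    cdf = np.cumsum(hist, axis=2) / tile_pixels
    lut = 255.0 * cdf  # (tr, tc, bins), float mapping

    # bilinear interpolation between tile-centre mappings
    ph, pw = padded.shape
    fy = np.clip((np.arange(ph) + 0.5) / th - 0.5, 0.0, tr - 1.0)
    fx = np.clip((np.arange(pw) + 0.5) / tw - 0.5, 0.0, tc - 1.0)
    y0 = np.minimum(fy.astype(int), tr - 1)
    x0 = np.minimum(fx.astype(int), tc - 1)
    y1 = np.minimum(y0 + 1, tr - 1)
    x1 = np.minimum(x0 + 1, tc - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    b = bin_idx
    y0g = y0[:, None]
    y1g = y1[:, None]
    x0g = x0[None, :]
    x1g = x1[None, :]
    out = (
        (1 - wy) * (1 - wx) * lut[y0g, x0g, b]
        + (1 - wy) * wx * lut[y0g, x1g, b]
        + wy * (1 - wx) * lut[y1g, x0g, b]
        + wy * wx * lut[y1g, x1g, b]
    )
    out = _round_half_away(np.clip(out[:h, :w], 0.0, 255.0))
    return out.astype(np.uint8)


# --------------------------------------------------------------------------
# Stage 1
# --------------------------------------------------------------------------


def stage1_enhance(
    image: np.ndarray, config: EnhanceConfig = EnhanceConfig()
) -> tuple[np.ndarray, DominanceResult]:
    """Dominance-selected chroma-plane CLAHE in CIELAB.

    The blue-channel variance picks a* (σ² ≤ θ) or b* (σ² > θ); that plane
    is embedded into 8-bit by the +128 offset convention, equalized with
    CLAHE, restored, and merged with the two untouched Lab planes before
    converting back to RGB.
    """
    sigma_sq = blue_channel_variance(image)
    dom = select_chroma_channel(sigma_sq, config.theta)
    lab = colorspace.rgb_to_lab(image, config.white)
    idx = 1 if dom.selected_channel == A_STAR else 2
    embedded = colorspace.lab_chroma_to_uint8(lab[..., idx])
    equalized = clahe(embedded, config.stage1_clahe)
    lab[..., idx] = colorspace.uint8_to_lab_chroma(equalized)
    return colorspace.lab_to_rgb(lab, config.white), dom


# --------------------------------------------------------------------------
# Bilateral filter
# --------------------------------------------------------------------------


def _bilateral_plane(plane: np.ndarray, params: BilateralParams) -> np.ndarray:
    r = params.radius
    h, w = plane.shape
    padded = np.pad(plane, r, mode="reflect")
    inv_2sd = 1.0 / (2.0 * params.sigma_d**2)
    inv_2sr = 1.0 / (2.0 * params.sigma_r**2)
    num = np.zeros_like(plane)
    den = np.zeros_like(plane)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            spatial = np.exp(-(di * di + dj * dj) * inv_2sd)
            shifted = padded[r + di : r + di + h, r + dj : r + dj + w]
            weight = spatial * np.exp(-((shifted - plane) ** 2) * inv_2sr)
            num += weight * shifted
            den += weight
    return num / den


def bilateral_filter(image: np.ndarray, params: BilateralParams = BilateralParams()) -> np.ndarray:
    """Edge-preserving bilateral smoothing, applied independently per channel.

    Each output pixel is the weighted mean of its (2·radius+1)² reflected
    neighborhood, weights being the product of a spatial Gaussian (σ_d) and
    a photometric Gaussian on the intensity difference to the centre pixel
    (σ_r).  Integer input is returned rounded back to 8-bit; float input is
    returned unrounded (useful for numerical comparisons).
    """
    arr = np.asarray(image)
    work = arr.astype(np.float64)
    if work.ndim == 2:
        out = _bilateral_plane(work, params)
    elif work.ndim == 3:
        out = np.stack(
            [_bilateral_plane(work[..., c], params) for c in range(work.shape[2])], axis=-1
        )
    else:
        raise ValueError(f"expected a 2-D plane or H×W×C image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)
    return out


# --------------------------------------------------------------------------
# Automatic brightness / contrast
# --------------------------------------------------------------------------


def compute_gain_bias(
    image: np.ndarray, clip_percent: float = 0.01
) -> BrightnessContrastParams:
    """Derive the gain α and bias β from the gray-image histogram.

    ``clip_percent`` of the pixel mass is discarded from each tail of the
    256-bin histogram of the channel-mean gray image; the surviving range
    [lo, hi] is stretched to [0, 255]: α = 255/(hi − lo), β = −α·lo.
    A constant image yields the identity mapping (α=1, β=0) with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if not 0.0 <= clip_percent < 0.5:
        raise ValueError("clip_percent must lie in [0, 0.5)")
    gray = image.astype(float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    gray = np.clip(_round_half_away(gray), 0, 255).astype(int)

    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    total = hist.sum()
    cdf = np.cumsum(hist) / total
    tail = 1.0 - np.concatenate(([0.0], cdf[:-1]))  # tail[k] = fraction of pixels >= k

    lo_candidates = np.flatnonzero(cdf > clip_percent)
    hi_candidates = np.flatnonzero(tail > clip_percent)
    lo = int(lo_candidates[0])
    hi = int(hi_candidates[-1])
    if hi <= lo:
        logger.warning("compute_gain_bias: degenerate histogram (hi <= lo); identity mapping")
        return BrightnessContrastParams(alpha=1.0, beta=0.0, clip_percent=clip_percent)
    alpha = 255.0 / (hi - lo)
    return BrightnessContrastParams(alpha=alpha, beta=-alpha * lo, clip_percent=clip_percent)


def apply_gain_bias(image: np.ndarray, params: BrightnessContrastParams) -> np.ndarray:
    """out = clamp(round(α·in + β), 0, 255), identically on all channels."""
    arr = np.asarray(image).astype(float)
    out = _round_half_away(params.alpha * arr + params.beta)
    return np.clip(out, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# Stage 2 and the full pipeline
# --------------------------------------------------------------------------


def stage2_enhance(
    image: np.ndarray,
    config: EnhanceConfig = EnhanceConfig(),
    *,
    return_intermediates: bool = False,
):
    """Green-channel CLAHE → bilateral denoising → automatic gain/bias.

    Only the green plane is equalized (red and blue pass through the CLAHE
    step unchanged); the bilateral filter and the brightness/contrast
    stretch then act on all channels.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    green_eq = image.copy()
    green_eq[..., 1] = clahe(image[..., 1], config.stage2_clahe)
    denoised = bilateral_filter(green_eq, config.bilateral)
    params = compute_gain_bias(denoised, config.clip_percent)
    final = apply_gain_bias(denoised, params)
    if return_intermediates:
        return final, {"stage2_green": green_eq, "stage2_bilateral": denoised}
    return final


def enhance_image(image: np.ndarray, config: EnhanceConfig = EnhanceConfig()) -> EnhanceResult:
    """Full pipeline: crop → Stage 1 (chroma CLAHE) → Stage 2 (green CLAHE,
    bilateral, gain/bias).

    Deterministic: the same image and config always produce bit-identical
    output.  ``config.keep_intermediates`` retains the per-stage images for
    inspection panels.
    """
    crop = crop_square_retina(image, config.crop_luminance_threshold)
    stage1, dom = stage1_enhance(crop.image, config)
    if config.keep_intermediates:
        final, inter = stage2_enhance(stage1, config, return_intermediates=True)
        intermediates = {"cropped": crop.image, "stage1": stage1, **inter, "final": final}
    else:
        final = stage2_enhance(stage1, config)
        intermediates = None
    return EnhanceResult(image=final, dominance=dom, crop=crop, intermediates=intermediates)
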