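"""Stage-1 front end: square field-of-view cropping and the color-dominance rule.

Fundus photographs are dominated either by reds (healthy, hemorrhagic,
pigmented retinas) or by pale yellows (media haze, myopic fundi, pallor).
The variance of the blue channel separates the two regimes: red-dominant
images carry little blue signal and hence low blue variance, pale images
carry much more.  A single threshold θ (default 1500, on the 0–255 gray
scale squared) picks the CIELAB chroma plane to enhance: a* (red–green
axis) when σ² ≤ θ, b* (yellow–blue axis) when σ² > θ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_THETA",
    "RetinaNotFoundError",
    "CropResult",
    "DominanceResult",
    "crop_square_retina",
    "blue_channel_variance",
    "select_chroma_channel",
]

DEFAULT_THETA = 1500.0

A_STAR = "a_star"
B_STAR = "b_star"
RED_DOMINANT = "red_dominant"
NON_RED_DOMINANT = "non_red_dominant"


class RetinaNotFoundError(ValueError):
    """Raised when no pixel clears the luminance threshold (all-dark image)."""


@dataclass(frozen=True)
class CropResult:
    """A square crop of the retinal field of view.

    ``row0``/``col0`` are the offsets of the crop in source coordinates and
    ``side`` its edge length; ``image`` is the cropped sub-image itself.
    """

    image: np.ndarray
    row0: int
    col0: int
    side: int


@dataclass(frozen=True)
class DominanceResult:
    """Outcome of the blue-variance dominance rule for one image."""

    sigma_sq: float
    theta: float
    selected_channel: str  # "a_star" or "b_star"
    dominance_label: str  # "red_dominant" or "non_red_dominant"


def crop_square_retina(image: np.ndarray, luminance_threshold: float = 0.04) -> CropResult:
    """Crop the square region containing the bright retinal field of view.

    A binary mask keeps pixels whose channel-mean luminance exceeds
    ``luminance_threshold`` (a fraction of full scale).  The bounding box of
    the mask is expanded symmetrically to a square, sliding inside the image
    borders when necessary; if the square cannot contain the full box (very
    elongated images) it is centred on the box and capped at
    ``min(height, width)``.

    Raises
    ------
    RetinaNotFoundError
        If no pixel clears the threshold.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    m, n = image.shape[:2]
    mask = image.astype(float).mean(axis=2) > luminance_threshold * 255.0
    if not mask.any():
        raise RetinaNotFoundError("no retina found: no pixel above the luminance threshold")

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1

    side = min(max(r1 - r0, c1 - c0), m, n)

    def _window(lo: int, hi: int, limit: int) -> int:
        # centre a window of length `side` on [lo, hi), clamped to [0, limit)
        start = (lo + hi - side) // 2
        return int(np.clip(start, 0, limit - side))

    row0 = _window(r0, r1, m)
    col0 = _window(c0, c1, n)
    crop = image[row0 : row0 + side, col0 : col0 + side]
    return CropResult(image=crop, row0=row0, col0=col0, side=side)


def blue_channel_variance(image: np.ndarray) -> float:
    """Population variance σ² = (1/mn)·ΣΣ[X(i,j) − μ]² of the blue plane.

    Computed on the 0–255 scale with divisor mn (not mn−1).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    blue = image[..., 2].astype(np.float64)
    return float(blue.var())


def select_chroma_channel(sigma_sq: float, theta: float = DEFAULT_THETA) -> DominanceResult:
    """Apply the dominance rule: σ² ≤ θ → red-dominant → a*; σ² > θ → b*.

    The boundary σ² = θ is red-dominant (the rule is a non-strict ≤).
    """
    if sigma_sq < 0:
        raise ValueError(f"variance must be non-negative, got {sigma_sq}")
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    if sigma_sq <= theta:
        return DominanceResult(float(sigma_sq), float(theta), A_STAR, RED_DOMINANT)
    return DominanceResult(float(sigma_sq), float(theta), B_STAR, NON_RED_DOMINANT)
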