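"""RGB ↔ CIE XYZ ↔ CIELAB conversions.

The transforms are implemented directly from the fixed 3×3 matrices and the
piecewise CIE lightness function, applied to linearly scaled channel values
in [0, 1] (no sRGB gamma companding by default, so the matrices are the
single source of truth).  The default reference white is the row-sum white
of the forward matrix, i.e. the D65-consistent point (0.950456, 1.000000,
1.088754); with that white, every gray maps to a* = b* = 0 and pure white
maps to L = 100 exactly.

Out-of-gamut values produced by the inverse transform (enhancement
legitimately pushes chroma outside the RGB cube) are silently clamped; the
number of clamped components is reported through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WhitePoint",
    "D65_WHITE",
    "RGB_TO_XYZ_MATRIX",
    "XYZ_TO_RGB_MATRIX",
    "rgb_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "xyz_to_rgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "lab_chroma_to_uint8",
    "uint8_to_lab_chroma",
]

#: Forward RGB→XYZ matrix (linear channel values in [0, 1]).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

#: Inverse XYZ→RGB matrix.
XYZ_TO_RGB_MATRIX = np.array(
    [
        [3.240479, -1.537150, -0.498535],
        [-0.969256, 1.875992, 0.041556],
        [0.055648, -0.204043, 1.057311],
    ]
)

# CIE piecewise-function knee: f switches branch at t = (6/29)^3.
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3


@dataclass(frozen=True)
class WhitePoint:
    """Reference-white tristimulus values (Xn, Yn, Zn), all strictly positive."""

    xn: float
    yn: float
    zn: float

    def __post_init__(self) -> None:
        if not (self.xn > 0 and self.yn > 0 and self.zn > 0):
            raise ValueError("white point tristimulus values must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.xn, self.yn, self.zn])


#: Row sums of the forward matrix — the white point under which RGB white
#: maps exactly to L=100, a*=b*=0.  Numerically the D65 white.
D65_WHITE = WhitePoint(0.950456, 1.000000, 1.088754)


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB image, got shape {image.shape}")
    if image.size == 0:
        raise ValueError("empty image")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return image


def _require_triplanar(image: np.ndarray, name: str) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 {name} image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError(f"{name} image contains non-finite values")
    return image


def _srgb_expand(u: np.ndarray) -> np.ndarray:
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def _srgb_compress(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, None)
    return np.where(u <= 0.0031308, 12.92 * u, 1.055 * u ** (1 / 2.4) - 0.055)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round ties to even; 8-bit quantization here rounds half away from zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def rgb_to_xyz(image: np.ndarray, *, gamma: bool = False) -> np.ndarray:
    """Convert an 8-bit RGB image to CIE XYZ tristimulus planes.

    Channels are scaled to [0, 1] and multiplied by the fixed forward
    matrix.  ``gamma=True`` additionally applies sRGB linearization before
    the matrix product (off by default: the plain matrix product is the
    documented behaviour).
    """
    rgb = _require_rgb(image).astype(float) / 255.0
    if gamma:
        rgb = _srgb_expand(rgb)
    return rgb @ RGB_TO_XYZ_MATRIX.T


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    cube_root = np.cbrt(np.clip(t, 0.0, None))
    linear = 4.0 / 29.0 + t * (1.0 / 3.0) * (29.0 / 6.0) ** 2
    return np.where(t > _DELTA3, cube_root, linear)


def _f_inv(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA, t**3, 3.0 * _DELTA**2 * (t - 4.0 / 29.0))


def xyz_to_lab(image: np.ndarray, white: WhitePoint = D65_WHITE) -> np.ndarray:
    """XYZ → CIELAB: L = 116·f(Y/Yn) − 16, a* = 500·[f(X/Xn) − f(Y/Yn)],
    b* = 200·[f(Y/Yn) − f(Z/Zn)]."""
    xyz = _require_triplanar(image, "XYZ")
    fx = _f(xyz[..., 0] / white.xn)
    fy = _f(xyz[..., 1] / white.yn)
    fz = _f(xyz[..., 2] / white.zn)
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def lab_to_xyz(image: np.ndarray, white: WhitePoint = D65_WHITE) -> np.ndarray:
    """CIELAB → XYZ through the inverse piecewise function f⁻¹."""
    lab = _require_triplanar(image, "Lab")
    fy = (lab[..., 0] + 16.0) / 116.0
    xyz = np.empty_like(lab)
    xyz[..., 0] = white.xn * _f_inv(fy + lab[..., 1] / 500.0)
    xyz[..., 1] = white.yn * _f_inv(fy)
    xyz[..., 2] = white.zn * _f_inv(fy - lab[..., 2] / 200.0)
    return xyz


def xyz_to_rgb(image: np.ndarray, *, gamma: bool = False) -> np.ndarray:
    """XYZ → 8-bit RGB via the fixed inverse matrix.

    Out-of-gamut components are clamped to [0, 1] (count reported through
    the module logger) before scaling to [0, 255] with round-half-away.
    """
    xyz = _require_triplanar(image, "XYZ")
    linear = xyz @ XYZ_TO_RGB_MATRIX.T
    clamped = np.count_nonzero((linear < 0.0) | (linear > 1.0))
    if clamped:
        logger.debug("xyz_to_rgb: clamped %d out-of-gamut components", clamped)
    linear = np.clip(linear, 0.0, 1.0)
    if gamma:
        linear = _srgb_compress(linear)
    return _round_half_away(linear * 255.0).astype(np.uint8)


def rgb_to_lab(
    image: np.ndarray, white: WhitePoint = D65_WHITE, *, gamma: bool = False
) -> np.ndarray:
    """8-bit RGB → CIELAB (composition of the two forward transforms)."""
    return xyz_to_lab(rgb_to_xyz(image, gamma=gamma), white)


def lab_to_rgb(
    image: np.ndarray, white: WhitePoint = D65_WHITE, *, gamma: bool = False
) -> np.ndarray:
    """CIELAB → 8-bit RGB (composition of the two inverse transforms)."""
    return xyz_to_rgb(lab_to_xyz(image, white), gamma=gamma)


def lab_chroma_to_uint8(plane: np.ndarray) -> np.ndarray:
    """Embed an a*/b* chroma plane into 8-bit by the +128 offset convention.

    CLAHE is defined on histograms of a bounded integer range, so the real-
    valued chroma plane is shifted by +128, clamped to [0, 255] and rounded.
    """
    return _round_half_away(np.clip(np.asarray(plane, dtype=float) + 128.0, 0.0, 255.0)).astype(
        np.uint8
    )


def uint8_to_lab_chroma(plane: np.ndarray) -> np.ndarray:
    """Invert :func:`lab_chroma_to_uint8` (exact on the stored grid)."""
    return np.asarray(plane, dtype=float) - 128.0
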