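"""Full-reference image-quality metrics for (input, enhanced) pairs.

Six metrics: mean squared error, peak signal-to-noise ratio, structural
similarity (SSIM), Pearson correlation r₁, Shannon entropy and the
universal quality index (UQI).  The pairwise metrics are evaluated on each
RGB plane and arithmetic-averaged ("per channel and averaged" protocol);
entropy is computed once per image on the rounded channel-mean gray plane.

Conventions (all configurable where it matters):
- variances and covariances use population normalization (divide by N),
- PSNR peak defaults to R = 255,
- SSIM uses an 8×8 uniform sliding window, stride 1, K1=0.01, K2=0.03,
  dynamic range 255, mean-pooled over all fully contained windows,
- UQI is the global (single-window) three-factor product as defined,
  not the sliding-window variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "pearson_r1",
    "shannon_entropy",
    "uqi",
    "report",
]


def _as_float_pair(reference: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean squared error (1/mn)·ΣΣ[Y−X]² (gray-level² units)."""
    x, y = _as_float_pair(reference, test)
    return float(np.mean((y - x) ** 2))


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10·log₁₀(R²/MSE) in dB.

    Identical planes have MSE 0; the +inf sentinel is returned in that case.
    """
    err = mse(reference, test)
    if err == 0.0:
        return math.inf
    return float(10.0 * math.log10(peak**2 / err))


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    *,
    window: int = 8,
    k1: float = 0.01,
    k2: float = 0.03,
    dynamic_range: float = 255.0,
) -> float:
    """Mean structural similarity over uniform sliding windows.

    Per window the luminance·contrast·structure product collapses to the
    standard two-factor form
    ``(2μxμy+C1)(2σxy+C2) / ((μx²+μy²+C1)(σx²+σy²+C2))`` with C1=(K1·L)²,
    C2=(K2·L)², population moments, pooled by the mean over all windows
    fully inside the planes.
    """
    x, y = _as_float_pair(reference, test)
    if x.ndim != 2:
        raise ValueError("ssim expects 2-D planes")
    if min(x.shape) < window:
        raise ValueError(f"plane {x.shape} smaller than the {window}×{window} SSIM window")
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2

    # scipy's uniform_filter centres an even window at [i-w/2, i+w/2-1]; the
    # valid slice below keeps exactly the windows fully inside the plane.
    half = window // 2
    sl = tuple(slice(half, dim - window + half + 1) for dim in x.shape)

    def w_mean(a: np.ndarray) -> np.ndarray:
        return uniform_filter(a, size=window, mode="constant")[sl]

    mu_x = w_mean(x)
    mu_y = w_mean(y)
    var_x = w_mean(x * x) - mu_x**2
    var_y = w_mean(y * y) - mu_y**2
    cov = w_mean(x * y) - mu_x * mu_y
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    return float(ssim_map.mean())


def pearson_r1(reference: np.ndarray, test: np.ndarray) -> float:
    """Pearson correlation coefficient between the two planes.

    Undefined (NaN, with a warning) when either plane is constant.
    """
    x, y = _as_float_pair(reference, test)
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(np.sum(dx * dx)))
    sy = math.sqrt(float(np.sum(dy * dy)))
    if sx == 0.0 or sy == 0.0:
        warnings.warn("pearson_r1 undefined for a constant plane; returning NaN", stacklevel=2)
        return math.nan
    return float(np.sum(dx * dy) / (sx * sy))


def shannon_entropy(plane: np.ndarray) -> float:
    """Shannon entropy −Σ p·log₂p of the 256-bin histogram, in bits."""
    plane = np.asarray(plane)
    values = np.clip(np.round(plane), 0, 255).astype(int)
    p = np.bincount(values.ravel(), minlength=256).astype(float)
    p /= p.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def uqi(reference: np.ndarray, test: np.ndarray) -> float:
    """Universal quality index: correlation × luminance × contrast factors,
    computed globally over the whole plane with population moments.

    NaN (with a warning) when a plane has zero variance or both means are 0.
    """
    x, y = _as_float_pair(reference, test)
    xm = float(x.mean())
    ym = float(y.mean())
    sx = float(x.std())  # population
    sy = float(y.std())
    if sx == 0.0 or sy == 0.0 or (xm == 0.0 and ym == 0.0):
        warnings.warn("uqi undefined (zero variance or zero means); returning NaN", stacklevel=2)
        return math.nan
    sxy = float(np.mean((x - xm) * (y - ym)))
    return (sxy / (sx * sy)) * (2 * xm * ym / (xm**2 + ym**2)) * (2 * sx * sy / (sx**2 + sy**2))


@dataclass(frozen=True)
class MetricReport:
    """The six quality metrics for one (input, enhanced) image pair.

    ``per_channel`` holds the (R, G, B) values of each pairwise metric; the
    top-level fields are their arithmetic means.  Entropies are computed on
    the rounded channel-mean gray images.
    """

    image_id: str
    mse: float
    psnr: float
    ssim: float
    pearson_r1: float
    uqi: float
    entropy_input: float
    entropy_output: float
    per_channel: dict[str, tuple[float, float, float]]

    def to_row(self) -> dict[str, float | str]:
        return {
            "id": self.image_id,
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "pearson_r1": self.pearson_r1,
            "uqi": self.uqi,
            "entropy_in": self.entropy_input,
            "entropy_out": self.entropy_output,
        }


def _gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return np.clip(np.round(arr), 0, 255)


def report(input_image: np.ndarray, enhanced: np.ndarray, image_id: str = "") -> MetricReport:
    """Evaluate all six metrics for one (input, enhanced) pair.

    Pairwise metrics are computed per RGB plane and averaged; entropy is
    one value per image, on the gray plane.
    """
    x = np.asarray(input_image)
    y = np.asarray(enhanced)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("report expects H×W×3 RGB images")

    per: dict[str, tuple[float, float, float]] = {}
    funcs = {"mse": mse, "psnr": psnr, "ssim": ssim, "pearson_r1": pearson_r1, "uqi": uqi}
    for name, fn in funcs.items():
        per[name] = tuple(float(fn(x[..., c], y[..., c])) for c in range(3))

    def avg(name: str) -> float:
        return float(np.mean(per[name]))

    return MetricReport(
        image_id=image_id,
        mse=avg("mse"),
        psnr=avg("psnr"),
        ssim=avg("ssim"),
        pearson_r1=avg("pearson_r1"),
        uqi=avg("uqi"),
        entropy_input=shannon_entropy(_gray(x)),
        entropy_output=shannon_entropy(_gray(y)),
        per_channel=per,
    )
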