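"""Deliberately naive double-loop reference implementations.

These are independent oracles for the vectorized library code: plain Python
loops transcribing each formula, kept free of any shared code paths with
the package.
"""

import math

import numpy as np


def naive_bilateral(plane, sigma_d, sigma_r, radius):
    plane = np.asarray(plane, dtype=float)
    h, w = plane.shape
    padded = np.pad(plane, radius, mode="reflect")
    out = np.zeros((h, w))
    for j0 in range(h):
        for j1 in range(w):
            num = den = 0.0
            centre = plane[j0, j1]
            for i0 in range(-radius, radius + 1):
                for i1 in range(-radius, radius + 1):
                    xi = padded[j0 + radius + i0, j1 + radius + i1]
                    weight = math.exp(-(i0 * i0 + i1 * i1) / (2 * sigma_d**2)) * math.exp(
                        -((xi - centre) ** 2) / (2 * sigma_r**2)
                    )
                    num += weight * xi
                    den += weight
            out[j0, j1] = num / den
    return out


def naive_gaussian_blur(plane, sigma_d, radius):
    """Spatial-only Gaussian window average (the bilateral sigma_r→inf limit)."""
    plane = np.asarray(plane, dtype=float)
    h, w = plane.shape
    padded = np.pad(plane, radius, mode="reflect")
    out = np.zeros((h, w))
    for j0 in range(h):
        for j1 in range(w):
            num = den = 0.0
            for i0 in range(-radius, radius + 1):
                for i1 in range(-radius, radius + 1):
                    weight = math.exp(-(i0 * i0 + i1 * i1) / (2 * sigma_d**2))
                    num += weight * padded[j0 + radius + i0, j1 + radius + i1]
                    den += weight
            out[j0, j1] = num / den
    return out


def naive_mse(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = 0.0
    for a, b in zip(x.ravel(), y.ravel()):
        total += (b - a) ** 2
    return total / x.size


def naive_psnr(x, y, peak=255.0):
    err = naive_mse(x, y)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak**2 / err)


def naive_pearson(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xm = sum(x) / len(x)
    ym = sum(y) / len(y)
    num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - xm) ** 2 for a in x))
    dy = math.sqrt(sum((b - ym) ** 2 for b in y))
    return num / (dx * dy)


def naive_entropy(plane):
    values = np.clip(np.round(np.asarray(plane, dtype=float)), 0, 255).astype(int).ravel()
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def naive_uqi(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sx = math.sqrt(sum((a - xm) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - ym) ** 2 for b in y) / n)
    sxy = sum((a - xm) * (b - ym) for a, b in zip(x, y)) / n
    return (
        (sxy / (sx * sy))
        * (2 * xm * ym / (xm**2 + ym**2))
        * (2 * sx * sy / (sx**2 + sy**2))
    )


def naive_ssim(x, y, window=8, k1=0.01, k2=0.03, dynamic_range=255.0):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    h, w = x.shape
    values = []
    for r in range(h - window + 1):
        for c in range(w - window + 1):
            wx = x[r : r + window, c : c + window].ravel()
            wy = y[r : r + window, c : c + window].ravel()
            n = len(wx)
            mx = sum(wx) / n
            my = sum(wy) / n
            vx = sum((a - mx) ** 2 for a in wx) / n
            vy = sum((b - my) ** 2 for b in wy) / n
            cov = sum((a - mx) * (b - my) for a, b in zip(wx, wy)) / n
            values.append(
                ((2 * mx * my + c1) * (2 * cov + c2))
                / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            )
    return sum(values) / len(values)
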