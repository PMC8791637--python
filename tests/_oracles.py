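"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: convolution is an
explicit shift-and-accumulate over a symmetric-padded array, and the
intermeans threshold is an exhaustive scan over candidate bins.
"""

from __future__ import annotations

import numpy as np


def brute_force_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-space 2D convolution with symmetric (reflect) boundary."""
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    ky, kx = kernel.shape
    ry, rx = ky // 2, kx // 2
    padded = np.pad(image, ((ry, ry), (rx, rx)), mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w), dtype=np.float64)
    for i in range(ky):
        for j in range(kx):
            out += kernel[i, j] * padded[2 * ry - i : 2 * ry - i + h, 2 * rx - j : 2 * rx - j + w]
    return out


def brute_force_intermeans(hist: np.ndarray) -> int:
    """Exhaustive scan for the intermeans stopping bin.

    For every candidate split index the two intensity-weighted class means
    are computed from scratch; the scan returns the rounded intermean at
    the first candidate where the next index would overshoot it (or the
    upper boundary is reached).
    """
    hist = np.asarray(hist, dtype=np.float64)
    occupied = np.nonzero(hist > 0)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    if lo == hi:
        return lo
    bins = np.arange(hist.size, dtype=np.float64)
    for m in range(lo, hi):
        below = hist[lo : m + 1]
        above = hist[m + 1 : hi + 1]
        mean_below = np.dot(bins[lo : m + 1], below) / below.sum()
        mean_above = np.dot(bins[m + 1 : hi + 1], above) / above.sum()
        result = (mean_below + mean_above) / 2.0
        if (m + 1) + 1 > result or (m + 1) >= hi - 1:
            return int(round(result))
    raise AssertionError("scan exhausted without a stopping index")


def masked_disc_mean_oracle(disc: np.ndarray, kernel: np.ndarray) -> tuple[float, float]:
    """(equivalent diameter, mean) inside the Otsu mask of a brute-force
    convolved disc.  Otsu is recomputed here from the histogram directly."""
    convolved = brute_force_convolve(disc, kernel)
    # exhaustive Otsu: maximize between-class variance over 256 bins
    lo, hi = convolved.min(), convolved.max()
    hist, edges = np.histogram(convolved, bins=256, range=(lo, hi))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = None, -1.0
    w = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    for t in range(1, 256):
        w0, w1 = w[t - 1], 1 - w[t - 1]
        if w0 <= 0 or w1 <= 0:
            continue
        m0 = mu[t - 1] / w0
        m1 = (mu_total - mu[t - 1]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    threshold = centers[best_t - 1]
    mask = convolved > threshold
    area = mask.sum()
    diameter = 2.0 * np.sqrt(area / np.pi)
    return float(diameter), float(convolved[mask].mean())
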