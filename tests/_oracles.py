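"""Independent brute-force oracles for cross-checking the library.

Every function here is a direct, loop-based transcription of the defining
formula, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def mse_oracle(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = a.shape
    total = 0.0
    for x in range(m):
        for y in range(n):
            total += (a[x, y] - b[x, y]) ** 2
    return total / (m * n)


def psnr_oracle(a, b, max_value=255.0, cap=100.0) -> float:
    err = mse_oracle(a, b)
    if err == 0.0:
        return cap
    return 10.0 * math.log10(max_value**2 / err)


def cr_oracle(image, mask) -> float:
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    fg, bg = [], []
    for x in range(image.shape[0]):
        for y in range(image.shape[1]):
            (fg if mask[x, y] else bg).append(image[x, y])
    return (sum(bg) / len(bg) - sum(fg) / len(fg)) / 255.0


def dice_oracle(a, b) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = na = nb = 0
    for x in range(a.shape[0]):
        for y in range(a.shape[1]):
            na += a[x, y]
            nb += b[x, y]
            inter += a[x, y] and b[x, y]
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def otsu_oracle(image) -> int:
    """Exhaustive search over all 256 thresholds for max between-class variance."""
    values = np.asarray(image).ravel()
    n = values.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        low = values[values <= t]
        high = values[values > t]
        if low.size == 0 or high.size == 0:
            continue
        w0, w1 = low.size / n, high.size / n
        var = w0 * w1 * (low.mean() - high.mean()) ** 2
        if var > best_var + 1e-12:  # strict improvement -> smallest maximizer kept
            best_var, best_t = var, t
    return best_t


def plcc_oracle(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xb, yb = x.mean(), y.mean()
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - xb) ** 2 for xi in x)) * math.sqrt(
        sum((yi - yb) ** 2 for yi in y)
    )
    return num / den


def _average_ranks(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def srcc_oracle(x, y) -> float:
    """Pearson on average ranks; equals 1 - 6*sum(d^2)/(N(N^2-1)) when tie-free."""
    return plcc_oracle(_average_ranks(x), _average_ranks(y))


def srcc_classic_oracle(x, y) -> float:
    """The classic rank-difference formula (valid for tie-free data only)."""
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    n = len(rx)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def rmse_oracle(s, p) -> float:
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(s, p)) / len(s))
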