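"""Independent scalar reference implementations of every pipeline curve.

Each function evaluates one formula straight from its mathematical
definition with ``math`` scalars (no numpy broadcasting, no shared code
with the package), so the vectorized implementations can be checked
against them pointwise.
"""

import math


def sharpen_pixel(i: float, detail: float, dmin: float, dmax: float) -> float:
    """(I + normalized detail)/2 with the global min-max of the detail layer."""
    norm = 0.0 if dmax == dmin else (detail - dmin) / (dmax - dmin)
    return (i + norm) / 2.0


def upper_membership(z: float, var: float, alpha: float) -> float:
    za = z**alpha
    return za + (1.0 - za) * var**alpha


def lower_membership(
    z: float, mu: float, sigma: float, k: float, b: float, c: float, d: float
) -> float:
    return (k * mu / (sigma + b)) * (z - c * mu) + mu**d


def hamacher(u: float, w: float, var: float) -> float:
    num = u + w + (var - 2.0) * u * w
    den = 1.0 - (1.0 - var) * u * w
    return num / den


def gamma_restore(t: float, tmax: float, alpha: float) -> float:
    return tmax * (t / tmax) ** (1.5 * alpha)


def gaussian_pdf(z: float) -> float:
    return math.exp(-(z**2) / 2.0) / math.sqrt(2.0 * math.pi)


def softplus(z: float) -> float:
    return math.log(1.0 + math.exp(z))


def lip_combine(g: float, s: float) -> float:
    return math.sqrt(g + s + g * s)


def gamma_normalize(l: float, lmin: float, lmax: float, eta: float) -> float:
    return ((l - lmin) / (lmax - lmin)) ** eta


def contrast_curve(z: float, lmin: float, lmax: float, eta: float) -> float:
    """Full contrast branch curve at one pixel, given the slice extrema of l."""
    l = lip_combine(gaussian_pdf(z), softplus(z))
    return gamma_normalize(l, lmin, lmax, eta)


def intensity_weight(l: float, m: float, sigma: float) -> float:
    return math.exp(-((l - (1.0 - m)) ** 2) / (2.0 * sigma**2))


def brightness_sigmas(means_sorted: list[float]) -> list[float]:
    """Width rule on ascending means: 1.5x end gaps, 0.75x straddling gaps."""
    n = len(means_sorted)
    out = []
    for i in range(n):
        if i == 0:
            out.append(1.5 * (means_sorted[1] - means_sorted[0]))
        elif i == n - 1:
            out.append(1.5 * (means_sorted[-1] - means_sorted[-2]))
        else:
            out.append(0.75 * (means_sorted[i + 1] - means_sorted[i - 1]))
    return out


def cdf_slope(counts: list[int], total: int, bins: int, level: float) -> float:
    """Empirical CDF slope at *level* for a histogram on [0, 1]."""
    idx = min(int(level * bins), bins - 1)
    return counts[idx] * bins / total


def gradient_weight(grads: list[float], n: int, eps: float) -> float:
    inv = [1.0 / g for g in grads]
    return inv[n] / (sum(inv) + eps)


def combined_weight(products: list[float], n: int, eps: float) -> float:
    return products[n] / (sum(products) + eps)


def fused_pixel(weights: list[float], levels: list[float]) -> float:
    return sum(w * l for w, l in zip(weights, levels))
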