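"""Contrast enhancement via curve transforms.

Two pointwise curves are applied to the sharpened slice — the standard
normal density g(Z) = phi(Z) (decreasing) and the softplus
s(Z) = log(1 + exp(Z)) (increasing) — then merged with a
logarithmic-image-processing style combination

    l = sqrt(g + s + g*s)

and stretched onto [0, 1] by a gamma-controlled normalization
L2 = ((l - min l)/(max l - min l)) ** eta.  The composite curve l(Z) is
strictly increasing on [0, 1] (the softplus growth dominates the density's
decay), so pixel ordering is preserved.
"""

from __future__ import annotations

import numpy as np

from .core import PipelineConfig, validate_image

__all__ = [
    "gaussian_pdf_map",
    "softplus_map",
    "lip_combine",
    "gamma_normalize",
    "enhance_contrast",
]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gaussian_pdf_map(img: np.ndarray) -> np.ndarray:
    """Standard normal density of each pixel: g = phi(Z).

    Strictly decreasing; on [0, 1] the range is [phi(1), phi(0)]
    ~= [0.24197, 0.39894].
    """
    arr = validate_image(img)
    return _INV_SQRT_2PI * np.exp(-0.5 * arr**2)


def softplus_map(img: np.ndarray) -> np.ndarray:
    """Softplus of each pixel: s = log(1 + exp(Z)), natural log."""
    arr = validate_image(img)
    return np.log1p(np.exp(arr))


def lip_combine(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Merge the two curve outputs: l = sqrt(g + s + g*s)."""
    ga = validate_image(g, "g")
    sa = validate_image(s, "s")
    if ga.shape != sa.shape:
        raise ValueError(f"shape mismatch: {ga.shape} vs {sa.shape}")
    return np.sqrt(ga + sa + ga * sa)


def gamma_normalize(l: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Gamma-controlled min-max stretch: L2 = ((l - min)/(max - min))^eta.

    Range is exactly [0, 1] for non-constant input; a constant input maps
    to all zeros (same degenerate rule as the global normalizer).
    """
    cfg = cfg or PipelineConfig()
    arr = validate_image(l, "l")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return np.power((arr - lo) / (hi - lo), cfg.eta)


def enhance_contrast(
    sharpened: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Full contrast branch: sharpened slice in, L2 out."""
    cfg = cfg or PipelineConfig()
    g = gaussian_pdf_map(sharpened)
    s = softplus_map(sharpened)
    return gamma_normalize(lip_combine(g, s), cfg)
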