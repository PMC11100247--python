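"""Perceptual fusion of the two enhanced branches.

The visibility-restored image L1 and the contrast-enhanced image L2 are
blended pixelwise.  Two weight families are built per image:

* intensity weights  w1_n(x) = exp(-(L_n(x) - (1 - m_n))^2 / (2 sigma_n^2))
  — a well-exposedness prior: pixels near the brightness complement of the
  image mean m_n count most; sigma_n is 1.5x (end members) or 0.75x
  (interior) the neighbouring mean gaps after sorting images by mean;
* global-gradient weights w2_n(x) ∝ 1 / Grad_n(L_n(x)) where Grad_n is the
  slope of the image's cumulative intensity histogram — pixels whose level
  is rare (flat CDF) carry more information and get more weight.

The products w1*w2 are normalized across images and the fused slice is the
weighted sum F = sum_n W_n L_n.  The engine accepts any N >= 2 images; the
pipeline uses N = 2.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core import PipelineConfig, validate_image

__all__ = [
    "WeightStack",
    "intensity_weights",
    "gradient_weights",
    "combine_weights",
    "fuse",
    "perceptual_fusion",
]


@dataclasses.dataclass
class WeightStack:
    """QC record of all per-image weight maps entering a fusion."""

    w_intensity: list[np.ndarray]
    w_gradient: list[np.ndarray]
    w_combined: list[np.ndarray]
    means: list[float]
    sigmas: list[float]

    @property
    def n_images(self) -> int:
        return len(self.w_combined)


def _validated_stack(images: Sequence[np.ndarray]) -> list[np.ndarray]:
    imgs = [validate_image(im, f"images[{i}]") for i, im in enumerate(images)]
    if len(imgs) < 2:
        raise ValueError("fusion needs at least 2 images")
    shape = imgs[0].shape
    for i, im in enumerate(imgs):
        if im.shape != shape:
            raise ValueError(f"images[{i}] shape {im.shape} != {shape}")
    return imgs


def intensity_weights(
    images: Sequence[np.ndarray], epsilon: float = 1e-6
) -> tuple[list[np.ndarray], list[float], list[float]]:
    """Well-exposedness weights with brightness-gap adaptive widths.

    Images are ranked by ascending mean brightness before the width rule
    is applied, so neighbouring mean differences are non-negative; each
    sigma_n is floored at *epsilon* to survive equal means.  Returns
    (weights, means, sigmas) in the original image order.
    """
    imgs = _validated_stack(images)
    n = len(imgs)
    means = [float(im.mean()) for im in imgs]
    order = sorted(range(n), key=lambda i: means[i])
    m_sorted = [means[i] for i in order]
    sigmas = [0.0] * n
    for rank, idx in enumerate(order):
        if rank == 0:
            s = 1.5 * (m_sorted[1] - m_sorted[0])
        elif rank == n - 1:
            s = 1.5 * (m_sorted[-1] - m_sorted[-2])
        else:
            s = 0.75 * (m_sorted[rank + 1] - m_sorted[rank - 1])
        sigmas[idx] = max(s, epsilon)
    weights = [
        np.exp(-((im - (1.0 - m)) ** 2) / (2.0 * s**2))
        for im, m, s in zip(imgs, means, sigmas)
    ]
    return weights, means, sigmas


def gradient_weights(
    images: Sequence[np.ndarray], cfg: PipelineConfig | None = None
) -> list[np.ndarray]:
    """Inverse cumulative-histogram-slope weights, normalized across images.

    Grad_n at level v is the empirical CDF slope at v's histogram bin,
    i.e. (bin count) / (pixel count * bin width), floored at epsilon.
    """
    cfg = cfg or PipelineConfig()
    imgs = _validated_stack(images)
    bins, eps = cfg.hist_bins, cfg.epsilon
    inv_grads = []
    for im in imgs:
        counts, _ = np.histogram(np.clip(im, 0.0, 1.0), bins=bins, range=(0.0, 1.0))
        density = counts.astype(np.float64) * bins / im.size  # CDF slope per bin
        density = np.maximum(density, eps)
        idx = np.clip((np.clip(im, 0.0, 1.0) * bins).astype(np.intp), 0, bins - 1)
        inv_grads.append(1.0 / density[idx])
    denom = np.sum(inv_grads, axis=0) + eps
    return [g / denom for g in inv_grads]


def combine_weights(
    w1: Sequence[np.ndarray],
    w2: Sequence[np.ndarray],
    cfg: PipelineConfig | None = None,
) -> list[np.ndarray]:
    """Normalize the products w1_n * w2_n across images.

        W_n = w1_n w2_n / (sum_n w1_n w2_n + epsilon)

    At pixels where the product sum itself falls below epsilon (both
    weight families vanished, e.g. two branches of identical brightness)
    the weights degenerate, so the blend falls back to the uniform 1/N —
    the limit of indifference between the inputs.
    """
    cfg = cfg or PipelineConfig()
    if len(w1) != len(w2):
        raise ValueError("w1 and w2 must have the same length")
    n = len(w1)
    products = []
    shape = validate_image(w1[0], "w1[0]").shape
    for a, b in zip(w1, w2):
        aa, bb = validate_image(a, "w1"), validate_image(b, "w2")
        if aa.shape != shape or bb.shape != shape:
            raise ValueError("weight map shape mismatch")
        products.append(aa * bb)
    total = np.sum(products, axis=0)
    degenerate = total <= cfg.epsilon
    denom = np.where(degenerate, 1.0, total + cfg.epsilon)
    return [np.where(degenerate, 1.0 / n, p / denom) for p in products]


def fuse(images: Sequence[np.ndarray], W: Sequence[np.ndarray]) -> np.ndarray:
    """Weighted sum F = sum_n W_n * L_n."""
    imgs = _validated_stack(images)
    if len(W) != len(imgs):
        raise ValueError("one weight map per image required")
    wsum = np.zeros_like(imgs[0])
    out = np.zeros_like(imgs[0])
    for im, w in zip(imgs, W):
        wa = validate_image(w, "W")
        if wa.shape != im.shape:
            raise ValueError("weight map shape mismatch")
        out += wa * im
        wsum += wa
    if wsum.max() > 1.0 + 1e-6:
        raise ValueError("combined weights exceed 1 at some pixel")
    return out


def perceptual_fusion(
    L1: np.ndarray, L2: np.ndarray, cfg: PipelineConfig | None = None
) -> tuple[np.ndarray, WeightStack]:
    """Fuse the two branch images; returns (F, WeightStack) for QC."""
    cfg = cfg or PipelineConfig()
    images = [validate_image(L1, "L1"), validate_image(L2, "L2")]
    w1, means, sigmas = intensity_weights(images, epsilon=cfg.epsilon)
    w2 = gradient_weights(images, cfg)
    W = combine_weights(w1, w2, cfg)
    F = fuse(images, W)
    return F, WeightStack(w1, w2, W, means, sigmas)
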