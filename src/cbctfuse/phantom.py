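"""Synthetic CBCT-like phantom slices.

Deterministic generator of clean/degraded pairs that emulate the look of a
low-dose oral CBCT axial slice: a dark background, a bright elliptical jaw
arch, tooth-sized discs along the arch, and very bright small discs that
stand in for metal miniscrews.  The degradation model applies the defects
the enhancement pipeline targets — global contrast compression toward
mid-grey, gamma underexposure, an optional saturated (overexposed) patch
and additive Gaussian noise.

This is a geometric phantom, not a physics simulation: no projection,
reconstruction, beam hardening or streak artifacts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core import validate_image

__all__ = ["PhantomSpec", "make_phantom"]

# nominal tissue intensities of the clean slice
_BACKGROUND = 0.05
_JAW = 0.45
_TOOTH = 0.70
_SCREW = 0.95


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and degradation parameters of one phantom pair.

    The same spec (including seed) always yields bit-identical images:
    a single ``numpy.random.default_rng(seed)`` stream drives all jitter
    and noise.

    Degradation defaults mirror a markedly degraded low-dose acquisition:
    contrast compressed to half (``contrast_compression=0.5``), gamma
    underexposure 1.8, additive Gaussian noise of standard deviation 0.01
    on the [0, 1] scale.
    """

    size: tuple[int, int] = (256, 256)
    seed: int = 0
    n_teeth: int = 6
    n_screws: int = 2
    underexposure_gamma: float = 1.8
    overexposure_patch: tuple[int, int, int, int] | None = None  # row, col, h, w
    contrast_compression: float = 0.5
    noise_std: float = 0.01

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("phantom must be at least 32x32")
        if self.n_teeth < 0 or self.n_screws < 0:
            raise ValueError("n_teeth and n_screws must be >= 0")
        if self.underexposure_gamma < 1.0:
            raise ValueError("underexposure_gamma must be >= 1")
        if not (0.0 < self.contrast_compression <= 1.0):
            raise ValueError("contrast_compression must be in (0, 1]")
        if self.noise_std < 0.0:
            raise ValueError("noise_std must be >= 0")
        if self.overexposure_patch is not None:
            r, c, ph, pw = self.overexposure_patch
            if r < 0 or c < 0 or ph <= 0 or pw <= 0 or r + ph > h or c + pw > w:
                raise ValueError("overexposure_patch outside image")


def _disc(mask_shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: mask_shape[0], : mask_shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _clean_slice(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    img = np.full((h, w), _BACKGROUND)

    # jaw arch: lower half of an elliptical annulus, opening upward
    cy, cx = 0.38 * h, 0.5 * w
    ry, rx = 0.42 * h, 0.38 * w
    yy, xx = np.ogrid[:h, :w]
    rho = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    band = (rho >= 0.55) & (rho <= 1.0) & (yy >= cy)
    img[band] = _JAW

    # teeth: discs spaced along the arch midline, small positional jitter
    arch_r = 0.78  # sqrt of mid-band rho
    angles = np.linspace(0.15 * np.pi, 0.85 * np.pi, spec.n_teeth) if spec.n_teeth else []
    tooth_r = 0.035 * min(h, w)
    for ang in angles:
        ty = cy + arch_r * ry * np.sin(ang) + rng.normal(0, 0.004 * h)
        tx = cx + arch_r * rx * np.cos(ang) + rng.normal(0, 0.004 * w)
        img[_disc((h, w), ty, tx, tooth_r)] = _TOOTH

    # miniscrews: very bright small discs just outside the arch
    screw_r = 0.015 * min(h, w)
    for _ in range(spec.n_screws):
        ang = rng.uniform(0.2 * np.pi, 0.8 * np.pi)
        sy = cy + 1.04 * ry * np.sin(ang)
        sx = cx + 1.04 * rx * np.cos(ang)
        sy = min(max(sy, screw_r + 1), h - screw_r - 2)
        sx = min(max(sx, screw_r + 1), w - screw_r - 2)
        img[_disc((h, w), sy, sx, screw_r)] = _SCREW

    # smooth edges so structures have soft CT-like boundaries
    return ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (clean, degraded) phantom pair.

    Degradation order: affine contrast compression toward 0.5, gamma
    darkening, optional saturated patch (driven to >= 0.98), additive
    Gaussian noise, clip to [0, 1].  With the identity settings
    (compression 1, gamma 1, no patch, zero noise) the degraded slice
    equals the clean one exactly.
    """
    rng = np.random.default_rng(spec.seed)
    clean = _clean_slice(spec, rng)

    if spec.contrast_compression != 1.0:
        degraded = 0.5 + spec.contrast_compression * (clean - 0.5)
    else:
        degraded = clean.copy()
    if spec.underexposure_gamma != 1.0:
        degraded = np.power(degraded, spec.underexposure_gamma)
    if spec.overexposure_patch is not None:
        r, c, ph, pw = spec.overexposure_patch
        degraded[r : r + ph, c : c + pw] = np.maximum(
            degraded[r : r + ph, c : c + pw], 0.98
        )
    if spec.noise_std > 0:
        degraded = degraded + rng.normal(0.0, spec.noise_std, size=spec.size)
    degraded = np.clip(degraded, 0.0, 1.0)
    return validate_image(clean), validate_image(degraded)
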