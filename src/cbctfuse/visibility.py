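"""Visibility restoration via type-II fuzzy memberships.

The sharpened slice is treated as a fuzzy image: each pixel gets an upper
and a lower membership bound built from the global mean ``mu`` and sample
standard deviation ``sigma`` of the slice.  The two bounds are merged by a
Hamacher t-conorm parameterized by the slice variance ``sigma**2``, and a
gamma restoration (exponent ``1.5 * alpha``) re-expands the tonal range
while preserving the global maximum.

Pipeline order: :func:`fuzzy_stats` -> :func:`upper_membership` /
:func:`lower_membership` -> :func:`hamacher_combine` ->
:func:`gamma_restore`, wrapped by :func:`restore_visibility`.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import PipelineConfig, validate_image

__all__ = [
    "FuzzyStats",
    "fuzzy_stats",
    "upper_membership",
    "lower_membership",
    "hamacher_combine",
    "gamma_restore",
    "restore_visibility",
]


@dataclasses.dataclass(frozen=True)
class FuzzyStats:
    """Global first and second moments of the sharpened slice.

    ``sigma`` uses the sample (n-1) denominator; for intensities in
    [0, 1] the variance ``sigma**2`` never exceeds 1, which keeps the
    membership bounds and the Hamacher parameter well behaved.
    """

    mu: float
    sigma: float
    n: int

    @property
    def variance(self) -> float:
        return self.sigma**2


def fuzzy_stats(img: np.ndarray) -> FuzzyStats:
    """Mean and sample standard deviation over all pixels."""
    arr = validate_image(img)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 pixels for a sample standard deviation")
    return FuzzyStats(mu=float(arr.mean()), sigma=float(arr.std(ddof=1)), n=n)


def upper_membership(
    img: np.ndarray, st: FuzzyStats, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Upper membership bound u(x) = Z^a + (1 - Z^a) * (sigma^2)^a.

    A convex blend of the fuzzified pixel with the slice variance: flat,
    low-variance slices pull the bound toward the pixel value itself,
    high-variance slices lift dark pixels.  Monotone non-decreasing in Z.
    """
    cfg = cfg or PipelineConfig()
    arr = validate_image(img)
    a = cfg.alpha
    za = np.power(arr, a)
    u = za + (1.0 - za) * st.variance**a
    if cfg.clip_memberships:
        u = np.clip(u, 0.0, 1.0)
    return u


def lower_membership(
    img: np.ndarray, st: FuzzyStats, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Lower membership bound w(x) = (k*mu/(sigma+b)) * (Z - c*mu) + mu^d.

    With the default coefficients this is a mean-centred contrast stretch
    with gain mu/sigma.  Clipped to [0, 1] when ``cfg.clip_memberships``
    so it is a valid t-conorm argument.
    """
    cfg = cfg or PipelineConfig()
    arr = validate_image(img)
    w = (cfg.k * st.mu / (st.sigma + cfg.b)) * (arr - cfg.c * st.mu) + st.mu**cfg.d
    if cfg.clip_memberships:
        w = np.clip(w, 0.0, 1.0)
    return w


def hamacher_combine(
    u: np.ndarray, w: np.ndarray, st: FuzzyStats, epsilon: float = 1e-6
) -> np.ndarray:
    """Merge the two membership maps with a Hamacher t-conorm.

        t = (u + w + (s2 - 2) u w) / (1 - (1 - s2) u w),   s2 = sigma^2

    For s2 in [0, 1] and u, w in [0, 1] the output is again in [0, 1];
    where the denominator vanishes (|den| < epsilon) the saturation limit
    1 is returned.
    """
    ua = validate_image(u, "u")
    wa = validate_image(w, "w")
    if ua.shape != wa.shape:
        raise ValueError(f"shape mismatch: {ua.shape} vs {wa.shape}")
    s2 = st.variance
    prod = ua * wa
    num = ua + wa + (s2 - 2.0) * prod
    den = 1.0 - (1.0 - s2) * prod
    safe = np.abs(den) >= epsilon
    t = np.where(safe, num / np.where(safe, den, 1.0), 1.0)
    return np.clip(t, 0.0, 1.0)


def gamma_restore(t: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Gamma restoration anchored at the global maximum.

        L1 = max(t) * (t / max(t)) ** (1.5 * alpha)

    Preserves the global maximum exactly and the pixel ordering (the map
    is monotone).  An all-zero input returns all zeros.
    """
    cfg = cfg or PipelineConfig()
    arr = validate_image(t, "t")
    tmax = float(arr.max())
    if tmax <= 0.0:
        return np.zeros_like(arr)
    return tmax * np.power(arr / tmax, 1.5 * cfg.alpha)


def restore_visibility(
    sharpened: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Full visibility branch: sharpened slice in, L1 out."""
    cfg = cfg or PipelineConfig()
    st = fuzzy_stats(sharpened)
    u = upper_membership(sharpened, st, cfg)
    w = lower_membership(sharpened, st, cfg)
    t = hamacher_combine(u, w, st, epsilon=cfg.epsilon)
    return gamma_restore(t, cfg)
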