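"""Shared image currency, configuration and low-level operators.

Every stage of the enhancement pipeline trades in plain 2-D ``float64``
numpy arrays whose intensities live nominally in ``[0, 1]``.  There is no
wrapper class: arrays are the field's lingua franca and keep the stage
functions composable.  :func:`validate_image` is the single gatekeeper each
public operation runs its input through.

The two operators defined here — global min-max normalization and Gaussian
low-pass filtering — are the primitives the sharpening stage is built from,
and the normalization rule (a constant field maps to all zeros) is shared
with the contrast stage.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any, Mapping

import numpy as np
from scipy import ndimage

logger = logging.getLogger("cbctfuse")

__all__ = ["PipelineConfig", "validate_image", "min_max_normalize", "gaussian_blur"]


@dataclasses.dataclass
class PipelineConfig:
    """All tunable constants of the enhancement pipeline.

    Parameters
    ----------
    alpha : float
        Fuzzification exponent of the visibility branch, in ``(0, 1]``.
        It shapes the upper membership bound and the restoration gamma
        (exponent ``1.5 * alpha``). Default 0.95.
    eta : float
        Gamma of the contrast branch's final normalization, ``> 0``.
        Values below 1 brighten midtones. Default 0.8.
    blur_sigma : float
        Scale (pixels) of the Gaussian low-pass used to build the detail
        layer for sharpening. Default 2.0.
    k, b, c, d : float
        Coefficients of the lower membership bound
        ``w(x) = (k*mu/(sigma+b)) * (Z(x) - c*mu) + mu**d``.  Defaults
        ``k=1, b=1e-6, c=1, d=1`` reduce it to a mean-centred contrast
        stretch; ``b`` guards the division when ``sigma`` is tiny.
    epsilon : float
        Small positive guard used in weight normalization, histogram-slope
        flooring and the Hamacher denominator. Default 1e-6.
    hist_bins : int
        Bin count of the intensity histogram behind the global-gradient
        fusion weights. Default 256.
    clip_memberships : bool
        Clip fuzzy membership maps to ``[0, 1]`` before the Hamacher
        combination (the t-conorm is only defined there). Default True.
    """

    alpha: float = 0.95
    eta: float = 0.8
    blur_sigma: float = 2.0
    k: float = 1.0
    b: float = 1e-6
    c: float = 1.0
    d: float = 1.0
    epsilon: float = 1e-6
    hist_bins: int = 256
    clip_memberships: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.blur_sigma <= 0:
            raise ValueError(f"blur_sigma must be > 0, got {self.blur_sigma}")
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.hist_bins < 2:
            raise ValueError(f"hist_bins must be >= 2, got {self.hist_bins}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def replace(self, **changes: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_image(img: Any, name: str = "image") -> np.ndarray:
    """Coerce *img* to a finite 2-D float64 array.

    Raises ``ValueError`` on wrong dimensionality, empty axes or
    non-finite values.  Does not enforce the [0, 1] range — individual
    stages state their own range contracts.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have positive height and width")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def min_max_normalize(field: Any) -> np.ndarray:
    """Affinely map *field* onto [0, 1].

    Returns ``(field - min) / (max - min)``.  A constant field is mapped
    to all zeros: a flat detail layer carries no edges, so the term it
    feeds should vanish rather than blow up.
    """
    arr = validate_image(field, "field")
    lo = float(arr.min())
    hi = float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def gaussian_blur(img: Any, sigma: float) -> np.ndarray:
    """Gaussian low-pass filter with edge-replicated boundaries.

    The kernel is truncated at 4 sigma.  Edge replication avoids the dark
    halos zero padding would create along the borders of bright anatomy.
    """
    arr = validate_image(img)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest", truncate=4.0)
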