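"""Sharpening correction.

Low-dose CBCT slices lose edge detail in under- and over-exposed regions.
The correction averages the input with a globally normalized unsharp-mask
detail layer:

    Z = (I + N{I - G*I}) / 2

where ``G*I`` is a Gaussian blur of the input and ``N`` maps the detail
layer onto [0, 1] by a global min-max stretch.  Both downstream branches
(visibility restoration and contrast enhancement) consume this single
sharpened image.
"""

from __future__ import annotations

import numpy as np

from .core import PipelineConfig, gaussian_blur, min_max_normalize, validate_image

__all__ = ["sharpen"]


def sharpen(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Sharpen *img*; output is in [0, 1] by construction.

    The normalization is global (one min, one max over the whole detail
    layer), not tile-wise, and a flat detail layer normalizes to zeros,
    so a constant image of level c maps to c/2.
    """
    cfg = cfg or PipelineConfig()
    arr = validate_image(img)
    detail = arr - gaussian_blur(arr, cfg.blur_sigma)
    out = (arr + min_max_normalize(detail)) / 2.0
    # average of two [0,1] fields; assert instead of clipping
    assert out.min() >= -1e-12 and out.max() <= 1.0 + 1e-12
    return out
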