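"""End-to-end enhancement pipeline and its ablation variants.

The full flow sharpens the input once, sends that single sharpened slice
through the visibility-restoration and contrast-enhancement branches, and
perceptually fuses the two branch outputs.  The ablation variants drop one
branch: by default the fusion stage is bypassed entirely and the surviving
branch is the output (a ``self_fusion`` switch instead fuses the branch
with itself, which is equivalent up to weight normalization).
"""

from __future__ import annotations

import numpy as np

from .contrast import enhance_contrast
from .core import PipelineConfig, validate_image
from .fusion import perceptual_fusion
from .sharpen import sharpen
from .visibility import restore_visibility

__all__ = ["enhance", "VARIANTS"]

VARIANTS = ("full", "no_vrm", "no_cem")


def enhance(
    img: np.ndarray,
    cfg: PipelineConfig | None = None,
    variant: str = "full",
    self_fusion: bool = False,
) -> tuple[np.ndarray, dict[str, object]]:
    """Enhance a low-dose slice; returns (output, intermediates).

    Parameters
    ----------
    img : 2-D array in [0, 1]
    cfg : PipelineConfig, optional
    variant : {"full", "no_vrm", "no_cem"}
        ``full`` fuses both branches; ``no_vrm`` drops the visibility
        branch (output = contrast branch); ``no_cem`` drops the contrast
        branch (output = visibility branch).
    self_fusion : bool
        For the ablation variants, fuse the surviving branch with itself
        instead of bypassing fusion.

    The intermediates dict is keyed by stage name (``sharpened``, ``L1``,
    ``L2``, ``weights``, ``fused``); ablated stages are absent.  The whole
    pipeline is deterministic: same input and config, bit-identical output.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    cfg = cfg or PipelineConfig()
    arr = validate_image(img)

    z = sharpen(arr, cfg)
    intermediates: dict[str, object] = {"sharpened": z}

    L1 = restore_visibility(z, cfg) if variant != "no_vrm" else None
    L2 = enhance_contrast(z, cfg) if variant != "no_cem" else None
    if L1 is not None:
        intermediates["L1"] = L1
    if L2 is not None:
        intermediates["L2"] = L2

    if variant == "full":
        out, stack = perceptual_fusion(L1, L2, cfg)
        intermediates["weights"] = stack
        intermediates["fused"] = out
    else:
        branch = L2 if variant == "no_vrm" else L1
        if self_fusion:
            out, stack = perceptual_fusion(branch, branch, cfg)
            intermediates["weights"] = stack
            intermediates["fused"] = out
        else:
            out = branch
    return out, intermediates
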