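"""Reading and writing grayscale slice images.

Supported on disk: 8/16-bit grayscale PNG and TIFF (read/write) and
single-frame grayscale DICOM (read only).  Everything is normalized to
float64 intensities in [0, 1] on load; integer files divide by the
bit-depth maximum, DICOM applies rescale slope/intercept and is then
min-max scaled.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import logger, validate_image

__all__ = ["load_image", "save_image"]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}

# Rec. 601 luminance, used only when a genuinely coloured image sneaks in.
_LUMA = np.array([0.299, 0.587, 0.114])


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        if np.array_equal(arr[:, :, 0], arr[:, :, 1]) and np.array_equal(
            arr[:, :, 0], arr[:, :, 2]
        ):
            return arr[:, :, 0]
        logger.warning(
            "%s is a colour image; converting to luminance (pipeline is "
            "defined on single-channel CBCT slices)",
            path,
        )
        return arr.astype(np.float64) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    return arr


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"only single-frame grayscale DICOM supported, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image and normalize it to [0, 1].

    8-bit integers divide by 255, 16-bit by 65535.  Float images are
    assumed to already be on the [0, 1] scale and are clipped to it with
    a warning if they stray outside.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _load_dicom(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises plugin-specific errors
        raise IOError(f"could not read {path}: {exc}") from exc
    raw = _collapse_channels(np.asarray(raw), path)
    if raw.dtype == np.uint8:
        arr = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        arr = raw.astype(np.float64) / 65535.0
    elif np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        arr = raw.astype(np.float64) / float(info.max)
    else:
        arr = raw.astype(np.float64)
        if arr.min() < 0.0 or arr.max() > 1.0:
            logger.warning("%s: float intensities outside [0, 1]; clipping", path)
            arr = np.clip(arr, 0.0, 1.0)
    return validate_image(arr, str(path))


def save_image(img: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Quantize *img* to 8 or 16 bits and write PNG/TIFF.

    Values are clipped to [0, 1] before quantization, so a reload agrees
    with the input within one quantization step per pixel.
    """
    arr = validate_image(img)
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    qmax = 2**bit_depth - 1
    quant = np.rint(np.clip(arr, 0.0, 1.0) * qmax)
    out = quant.astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = Path(path)
    try:
        iio.imwrite(path, out)
    except Exception as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
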