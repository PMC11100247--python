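"""Image quality measures.

Average gradient (AG) is the first-party no-reference sharpness proxy:
higher AG means more local detail.  PSNR is a full-reference helper for
synthetic-phantom recovery checks.  Learned no-reference scores (BRISQUE,
NIQE, FADE) are deliberately not reimplemented — each is its own published
method with trained parameters; :func:`third_party_scores` forwards to an
installed implementation if one exists and is non-authoritative.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import validate_image

__all__ = ["average_gradient", "psnr", "third_party_scores", "batch_metrics"]

PSNR_CAP_DB = 99.0


def average_gradient(img: np.ndarray) -> float:
    """Mean local gradient magnitude on the [0, 1] intensity scale.

    Forward finite differences along rows and columns on the common
    (H-1) x (W-1) grid; AG = mean sqrt((dx^2 + dy^2) / 2).  Zero for a
    constant image; scales linearly with intensity scaling.  Magnitudes
    depend on the intensity scale, so only orderings are comparable
    across differently scaled sources.
    """
    arr = validate_image(img)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("average gradient needs height and width >= 2")
    dx = arr[1:, :-1] - arr[:-1, :-1]
    dy = arr[:-1, 1:] - arr[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on the [0, 1] scale.

    Identical images are reported as the cap ``PSNR_CAP_DB`` (99 dB)
    rather than infinity.
    """
    ra = validate_image(ref, "ref")
    ta = validate_image(test, "test")
    if ra.shape != ta.shape:
        raise ValueError(f"shape mismatch: {ra.shape} vs {ta.shape}")
    mse = float(np.mean((ra - ta) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(10.0 * np.log10(1.0 / mse), PSNR_CAP_DB)


def third_party_scores(img: np.ndarray) -> dict[str, float]:
    """Optional learned no-reference scores from installed third parties.

    Tries piq (BRISQUE) if available; returns an empty dict otherwise.
    These scores are implementation-dependent and non-authoritative.
    """
    arr = validate_image(img)
    scores: dict[str, float] = {}
    try:  # pragma: no cover - optional dependency
        import piq  # type: ignore
        import torch  # type: ignore

        t = torch.from_numpy(arr[None, None].astype("float32"))
        scores["brisque"] = float(piq.brisque(t, data_range=1.0))
    except Exception:
        pass
    return scores


def batch_metrics(paths: Iterable[str | Path]) -> list[dict[str, float | str]]:
    """Compute per-file metrics; returns one row dict per image."""
    from .io import load_image

    rows: list[dict[str, float | str]] = []
    for p in paths:
        img = load_image(p)
        row: dict[str, float | str] = {
            "filename": Path(p).name,
            "AG": average_gradient(img),
        }
        row.update(third_party_scores(img))
        rows.append(row)
    return rows


def write_metrics_csv(rows: list[dict[str, float | str]], path: str | Path) -> None:
    """Write batch_metrics rows to CSV (union of columns, filename first)."""
    cols: list[str] = ["filename"]
    for row in rows:
        for k in row:
            if k not in cols:
                cols.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        writer.writerows(rows)
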