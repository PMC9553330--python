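"""Pre-training image conditioning: denoising smoothers and normalization.

Normalization is per-image so inference never depends on training-set
statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateInputError, ParameterError
from .imaging_io import ImageRecord

__all__ = ["smooth", "normalize"]


def _as_record(image) -> ImageRecord:
    if isinstance(image, ImageRecord):
        return image
    return ImageRecord(np.asarray(image))


def smooth(image, method: str = "gaussian", strength: float = 1.0) -> ImageRecord:
    """Denoise an image before training.

    gaussian: ``strength`` is the kernel sigma in pixels.
    median:   ``strength`` is the (odd) window size; values < 3 round up to 3.
    """
    rec = _as_record(image)
    if strength <= 0:
        raise ParameterError("strength must be > 0")
    px = rec.pixels.astype(np.float64)
    if method == "gaussian":
        out = ndimage.gaussian_filter(px, sigma=strength)
    elif method == "median":
        size = max(3, int(round(strength)) | 1)
        out = ndimage.median_filter(px, size=size)
    else:
        raise ParameterError(f"unknown smoothing method {method!r}")
    return ImageRecord(out, rec.spacing, rec.source_path)


def normalize(image, mode: str = "zscore") -> ImageRecord:
    """Per-image intensity normalization: zscore (mean 0, sd 1) or minmax [0, 1]."""
    rec = _as_record(image)
    px = rec.pixels.astype(np.float64)
    if mode == "zscore":
        sd = px.std()
        if sd == 0:
            raise DegenerateInputError("constant image cannot be z-scored")
        out = (px - px.mean()) / sd
    elif mode == "minmax":
        lo, hi = px.min(), px.max()
        out = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    return ImageRecord(out, rec.spacing, rec.source_path)
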