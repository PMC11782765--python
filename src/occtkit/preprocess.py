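"""Four-stage enhancement chain for OCT B-scans.

Order: white-border removal -> grayscale erosion -> median filtering ->
alpha-beta (gain/bias) correction. Erosion and the median filter use
edge replication at the image boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    erosion_kernel: int = 5
    median_window: int = 3
    alpha: float = 1.0
    beta: float = 2.0
    border_white_level: int = 245
    border_white_fraction: float = 0.9

    def __post_init__(self):
        if self.erosion_kernel < 1 or self.erosion_kernel % 2 == 0:
            raise PreprocessError("erosion_kernel must be odd and >= 1")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise PreprocessError("median_window must be odd and >= 1")
        if self.alpha <= 0:
            raise PreprocessError("alpha must be positive")
        if not -127 <= self.beta <= 127:
            raise PreprocessError("beta must lie in [-127, 127]")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise PreprocessError("expected a 2-D grayscale image")
    if img.size == 0:
        raise PreprocessError("empty image")
    return img


def remove_white_border(img: np.ndarray,
                        cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Crop contiguous near-white margin rows/columns from each edge.

    A margin line is white when at least ``border_white_fraction`` of its
    pixels are >= ``border_white_level``. Raises if the whole image is white.
    """
    img = _check_image(img)
    level, frac = cfg.border_white_level, cfg.border_white_fraction
    white = img >= level

    def white_run(fractions) -> int:
        n = 0
        for f in fractions:
            if f >= frac:
                n += 1
            else:
                break
        return n

    row_frac = white.mean(axis=1)
    col_frac = white.mean(axis=0)
    top = white_run(row_frac)
    bottom = white_run(row_frac[::-1])
    left = white_run(col_frac)
    right = white_run(col_frac[::-1])
    if top + bottom >= img.shape[0] or left + right >= img.shape[1]:
        raise PreprocessError("image is entirely white; nothing left after crop")
    h, w = img.shape
    return img[top:h - bottom, left:w - right]


def erode(img: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Grayscale erosion: local minimum over a kernel x kernel window."""
    img = _check_image(img)
    if kernel < 1 or kernel % 2 == 0:
        raise PreprocessError("erosion kernel must be odd and >= 1")
    return ndimage.grey_erosion(img, size=(kernel, kernel), mode="nearest")


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Sliding-window median with edge replication."""
    img = _check_image(img)
    if window < 1 or window % 2 == 0:
        raise PreprocessError("median window must be odd and >= 1")
    return ndimage.median_filter(img, size=window, mode="nearest")


def adjust_alpha_beta(img: np.ndarray, alpha: float = 1.0,
                      beta: float = 2.0) -> np.ndarray:
    """Per-pixel gain/bias: clip(round(alpha * f + beta), 0, 255).

    Rounding is half-up to the nearest integer.
    """
    img = _check_image(img)
    if alpha <= 0:
        raise PreprocessError("alpha must be positive")
    out = np.floor(alpha * img.astype(np.float64) + beta + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def preprocess(img: np.ndarray,
               cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Full chain: border removal -> erosion -> median -> alpha-beta."""
    out = remove_white_border(img, cfg)
    out = erode(out, cfg.erosion_kernel)
    out = median_filter(out, cfg.median_window)
    return adjust_alpha_beta(out, cfg.alpha, cfg.beta)
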