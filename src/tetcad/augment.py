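"""Training-time image augmentation.

Mirrors the variability of scanned/re-thresholded reports: slight Gaussian
blurring and re-binarization with different thresholds obtained by simple
(jittered) thresholding, Otsu's between-class-variance criterion, or
local-mean adaptive thresholding.  Every mode is deterministic given
(image, mode, seed).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["augment", "otsu_threshold", "AUGMENT_MODES"]

AUGMENT_MODES = ("blur", "simple_threshold", "otsu", "adaptive")


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's optimal threshold by exhaustive search over the 256 candidates.

    Maximizes the between-class variance w0 * w1 * (mu0 - mu1)^2 of the
    split  {v <= t} / {v > t}; the lowest maximizing t is returned.
    """
    hist = np.bincount(np.asarray(gray, dtype=np.uint8).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist)
    w1 = total - w0
    cum_mean = np.cumsum(hist * np.arange(256))
    grand_mean = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))


def augment(image: np.ndarray, mode: str, seed: int = 0, *,
            blur_sigma_range: tuple[float, float] = (0.4, 1.0),
            threshold_jitter: int = 40,
            adaptive_window: int = 31,
            adaptive_offset: float = 10.0) -> np.ndarray:
    """Apply one augmentation mode to a grayscale uint8 image.

    - ``blur``: small-radius Gaussian smoothing (sigma drawn from
      *blur_sigma_range*);
    - ``simple_threshold``: binarize at 128 +- a seed-jittered offset;
    - ``otsu``: binarize at the Otsu-optimal threshold;
    - ``adaptive``: binarize against the local mean over
      *adaptive_window*, shifted by *adaptive_offset*.

    Thresholded outputs keep dark traces at 0 on a 255 background.
    """
    gray = np.asarray(image)
    if gray.ndim != 2:
        raise ValueError(f"augment expects a single-plane image, got shape {gray.shape}")
    rng = np.random.default_rng(seed)
    if mode == "blur":
        sigma = rng.uniform(*blur_sigma_range)
        return np.clip(np.rint(
            ndimage.gaussian_filter(gray.astype(np.float64), sigma=sigma)
        ), 0, 255).astype(np.uint8)
    if mode == "simple_threshold":
        t = 128 + int(rng.integers(-threshold_jitter, threshold_jitter + 1))
        return np.where(gray > t, 255, 0).astype(np.uint8)
    if mode == "otsu":
        return np.where(gray > otsu_threshold(gray), 255, 0).astype(np.uint8)
    if mode == "adaptive":
        local_mean = ndimage.uniform_filter(gray.astype(np.float64), size=adaptive_window)
        return np.where(gray > local_mean - adaptive_offset, 255, 0).astype(np.uint8)
    raise ValueError(f"unknown augmentation mode {mode!r}; expected one of {AUGMENT_MODES}")
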