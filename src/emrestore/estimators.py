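"""Noise-level and blur-level estimation.

Two median-absolute-deviation noise estimators are provided:

* ``mad_raw`` — the plugin's printed form, sigma_hat = med(|y - med(y)|),
  applied directly to pixel intensities. Robust but biased: it conflates
  signal texture with noise, and even on pure Gaussian noise the median of
  |N(0, sigma)| is 0.6745*sigma, not sigma.
* ``mad_wavelet`` — the Gaussian-consistent variant used by parameter
  calibration: med(|d|)/0.6745 over the finest diagonal (HH) wavelet detail
  coefficients, where smooth signal content is largely absent.

The blur metric compares first-order pixel variation of the image against a
1-D moving-average smoothed copy, separately along x and y; the final score
is the maximum of the two directional values and lies in [0, 1] (0 = sharp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .core import ImageVolume

MAD_GAUSSIAN_CONSTANT = 0.6745  # median of |N(0,1)|


@dataclass
class NoiseEstimate:
    sigma_hat: float
    method: str  # 'mad_raw' | 'mad_wavelet'

    def __post_init__(self):
        if self.sigma_hat < 0:
            raise ValueError("sigma_hat must be >= 0")


@dataclass
class BlurEstimate:
    b: float
    b_x: float
    b_y: float
    smoothing_len: int

    def __post_init__(self):
        if not (0.0 <= self.b <= 1.0):
            raise ValueError("blur metric must lie in [0, 1]")


def _as_array(image) -> np.ndarray:
    if isinstance(image, ImageVolume):
        return image.data
    return np.asarray(image, dtype=np.float64)


def estimate_noise_mad(image, method: str = "mad_wavelet") -> NoiseEstimate:
    """Median-absolute-deviation noise estimate on the [0, 1] scale."""
    arr = _as_array(image)
    if arr.size < 2:
        raise ValueError("need at least 2 pixels to estimate noise")
    if method == "mad_raw":
        sigma = float(np.median(np.abs(arr - np.median(arr))))
    elif method == "mad_wavelet":
        planes = arr if arr.ndim == 3 else arr[np.newaxis]
        details = []
        for plane in planes:
            _, (_, _, hh) = pywt.dwt2(plane, "db1", mode="symmetric")
            details.append(np.abs(hh).ravel())
        sigma = float(np.median(np.concatenate(details)) / MAD_GAUSSIAN_CONSTANT)
    else:
        raise ValueError(f"method must be 'mad_raw' or 'mad_wavelet', got {method!r}")
    return NoiseEstimate(sigma_hat=sigma, method=method)


def _directional_blur(plane: np.ndarray, smoothing_len: int) -> float:
    """Blur level along the last (x) axis of a 2-D plane."""
    smoothed = ndimage.uniform_filter1d(plane, smoothing_len, axis=1, mode="reflect")
    dy = np.abs(np.diff(plane, axis=1))  # |D_x y|, last column dropped
    dys = np.abs(np.diff(smoothed, axis=1))
    v = np.maximum(0.0, dy - dys)
    total = dy.sum()
    if total == 0:
        return None  # constant along this direction; metric undefined
    return float((total - v.sum()) / total)


def estimate_blur(image, smoothing_len: int = 9) -> BlurEstimate:
    """Directional blur metric in [0, 1]; b = max(b_x, b_y).

    Variations are taken as absolute first-order forward differences;
    smoothing uses a 1-D moving average of length ``smoothing_len``.
    Constant images are rejected (the normalizing total variation is zero).
    """
    if smoothing_len < 2:
        raise ValueError("smoothing_len must be >= 2")
    arr = _as_array(image)
    planes = arr if arr.ndim == 3 else arr[np.newaxis]
    bx_vals, by_vals = [], []
    for plane in planes:
        bx = _directional_blur(plane, smoothing_len)
        by = _directional_blur(plane.T, smoothing_len)
        if bx is not None:
            bx_vals.append(bx)
        if by is not None:
            by_vals.append(by)
    if not bx_vals and not by_vals:
        raise ValueError("constant image: blur metric undefined (zero total variation)")
    # a direction with zero total variation carries no blur evidence -> 0
    b_x = float(np.mean(bx_vals)) if bx_vals else 0.0
    b_y = float(np.mean(by_vals)) if by_vals else 0.0
    return BlurEstimate(b=max(b_x, b_y), b_x=b_x, b_y=b_y, smoothing_len=smoothing_len)
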