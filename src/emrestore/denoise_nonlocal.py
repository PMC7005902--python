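"""Nonlocal means denoising and nonlocal-means-regularized deconvolution.

Pixel similarity is measured as the raw squared L2 distance between the
(2B+1)^2 intensity patches around two pixels; the averaging weight is
w_ij = exp(-0.5 * ||y_Ni - y_Nj||^2 / h), evaluated for every j inside the
(2W+1)^2 search window around i and normalized to unit sum. Note the damping
parameter ``h`` divides the squared distance directly (not h^2) and patch
distances are not per-pixel normalized, so published h values transfer only
at the stated patch size B. Patches reaching past the border use mirror
padding.

Deconvolution reuses the weights, computed once on an NLM-denoised pilot
image and held fixed, as a quadratic nonlocal prior:
min_x ||y - Hx||^2 + lam * sum_ij w_ij (x_i - x_j)^2, solved by monotone
first-order descent. The double sum is restricted to the same search window
used for denoising (weights outside it are numerically negligible). H is
applied as a periodic Gaussian convolution so its adjoint is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import gaussian_kernel2d


@dataclass
class NlmParams:
    h: float = 0.23
    B: int = 4  # half patch size
    W: int = 5  # half search window size
    normalize_patch: bool = False  # divide patch SSD by patch pixel count

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.W < self.B:
            raise ValueError("W must be >= B")


@dataclass
class NlmDeconvParams(NlmParams):
    lam: float = 0.05
    sigma_psf: float = 0.0
    n_iter: int = 20

    def __post_init__(self):
        super().__post_init__()
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.sigma_psf < 0:
            raise ValueError("sigma_psf must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _search_offsets(W: int):
    return [(dy, dx) for dy in range(-W, W + 1) for dx in range(-W, W + 1)]


def _offset_weights(y: np.ndarray, params: NlmParams):
    """Per-offset weight maps.

    Returns (pad, padded image, list of (offset, weight map over image
    pixels)). The weight for pixel i and offset o is
    exp(-0.5 * SSD(patch_i, patch_{i+o}) / h) on the mirror-padded image.
    """
    h_img, w_img = y.shape
    B, W = params.B, params.W
    pad = B + W
    yp = np.pad(y, pad, mode="symmetric")
    patch_px = (2 * B + 1) ** 2
    entries = []
    for dy, dx in _search_offsets(W):
        diff2 = np.zeros_like(yp)
        ys0, ys1 = max(0, -dy), yp.shape[0] - max(0, dy)
        xs0, xs1 = max(0, -dx), yp.shape[1] - max(0, dx)
        diff2[ys0:ys1, xs0:xs1] = (
            yp[ys0:ys1, xs0:xs1] - yp[ys0 + dy : ys1 + dy, xs0 + dx : xs1 + dx]
        ) ** 2
        ssd = ndimage.uniform_filter(diff2, size=2 * B + 1, mode="constant") * patch_px
        ssd = ssd[pad : pad + h_img, pad : pad + w_img]
        if params.normalize_patch:
            ssd = ssd / patch_px
        entries.append(((dy, dx), np.exp(-0.5 * ssd / params.h)))
    return pad, yp, entries


def nlm_denoise(image: np.ndarray, params: NlmParams) -> np.ndarray:
    """Nonlocal means: normalized patch-similarity weighted averaging."""
    y = np.asarray(image, dtype=np.float64)
    if min(y.shape) <= 2 * params.B + 1:
        raise ValueError("image must be larger than the patch diameter 2B+1")
    pad, yp, entries = _offset_weights(y, params)
    h_img, w_img = y.shape
    num = np.zeros_like(y)
    den = np.zeros_like(y)
    for (dy, dx), wgt in entries:
        neighbor = yp[pad + dy : pad + dy + h_img, pad + dx : pad + dx + w_img]
        num += wgt * neighbor
        den += wgt
    return num / den


def _reflect_index(idx: np.ndarray, n: int) -> np.ndarray:
    """Map out-of-range indices back inside by mirror (symmetric) reflection."""
    idx = np.where(idx < 0, -idx - 1, idx)
    idx = np.where(idx >= n, 2 * n - idx - 1, idx)
    return idx


def nlm_weight_graph(y: np.ndarray, params: NlmParams):
    """Sparse nonlocal weight graph on the image grid.

    Returns a list of (flat neighbor index array, weight array) pairs, one
    per search offset, with out-of-image neighbors mirrored back inside --
    the graph the deconvolution prior and its dense-algebra form share.
    """
    h_img, w_img = y.shape
    _, _, entries = _offset_weights(y, params)
    ys = np.arange(h_img)
    xs = np.arange(w_img)
    graph = []
    for (dy, dx), wgt in entries:
        jy = _reflect_index(ys + dy, h_img)
        jx = _reflect_index(xs + dx, w_img)
        flat_j = (jy[:, None] * w_img + jx[None, :]).ravel()
        graph.append((flat_j, wgt.ravel()))
    return graph


def _nlm_prior_value_grad(x: np.ndarray, graph, lam: float):
    """lam * sum_ij w_ij (x_i - x_j)^2 and its exact gradient."""
    xf = x.ravel()
    val = 0.0
    grad = np.zeros_like(xf)
    for flat_j, wgt in graph:
        d = xf - xf[flat_j]
        wd = wgt * d
        val += float((wd * d).sum())
        grad += 2.0 * wd
        np.subtract.at(grad, flat_j, 2.0 * wd)
    return lam * val, lam * grad.reshape(x.shape)


def nlm_deconv(image: np.ndarray, params: NlmDeconvParams) -> np.ndarray:
    """Nonlocal-prior deconvolution with weights fixed on an NLM pilot."""
    y = np.asarray(image, dtype=np.float64)
    pilot = nlm_denoise(y, NlmParams(params.h, params.B, params.W, params.normalize_patch))
    graph = nlm_weight_graph(pilot, params)
    if params.sigma_psf > 0:
        kernel = gaussian_kernel2d(params.sigma_psf)
        big = np.zeros(y.shape)
        kh, kw = kernel.shape
        big[:kh, :kw] = kernel
        Hf = np.fft.fft2(np.roll(big, (-(kh // 2), -(kw // 2)), axis=(0, 1)))

        def apply_H(v):
            return np.real(np.fft.ifft2(Hf * np.fft.fft2(v)))

        def apply_Ht(v):
            return np.real(np.fft.ifft2(np.conj(Hf) * np.fft.fft2(v)))

    else:

        def apply_H(v):
            return v

        def apply_Ht(v):
            return v

    def objective_grad(x):
        res = apply_H(x) - y
        val = float((res * res).sum())
        grad = 2.0 * apply_Ht(res)
        pv, pg = _nlm_prior_value_grad(x, graph, params.lam)
        return val + pv, grad + pg

    x = y.copy()
    f, g = objective_grad(x)
    t = 0.25
    for _ in range(params.n_iter):
        gnorm2 = float((g * g).sum())
        if gnorm2 <= 1e-28:
            break
        accepted = False
        for _ in range(60):
            x_new = x - t * g
            f_new, g_new = objective_grad(x_new)
            if f_new < f:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        s = x_new - x
        dg = g_new - g
        sy = float((s * dg).sum())
        if sy > 1e-30:
            t = float((s * s).sum()) / sy
        x, f, g = x_new, f_new, g_new
    return x
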