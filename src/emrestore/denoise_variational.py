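"""Energy-minimization restoration: Tikhonov and total-variation.

Tikhonov solves  min_x ||y - Hx||^2 + lam ||Lx||^2  with L the 5-point
discrete Laplacian and H a Gaussian PSF (identity when sigma_psf = 0), by
conjugate gradients on the normal equations under periodic boundary
conditions (which makes an FFT closed form available as an independent
check).

TV solves the ROF-type problem  min_x ||y - x||^2 + lam * sum_i
sqrt([Dx x]_i^2 + [Dy x]_i^2 + eps^2)  with an epsilon-smoothed gradient and
first-order descent (Barzilai-Borwein step initialization with monotone
backtracking), so the objective is directly evaluable and non-increasing
across iterations. Volumes are processed slice-by-slice, so only the 2-D
difference terms appear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import gaussian_kernel2d

LAPLACIAN_STENCIL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class TikhonovParams:
    lam: float = 1.5
    sigma_psf: float = 0.0  # 0 -> pure denoising
    n_iter: int = 10

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.sigma_psf < 0:
            raise ValueError("sigma_psf must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class TvParams:
    lam: float = 0.1
    n_iter: int = 100
    eps: float = 1e-3

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def _periodic_otf(kernel: np.ndarray, shape) -> np.ndarray:
    """Embed a centered kernel into ``shape`` with wrap-around and FFT it."""
    h, w = shape
    kh, kw = kernel.shape
    big = np.zeros(shape)
    big[:kh, :kw] = kernel
    big = np.roll(big, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.fft2(big)


def tikhonov(image: np.ndarray, params: TikhonovParams, pad: int = 0) -> np.ndarray:
    """Conjugate-gradient Tikhonov restoration (periodic boundary).

    ``pad > 0`` mirror-pads the image before the periodic solve and crops
    afterwards, suppressing wrap-around artifacts on non-periodic data.
    """
    if pad > 0:
        yo = np.asarray(image, dtype=np.float64)
        xp = tikhonov(np.pad(yo, pad, mode="symmetric"), params, pad=0)
        return xp[pad : pad + yo.shape[0], pad : pad + yo.shape[1]]
    y = np.asarray(image, dtype=np.float64)
    if params.sigma_psf > 0:
        Hf = _periodic_otf(gaussian_kernel2d(params.sigma_psf), y.shape)
    else:
        Hf = np.ones(y.shape, dtype=complex)
    Lf = _periodic_otf(LAPLACIAN_STENCIL, y.shape)
    Af = np.abs(Hf) ** 2 + params.lam * np.abs(Lf) ** 2  # normal operator spectrum

    def apply_A(v):
        return np.real(np.fft.ifft2(Af * np.fft.fft2(v)))

    b = np.real(np.fft.ifft2(np.conj(Hf) * np.fft.fft2(y)))
    x = np.zeros_like(y)
    r = b.copy()
    p = r.copy()
    rs = float((r * r).sum())
    rs0 = rs
    growth_streak = 0
    for _ in range(params.n_iter):
        if rs <= 1e-30 * max(rs0, 1.0):
            break
        Ap = apply_A(p)
        alpha = rs / float((p * Ap).sum())
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = float((r * r).sum())
        # transient residual growth is normal for CG (only the A-norm error
        # is monotone); report divergence only on sustained large growth
        growth_streak = growth_streak + 1 if rs_new > rs else 0
        if rs_new > 10.0 * rs0 and growth_streak >= 5:
            warnings.warn("tikhonov: conjugate gradient diverging", RuntimeWarning)
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def _forward_diffs(x: np.ndarray):
    """Forward differences with Neumann boundary (zero at the last row/col)."""
    dx = np.zeros_like(x)
    dy = np.zeros_like(x)
    dx[:, :-1] = x[:, 1:] - x[:, :-1]
    dy[:-1, :] = x[1:, :] - x[:-1, :]
    return dx, dy


def _div_adjoint(px: np.ndarray, py: np.ndarray):
    """Negative adjoint of _forward_diffs: returns Dx^T px + Dy^T py."""
    out = np.zeros_like(px)
    out[:, :-1] -= px[:, :-1]
    out[:, 1:] += px[:, :-1]
    out[:-1, :] -= py[:-1, :]
    out[1:, :] += py[:-1, :]
    return out


def tv_objective(x: np.ndarray, y: np.ndarray, lam: float, eps: float) -> float:
    dx, dy = _forward_diffs(x)
    fidelity = float(((y - x) ** 2).sum())
    tv = float(np.sqrt(dx**2 + dy**2 + eps**2).sum())
    return fidelity + lam * tv


def _tv_gradient(x: np.ndarray, y: np.ndarray, lam: float, eps: float) -> np.ndarray:
    dx, dy = _forward_diffs(x)
    rho = np.sqrt(dx**2 + dy**2 + eps**2)
    return 2.0 * (x - y) + lam * _div_adjoint(dx / rho, dy / rho)


def tv_denoise(image: np.ndarray, params: TvParams) -> np.ndarray:
    """Smoothed-TV denoising by monotone first-order descent.

    Steps are initialized with the Barzilai-Borwein rule and backtracked
    (halved) until the objective decreases, so the energy is non-increasing
    across all iterations.
    """
    y = np.asarray(image, dtype=np.float64)
    if params.lam == 0:
        return y.copy()
    x = y.copy()
    f = tv_objective(x, y, params.lam, params.eps)
    g = _tv_gradient(x, y, params.lam, params.eps)
    # safe initial step: inverse of the data-term curvature
    t = 0.25
    for _ in range(params.n_iter):
        gnorm2 = float((g * g).sum())
        if gnorm2 <= 1e-28:
            break
        accepted = False
        for _ in range(60):
            x_new = x - t * g
            f_new = tv_objective(x_new, y, params.lam, params.eps)
            if f_new < f:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        g_new = _tv_gradient(x_new, y, params.lam, params.eps)
        s = x_new - x
        yv = g_new - g
        sy = float((s * yv).sum())
        if sy > 1e-30:
            t = float((s * s).sum()) / sy  # BB1 step for the next iteration
        x, f, g = x_new, f_new, g_new
    return x
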