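"""Local spatial filters: Gaussian smoothing, anisotropic diffusion, bilateral.

All three are convex-averaging filters on a single 2-D slice: outputs stay
within [min(input), max(input)]. Window sizes follow the plugin conventions
(7x7 Gaussian, 15x15 bilateral); diffusion is an explicit 4-neighbor
Perona-Malik scheme with a stability bound eta <= 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import convolve2d_reflect, gaussian_kernel2d

GAUSSIAN_WINDOW_RADIUS = 3  # fixed 7x7 window
BILATERAL_WINDOW_RADIUS = 7  # fixed 15x15 window
DIFFUSION_ETA_MAX = 0.25


@dataclass
class DiffusionParams:
    """Explicit anisotropic-diffusion settings.

    ``eta`` is the step size per iteration (stability requires eta <= 0.25 on
    the 4-neighbor stencil), ``kappa`` the edge threshold of the conductance
    function, ``variant`` chooses the exponential or rational conductance.
    """

    eta: float = 0.07
    n_iter: int = 5
    kappa: float = 0.18
    variant: str = "exponential"

    def __post_init__(self):
        if not (0.0 < self.eta <= DIFFUSION_ETA_MAX):
            raise ValueError(f"eta must lie in (0, {DIFFUSION_ETA_MAX}]")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.variant not in ("exponential", "rational"):
            raise ValueError("variant must be 'exponential' or 'rational'")


@dataclass
class BilateralParams:
    sigma_sp: float = 3.0  # spatial kernel std, pixels
    sigma_int: float = 0.1  # intensity kernel std, [0,1] scale

    def __post_init__(self):
        if self.sigma_sp <= 0 or self.sigma_int <= 0:
            raise ValueError("sigma_sp and sigma_int must be > 0")


def gaussian_filter(image: np.ndarray, sigma_g: float) -> np.ndarray:
    """Convolve with a normalized 7x7 Gaussian kernel (mirror boundary)."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be > 0")
    kernel = gaussian_kernel2d(sigma_g, radius=GAUSSIAN_WINDOW_RADIUS)
    return convolve2d_reflect(image, kernel)


def conductance(s: np.ndarray, kappa: float, variant: str = "exponential") -> np.ndarray:
    """Edge-stopping function c(s): exp(-(s/kappa)^2) or 1/(1+(s/kappa)^2)."""
    r = (np.asarray(s, dtype=np.float64) / kappa) ** 2
    if variant == "exponential":
        return np.exp(-r)
    if variant == "rational":
        return 1.0 / (1.0 + r)
    raise ValueError("variant must be 'exponential' or 'rational'")


def anisotropic_diffusion(image: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """N explicit iterations of x <- x + eta * div(c(|grad x|) grad x).

    The divergence is discretized on the 4-neighbor stencil with the
    conductance evaluated per arm on the forward difference (Perona-Malik).
    Boundary arms see a replicated edge (zero difference), i.e. Neumann.
    """
    x = np.asarray(image, dtype=np.float64).copy()
    for _ in range(params.n_iter):
        d_n = np.zeros_like(x)
        d_s = np.zeros_like(x)
        d_e = np.zeros_like(x)
        d_w = np.zeros_like(x)
        d_n[1:, :] = x[:-1, :] - x[1:, :]
        d_s[:-1, :] = x[1:, :] - x[:-1, :]
        d_e[:, :-1] = x[:, 1:] - x[:, :-1]
        d_w[:, 1:] = x[:, :-1] - x[:, 1:]
        flux = sum(
            conductance(np.abs(d), params.kappa, params.variant) * d
            for d in (d_n, d_s, d_e, d_w)
        )
        x = x + params.eta * flux
    return x


def bilateral(image: np.ndarray, params: BilateralParams) -> np.ndarray:
    """Edge-preserving weighted mean over the fixed 15x15 window.

    Weights are the product of a spatial Gaussian on pixel distance and an
    intensity Gaussian on absolute intensity difference, normalized to unit
    sum per pixel; patches at borders use mirror padding.
    """
    y = np.asarray(image, dtype=np.float64)
    r = BILATERAL_WINDOW_RADIUS
    pad = np.pad(y, r, mode="symmetric")
    num = np.zeros_like(y)
    den = np.zeros_like(y)
    h, w = y.shape
    inv2sp = 1.0 / (2.0 * params.sigma_sp**2)
    inv2int = 1.0 / (2.0 * params.sigma_int**2)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = pad[r + dy : r + dy + h, r + dx : r + dx + w]
            wgt = np.exp(-(dy * dy + dx * dx) * inv2sp - (y - shifted) ** 2 * inv2int)
            num += wgt * shifted
            den += wgt
    return num / den
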