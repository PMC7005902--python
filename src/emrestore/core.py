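"""Canonical image containers and the forward degradation model.

Volumes are stored as float64 arrays indexed ``(z, y, x)`` with intensities
normalized to the unit interval. The acquisition model is

    y = H x + n,

where ``H`` is an isotropic 2-D Gaussian point-spread function applied
slice-by-slice and ``n`` is i.i.d. mean-zero Gaussian noise with constant
per-pixel variance. Restoration algorithms operate on (and may exceed) the
[0, 1] scale; clipping is an explicit export-time choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# algorithm registry: required parameter names and legal ranges
# ---------------------------------------------------------------------------

#: name -> {param: (low, high, low_inclusive)}; ``variant`` is a free string.
PARAM_SPECS: dict = {
    "gaussian": {"sigma_g": (0.0, 25.0, False)},
    "wavelet": {"T": (0.0, np.inf, True), "n_scales": (1, 12, True)},
    "anisotropic_diffusion": {
        "eta": (0.0, 0.25, False),
        "n_iter": (0, 10_000, True),
        "kappa": (0.0, np.inf, False),
    },
    "bilateral": {
        "sigma_sp": (0.0, np.inf, False),
        "sigma_int": (0.0, np.inf, False),
    },
    "tikhonov": {
        "lam": (0.0, np.inf, True),
        "sigma_psf": (0.0, np.inf, True),
        "n_iter": (1, 100_000, True),
    },
    "tv": {
        "lam": (0.0, np.inf, True),
        "n_iter": (1, 100_000, True),
        "eps": (0.0, np.inf, False),
    },
    "blsgsm": {
        "sigma_n": (0.0, np.inf, False),
        "J": (1, 8, True),
        "K_orient": (1, 16, True),
    },
    "nlm": {
        "h": (0.0, np.inf, False),
        "B": (1, 64, True),
        "W": (1, 256, True),
    },
    "nlm_deconv": {
        "h": (0.0, np.inf, False),
        "B": (1, 64, True),
        "W": (1, 256, True),
        "lam": (0.0, np.inf, True),
        "sigma_psf": (0.0, np.inf, True),
        "n_iter": (1, 100_000, True),
    },
}

#: optional parameters per algorithm (validated only if present)
OPTIONAL_PARAMS: dict = {
    "anisotropic_diffusion": {"variant"},
}


@dataclass
class ImageVolume:
    """A 3-D grayscale volume, ``data`` indexed ``(z, y, x)`` on [0, 1].

    A 2-D image is represented as a volume with a single z-plane.
    ``source_dtype`` records the original bit depth ('uint8', 'uint16' or
    'float') so an integer round-trip stays possible after processing.
    """

    data: np.ndarray
    voxel_size: Optional[Tuple[float, float, float]] = None
    source_dtype: str = "float"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D data, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image data contains NaN or Inf")
        if min(arr.shape) < 1:
            raise ValueError("all dimensions must have extent >= 1")
        self.data = arr

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def slice(self, z: int) -> np.ndarray:
        return self.data[z]

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.data.copy(),
            voxel_size=self.voxel_size,
            source_dtype=self.source_dtype,
            metadata=dict(self.metadata),
        )


@dataclass
class DegradationModel:
    """Forward model y = Hx + n.

    ``sigma_psf`` is the Gaussian PSF standard deviation in pixels (0 means
    H is the identity); ``sigma_noise`` the additive-noise standard deviation
    on the [0, 1] intensity scale.
    """

    sigma_psf: float = 0.0
    sigma_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_psf < 0:
            raise ValueError("sigma_psf must be >= 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


@dataclass
class AlgorithmSpec:
    """A restoration algorithm identity plus its full parameter set.

    Serializable; embedded in output metadata so a run can be reproduced
    bit-identically.
    """

    algorithm: str
    params: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def validate(self) -> "AlgorithmSpec":
        if self.algorithm not in PARAM_SPECS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose from {sorted(PARAM_SPECS)}"
            )
        spec = PARAM_SPECS[self.algorithm]
        optional = OPTIONAL_PARAMS.get(self.algorithm, set())
        required = set(spec)
        given = set(self.params)
        missing = required - given
        extra = given - required - optional
        if missing:
            raise ValueError(f"{self.algorithm}: missing parameters {sorted(missing)}")
        if extra:
            raise ValueError(f"{self.algorithm}: unexpected parameters {sorted(extra)}")
        for name, (lo, hi, lo_inc) in spec.items():
            v = self.params[name]
            ok = (v >= lo if lo_inc else v > lo) and v <= hi
            if not ok:
                bracket = "[" if lo_inc else "("
                raise ValueError(
                    f"{self.algorithm}: {name}={v} outside {bracket}{lo}, {hi}]"
                )
        if self.algorithm == "nlm" or self.algorithm == "nlm_deconv":
            if self.params["W"] < self.params["B"]:
                raise ValueError("nlm: W must be >= B")
        return self

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": dict(self.params),
            "version": self.version,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AlgorithmSpec":
        return cls(
            algorithm=d["algorithm"],
            params=dict(d["params"]),
            version=d.get("version", "0.1.0"),
        ).validate()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

_DTYPE_RANGES = {"uint8": (0.0, 255.0), "uint16": (0.0, 65535.0)}


def normalize_to_unit(raw: np.ndarray, declared_dtype: str = "float") -> ImageVolume:
    """Map raw pixel data onto [0, 1].

    Integer dtypes are scaled by their full dynamic range
    ``(raw - dtype_min) / (dtype_max - dtype_min)``; float data is min-max
    scaled only when it falls outside [0, 1]. The declared dtype is recorded
    on the returned volume for round-tripping.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot normalize: input contains NaN or Inf")
    if declared_dtype in _DTYPE_RANGES:
        lo, hi = _DTYPE_RANGES[declared_dtype]
        data = (arr - lo) / (hi - lo)
    elif declared_dtype == "float":
        amin, amax = float(arr.min()), float(arr.max())
        if amin < 0.0 or amax > 1.0:
            span = amax - amin
            data = (arr - amin) / span if span > 0 else np.zeros_like(arr)
        else:
            data = arr
    else:
        raise ValueError(
            f"declared_dtype must be 'uint8', 'uint16' or 'float', got {declared_dtype!r}"
        )
    return ImageVolume(data, source_dtype=declared_dtype)


# ---------------------------------------------------------------------------
# PSF kernel and degradation
# ---------------------------------------------------------------------------


def gaussian_kernel2d(sigma: float, radius: Optional[int] = None) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel, truncated and renormalized to unit sum.

    Default truncation radius is ceil(4*sigma) pixels each side (the PSF
    convention); pass ``radius`` explicitly for fixed-window filters.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if radius is None:
        radius = int(np.ceil(4.0 * sigma)) if sigma > 0 else 0
    if sigma == 0:
        k = np.zeros((2 * radius + 1, 2 * radius + 1))
        k[radius, radius] = 1.0
        return k
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def convolve2d_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2-D convolution with mirror (edge-repeating) boundary handling."""
    return ndimage.convolve(np.asarray(image, dtype=np.float64), kernel, mode="reflect")


def apply_psf(image: np.ndarray, sigma_psf: float) -> np.ndarray:
    """Blur one slice with the truncated, normalized Gaussian PSF."""
    if sigma_psf == 0:
        return np.asarray(image, dtype=np.float64).copy()
    return convolve2d_reflect(image, gaussian_kernel2d(sigma_psf))


def degrade(x: ImageVolume, model: DegradationModel) -> ImageVolume:
    """Apply the forward model y = Hx + n slice-by-slice.

    Blur is a per-slice 2-D Gaussian convolution with reflective boundary;
    noise is i.i.d. N(0, sigma_noise^2) drawn from ``model.seed``. The output
    is deliberately NOT clipped: restoration inputs may exceed [0, 1].
    """
    out = np.empty_like(x.data)
    for z in range(x.shape[0]):
        out[z] = apply_psf(x.data[z], model.sigma_psf)
    if model.sigma_noise > 0:
        rng = np.random.default_rng(model.seed)
        out = out + rng.normal(0.0, model.sigma_noise, size=out.shape)
    vol = ImageVolume.__new__(ImageVolume)
    vol.data = out
    vol.voxel_size = x.voxel_size
    vol.source_dtype = x.source_dtype
    vol.metadata = dict(x.metadata)
    vol.metadata["degradation"] = {
        "sigma_psf": model.sigma_psf,
        "sigma_noise": model.sigma_noise,
        "seed": model.seed,
    }
    return vol


def clip_unit(volume: ImageVolume) -> ImageVolume:
    """Clip intensities to [0, 1] (export helper; never applied implicitly)."""
    v = volume.copy()
    np.clip(v.data, 0.0, 1.0, out=v.data)
    return v
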