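"""EM-like ground-truth phantoms with known structure and object counts.

Three families mimic the structures the restoration pipeline is judged on:

* ``membranes`` — a Voronoi cell partition whose boundaries are dilated to a
  configurable width, dark membranes on a bright, gently textured background
  (stand-in for neuronal membrane stacks);
* ``sarcomere`` — alternating dark A-bands and bright I-bands of striated
  muscle;
* ``filaments`` — non-overlapping bright disks on a dark background, i.e.
  filament cross-sections with an exactly known count.

All phantoms are noise-free: degradation is applied only through
:func:`emrestore.core.degrade`, so every experiment has an exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import ImageVolume

#: retry cap for rejection-sampled filament placement
PLACEMENT_RETRY_CAP = 10_000

#: background texture amplitude for the membrane phantom (a flat background
#: would make every denoiser look perfect)
TEXTURE_AMPLITUDE = 0.05


@dataclass
class PhantomSpec:
    """Configuration for one phantom image/volume."""

    kind: str  # 'membranes' | 'sarcomere' | 'filaments'
    shape: Tuple[int, ...] = (256, 256)  # (y, x) or (z, y, x)
    seed: int = 0
    # membranes
    membrane_width: int = 5
    n_cells: int = 12
    # sarcomere
    band_period: int = 24
    band_contrast: float = 0.3
    duty_cycle: float = 0.5
    # filaments
    n_filaments: int = 25
    radius: int = 6
    # intensity levels
    foreground: float = 0.3  # membranes / A-band / disk level depending on kind
    background: float = 0.75

    def __post_init__(self):
        if self.kind not in ("membranes", "sarcomere", "filaments"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be (y, x) or (z, y, x)")
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1")
        if self.band_period < 2:
            raise ValueError("band_period must be >= 2")
        if self.band_contrast < 0:
            raise ValueError("band_contrast must be >= 0")

    @property
    def plane_shape(self) -> Tuple[int, int]:
        return tuple(self.shape[-2:])

    @property
    def n_planes(self) -> int:
        return 1 if len(self.shape) == 2 else int(self.shape[0])

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PhantomSpec":
        d = json.loads(s)
        d["shape"] = tuple(d["shape"])
        return cls(**d)


def _as_volume(plane: np.ndarray, spec: PhantomSpec) -> ImageVolume:
    stack = np.repeat(plane[np.newaxis], spec.n_planes, axis=0)
    return ImageVolume(stack, metadata={"phantom": spec.to_json()})


def _stack_mask(mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    return np.repeat(mask[np.newaxis], spec.n_planes, axis=0)


def _smooth_noise(shape, rng, sigma=4.0):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")


def make_membranes(spec: PhantomSpec) -> Tuple[ImageVolume, np.ndarray]:
    """Voronoi-style cell partition with boundaries dilated to membrane_width.

    Returns the image volume and a binary {0,1} membrane mask of the same
    shape. Dark membranes on a bright background carrying low-amplitude
    smoothed texture.
    """
    if spec.n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    ny, nx = spec.plane_shape
    if spec.n_cells * 16 > ny * nx:
        raise ValueError(f"shape {spec.plane_shape} too small for {spec.n_cells} cells")
    rng = np.random.default_rng(spec.seed)
    sites = np.column_stack([rng.uniform(0, ny, spec.n_cells), rng.uniform(0, nx, spec.n_cells)])
    yy, xx = np.mgrid[0:ny, 0:nx]
    # nearest-site label map
    d2 = (yy[..., None] - sites[:, 0]) ** 2 + (xx[..., None] - sites[:, 1]) ** 2
    labels = np.argmin(d2, axis=-1)
    # boundary pixels: any 4-neighbor with a different label
    boundary = np.zeros((ny, nx), dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[1:, :] |= labels[1:, :] != labels[:-1, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    # dilate to the requested width via the distance transform
    dist = ndimage.distance_transform_edt(~boundary)
    mask = (dist <= (spec.membrane_width - 1) / 2.0).astype(np.uint8)
    texture = TEXTURE_AMPLITUDE * _smooth_noise((ny, nx), rng)
    img = np.full((ny, nx), spec.background) + texture
    img[mask == 1] = spec.foreground
    img = np.clip(img, 0.0, 1.0)
    return _as_volume(img, spec), _stack_mask(mask, spec)


def make_sarcomere(spec: PhantomSpec) -> Tuple[ImageVolume, np.ndarray]:
    """Alternating horizontal A (dark) / I (bright) bands.

    Band transitions are smoothed slightly; the returned label mask marks
    A-band pixels 1 and I-band pixels 2 from the un-smoothed square wave.
    """
    if spec.band_contrast < 0:
        raise ValueError("band_contrast must be >= 0")
    ny, nx = spec.plane_shape
    y = np.arange(ny)
    phase = (y % spec.band_period) / spec.band_period
    a_band = phase < spec.duty_cycle  # True where A (dark)
    mid = (spec.foreground + spec.background) / 2.0
    half = spec.band_contrast / 2.0
    profile = np.where(a_band, mid - half, mid + half).astype(np.float64)
    if spec.band_contrast > 0:
        profile = ndimage.gaussian_filter1d(profile, 1.0, mode="wrap")
    img = np.repeat(profile[:, None], nx, axis=1)
    img = np.clip(img, 0.0, 1.0)
    mask = np.where(a_band, 1, 2).astype(np.uint8)[:, None].repeat(nx, axis=1)
    return _as_volume(img, spec), _stack_mask(mask, spec)


def make_filaments(spec: PhantomSpec) -> Tuple[ImageVolume, np.ndarray, int]:
    """Bright non-overlapping disks on a dark background.

    Disk centers are rejection-sampled so pairwise center distance exceeds
    2*radius + 2 px; placement failure after the retry cap raises with the
    count achieved. Returns (image, binary mask, true_count).
    """
    ny, nx = spec.plane_shape
    r = spec.radius
    rng = np.random.default_rng(spec.seed)
    centers: list = []
    attempts = 0
    min_d2 = (2 * r + 2) ** 2
    while len(centers) < spec.n_filaments:
        if attempts >= PLACEMENT_RETRY_CAP:
            raise ValueError(
                f"could not place {spec.n_filaments} filaments "
                f"(placed {len(centers)} after {attempts} attempts)"
            )
        attempts += 1
        cy = rng.uniform(r + 1, ny - r - 1)
        cx = rng.uniform(r + 1, nx - r - 1)
        if all((cy - a) ** 2 + (cx - b) ** 2 > min_d2 for a, b in centers):
            centers.append((cy, cx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros((ny, nx), dtype=np.uint8)
    for cy, cx in centers:
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1
    lo, hi = sorted((spec.foreground, spec.background))
    img = np.full((ny, nx), lo)
    img[mask == 1] = hi
    return _as_volume(img, spec), _stack_mask(mask, spec), spec.n_filaments


def make_phantom(spec: PhantomSpec):
    """Dispatch on ``spec.kind``; filaments additionally return the count."""
    if spec.kind == "membranes":
        return make_membranes(spec)
    if spec.kind == "sarcomere":
        return make_sarcomere(spec)
    return make_filaments(spec)
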