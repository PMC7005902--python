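"""TIFF/PNG I/O with run metadata, ROI preview, batch processing, throughput.

The headless counterpart of the interactive workflow: estimate noise on a
representative ROI, preview an algorithm on that ROI, then apply it
slice-by-slice to the whole stack. Every output carries a RunRecord (JSON in
the TIFF ImageDescription tag) holding the algorithm spec, the estimates and
an input checksum -- enough to regenerate the output bit-identically.

Float32 is the on-disk format for restored data; PNG export is an explicit,
lossy 8-bit conversion. Slice indices are 0-based in the API.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

from . import denoise_local, denoise_nonlocal, denoise_variational, denoise_wavelet
from .core import AlgorithmSpec, ImageVolume, normalize_to_unit

RUNRECORD_KEY = "emrestore_run"


@dataclass
class RoiSpec:
    """Half-open rectangle [y0, y1) x [x0, x1) on slice ``z``."""

    z: int
    y0: int
    y1: int
    x0: int
    x1: int
    margin: int = 0

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.y0 >= self.y1 or self.x0 >= self.x1:
            raise ValueError("ROI rectangle must be non-empty")

    def validate_against(self, volume: ImageVolume) -> "RoiSpec":
        nz, ny, nx = volume.shape
        if not (0 <= self.z < nz):
            raise ValueError(f"slice {self.z} outside [0, {nz})")
        if self.y0 < 0 or self.x0 < 0 or self.y1 > ny or self.x1 > nx:
            raise ValueError("ROI rectangle outside slice bounds")
        return self


@dataclass
class RunRecord:
    """Provenance of one restoration run, sufficient for a bit-exact re-run."""

    spec: dict
    sigma_hat: Optional[float] = None
    blur_hat: Optional[float] = None
    slice_range: Optional[Tuple[int, int]] = None
    timestamp: str = ""
    input_sha256: str = ""
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        if d["slice_range"] is not None:
            d["slice_range"] = list(d["slice_range"])
        return json.dumps({RUNRECORD_KEY: d}, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunRecord":
        d = json.loads(s)[RUNRECORD_KEY]
        if d.get("slice_range") is not None:
            d["slice_range"] = tuple(d["slice_range"])
        return cls(**d)


@dataclass
class AcquisitionPlan:
    """Inputs of the acquisition-throughput arithmetic."""

    n_images: int
    pixels_per_image: float
    dwell_us: float
    slice_time_s: float = 18.0
    n_slicings: int = 0

    def __post_init__(self):
        for name in ("n_images", "pixels_per_image", "dwell_us", "slice_time_s", "n_slicings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def acquisition_time(plan: AcquisitionPlan) -> float:
    """Total acquisition + slicing time in hours."""
    seconds = (
        plan.n_images * plan.pixels_per_image * plan.dwell_us * 1e-6
        + plan.n_slicings * plan.slice_time_s
    )
    return seconds / 3600.0


# ---------------------------------------------------------------------------
# algorithm dispatch
# ---------------------------------------------------------------------------


def apply_algorithm(plane: np.ndarray, spec: AlgorithmSpec) -> np.ndarray:
    """Run one validated algorithm spec on a single 2-D slice."""
    spec.validate()
    p = spec.params
    a = spec.algorithm
    if a == "gaussian":
        return denoise_local.gaussian_filter(plane, p["sigma_g"])
    if a == "wavelet":
        return denoise_wavelet.wavelet_denoise(
            plane, denoise_wavelet.WaveletParams(T=p["T"], n_scales=int(p["n_scales"]))
        )
    if a == "anisotropic_diffusion":
        return denoise_local.anisotropic_diffusion(
            plane,
            denoise_local.DiffusionParams(
                eta=p["eta"],
                n_iter=int(p["n_iter"]),
                kappa=p["kappa"],
                variant=p.get("variant", "exponential"),
            ),
        )
    if a == "bilateral":
        return denoise_local.bilateral(
            plane,
            denoise_local.BilateralParams(sigma_sp=p["sigma_sp"], sigma_int=p["sigma_int"]),
        )
    if a == "tikhonov":
        return denoise_variational.tikhonov(
            plane,
            denoise_variational.TikhonovParams(
                lam=p["lam"], sigma_psf=p["sigma_psf"], n_iter=int(p["n_iter"])
            ),
        )
    if a == "tv":
        return denoise_variational.tv_denoise(
            plane,
            denoise_variational.TvParams(lam=p["lam"], n_iter=int(p["n_iter"]), eps=p["eps"]),
        )
    if a == "blsgsm":
        return denoise_wavelet.blsgsm_denoise(
            plane,
            denoise_wavelet.GsmParams(
                sigma_n=p["sigma_n"], J=int(p["J"]), K_orient=int(p["K_orient"])
            ),
        )
    if a == "nlm":
        return denoise_nonlocal.nlm_denoise(
            plane, denoise_nonlocal.NlmParams(h=p["h"], B=int(p["B"]), W=int(p["W"]))
        )
    if a == "nlm_deconv":
        return denoise_nonlocal.nlm_deconv(
            plane,
            denoise_nonlocal.NlmDeconvParams(
                h=p["h"],
                B=int(p["B"]),
                W=int(p["W"]),
                lam=p["lam"],
                sigma_psf=p["sigma_psf"],
                n_iter=int(p["n_iter"]),
            ),
        )
    raise ValueError(f"unhandled algorithm {a!r}")


def influence_radius(spec: AlgorithmSpec) -> float:
    """Half-width of the spatial neighborhood one output pixel depends on."""
    p = spec.params
    return {
        "gaussian": denoise_local.GAUSSIAN_WINDOW_RADIUS,
        "bilateral": denoise_local.BILATERAL_WINDOW_RADIUS,
        "nlm": p.get("B", 0) + p.get("W", 0),
        "nlm_deconv": np.inf,  # iterative coupling is global
        "anisotropic_diffusion": p.get("n_iter", 0),
        "wavelet": np.inf,  # full-depth undecimated transform
        "tikhonov": np.inf,
        "tv": np.inf,
        "blsgsm": np.inf,
    }[spec.algorithm]


# ---------------------------------------------------------------------------
# TIFF / PNG I/O
# ---------------------------------------------------------------------------


def read_volume(path) -> Tuple[ImageVolume, Optional[RunRecord]]:
    """Read a grayscale multi-page TIFF; integer data is unit-normalized."""
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].samplesperpixel != 1:
            raise ValueError("only single-channel grayscale TIFF is supported")
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"only grayscale (multi-page) TIFF supported, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        vol = normalize_to_unit(arr, "uint8")
    elif arr.dtype == np.uint16:
        vol = normalize_to_unit(arr, "uint16")
    elif np.issubdtype(arr.dtype, np.floating):
        vol = ImageVolume(np.asarray(arr, dtype=np.float64), source_dtype="float")
    else:
        raise ValueError(f"unsupported TIFF dtype {arr.dtype}")
    record = None
    if RUNRECORD_KEY in desc:
        try:
            record = RunRecord.from_json(desc)
        except (json.JSONDecodeError, KeyError):
            warnings.warn("unparseable run metadata in TIFF description")
    if record is not None:
        vol.metadata["run_record"] = record.to_json()
    return vol, record


def write_volume(volume: ImageVolume, path, record: Optional[RunRecord] = None) -> None:
    """Write float32 pages with the RunRecord JSON in ImageDescription."""
    data = volume.data.astype(np.float32)
    desc = record.to_json() if record is not None else ""
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def export_png(plane: np.ndarray, path, clip: bool = True) -> None:
    """Explicit lossy 8-bit export of one slice."""
    arr = np.asarray(plane, dtype=np.float64)
    if clip:
        arr = np.clip(arr, 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def checksum(volume: ImageVolume) -> str:
    return hashlib.sha256(np.ascontiguousarray(volume.data).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# preview and batch application
# ---------------------------------------------------------------------------


def preview_roi(volume: ImageVolume, roi: RoiSpec, spec: AlgorithmSpec) -> np.ndarray:
    """Denoise the margin-expanded ROI and return the central crop.

    With a margin of at least the algorithm's influence radius the result
    equals the same crop of a full-slice run; a smaller margin triggers a
    warning because pixels near the ROI border may then differ.
    """
    roi.validate_against(volume)
    radius = influence_radius(spec.validate())
    if roi.margin < radius:
        warnings.warn(
            f"preview margin {roi.margin} is below the influence radius "
            f"({radius}) of {spec.algorithm}; border pixels may differ from a "
            "full-slice run",
            RuntimeWarning,
        )
    _, ny, nx = volume.shape
    y0 = max(0, roi.y0 - roi.margin)
    y1 = min(ny, roi.y1 + roi.margin)
    x0 = max(0, roi.x0 - roi.margin)
    x1 = min(nx, roi.x1 + roi.margin)
    patch = volume.data[roi.z, y0:y1, x0:x1]
    restored = apply_algorithm(patch, spec)
    return restored[roi.y0 - y0 : roi.y1 - y0, roi.x0 - x0 : roi.x1 - x0]


def apply_to_stack(
    volume: ImageVolume,
    spec: AlgorithmSpec,
    slice_range: Optional[Tuple[int, int]] = None,
    sigma_hat: Optional[float] = None,
    blur_hat: Optional[float] = None,
) -> Tuple[ImageVolume, RunRecord]:
    """Apply one algorithm independently to each slice in ``slice_range``.

    ``slice_range`` is an inclusive 0-based (first, last) pair; omitted means
    the full stack. Slices outside the range are copied verbatim and the
    input volume is never mutated.
    """
    spec.validate()
    nz = volume.shape[0]
    lo, hi = slice_range if slice_range is not None else (0, nz - 1)
    if not (0 <= lo <= hi < nz):
        raise ValueError(f"slice range [{lo}, {hi}] outside stack of {nz} slices")
    out = volume.data.copy()
    for z in range(lo, hi + 1):
        try:
            out[z] = apply_algorithm(volume.data[z], spec)
        except Exception as e:
            raise RuntimeError(f"restoration failed on slice {z}: {e}") from e
    record = RunRecord(
        spec=spec.to_dict(),
        sigma_hat=sigma_hat,
        blur_hat=blur_hat,
        slice_range=(lo, hi),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        input_sha256=checksum(volume),
    )
    result = ImageVolume.__new__(ImageVolume)
    result.data = out
    result.voxel_size = volume.voxel_size
    result.source_dtype = volume.source_dtype
    result.metadata = dict(volume.metadata)
    result.metadata["run_record"] = record.to_json()
    return result, record


def rerun_from_record(volume: ImageVolume, record: RunRecord) -> ImageVolume:
    """Re-apply the run described by ``record`` to ``volume``.

    Verifies the input checksum so the re-run is guaranteed bit-identical to
    the recorded output.
    """
    if record.input_sha256 and checksum(volume) != record.input_sha256:
        raise ValueError("input checksum does not match the run record")
    spec = AlgorithmSpec.from_dict(record.spec)
    out, _ = apply_to_stack(volume, spec, record.slice_range)
    return out
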