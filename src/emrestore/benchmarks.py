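"""Benchmark image banks and per-algorithm apply functions for calibration.

The plugin's calibration was trained on a bank of noise-free benchmark EM
images; here the bank is a reproducible mix of the three phantom families.
``calibration_apply_fn`` adapts the algorithm dispatch to the calibration
interface (2-D slice + searched-parameter dict), merging in the fixed,
non-searched parameters.
"""

from __future__ import annotations

from typing import Callable, Dict, List

import numpy as np

from .calibrate import DEFAULT_FIXED
from .core import AlgorithmSpec, ImageVolume
from .phantom import PhantomSpec, make_phantom
from .workflow import apply_algorithm

_KINDS = ("membranes", "sarcomere", "filaments")


def make_benchmark(K: int = 10, size: int = 128, seed: int = 0) -> List[ImageVolume]:
    """K clean phantom images of side ``size``, cycling phantom families."""
    bench = []
    for k in range(K):
        spec = PhantomSpec(
            kind=_KINDS[k % len(_KINDS)],
            shape=(size, size),
            seed=seed * 1_000 + k,
            n_cells=max(4, size // 24),
            n_filaments=max(4, size // 16),
            radius=max(3, size // 24),
        )
        bench.append(make_phantom(spec)[0])
    return bench


def calibration_apply_fn(algorithm: str) -> Callable[[np.ndarray, Dict[str, float]], np.ndarray]:
    """Bind an algorithm name to a (plane, searched-params) -> plane callable."""
    fixed = DEFAULT_FIXED.get(algorithm, {})

    def apply_fn(plane: np.ndarray, theta: Dict[str, float]) -> np.ndarray:
        params = {**fixed, **theta}
        return apply_algorithm(plane, AlgorithmSpec(algorithm=algorithm, params=params))

    return apply_fn
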