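"""Artificial image-quality degradation operators and magnitude sweeps.

Three operators emulate progressively worse acquisitions:

* additive Gaussian noise      ``I + W``,        ``W ~ N(0, sigma)``
* additive speckle noise       ``I + W * I``     (point-wise product)
* Gaussian smoothing           ``I (x) K``,      kernel std ``sigma`` voxels

A sweep applies one operator over 11 evenly spaced magnitudes starting at 0
(default grids: sigma in [0, 70] for Gaussian noise, [0, 1] for speckle,
[0, 4] for smoothing). The noise sigmas act on image-intensity units; only
the smoothing sigma is spatial (voxels). Sweeps are bit-reproducible: the
magnitude-0 image is the input unchanged and each magnitude draws an
independent noise field from a seed derived deterministically from the sweep
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import ndimage

__all__ = ["DegradationSpec", "gaussian_noise", "speckle_noise",
           "gaussian_smooth", "degradation_sweep", "DEFAULT_SIGMA_MAX"]

#: default grid endpoints per operator
DEFAULT_SIGMA_MAX = {"gaussian_noise": 70.0, "speckle_noise": 1.0,
                     "gaussian_smooth": 4.0}

_SeedLike = Union[int, list, np.random.Generator]


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation sweep: operator, magnitude grid, RNG seed."""

    kind: str
    sigma_max: float = None  # type: ignore[assignment]
    steps: int = 11
    seed: int = 0
    _grid: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_SIGMA_MAX:
            raise ValueError(f"kind must be one of {sorted(DEFAULT_SIGMA_MAX)}")
        sigma_max = self.sigma_max
        if sigma_max is None:
            sigma_max = DEFAULT_SIGMA_MAX[self.kind]
        if sigma_max < 0:
            raise ValueError("sigma_max must be non-negative")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        object.__setattr__(self, "sigma_max", float(sigma_max))
        object.__setattr__(self, "_grid", np.linspace(0.0, self.sigma_max, self.steps))

    @property
    def sigma_grid(self) -> np.ndarray:
        """Evenly spaced magnitudes, ascending, first element 0."""
        return self._grid.copy()


def _check_sigma(sigma: float) -> float:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(sigma)


def gaussian_noise(image: np.ndarray, sigma: float, seed: _SeedLike = 0) -> np.ndarray:
    """Add a zero-mean Gaussian noise field of standard deviation ``sigma``."""
    sigma = _check_sigma(sigma)
    x = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return x + rng.normal(0.0, sigma, size=x.shape)


def speckle_noise(image: np.ndarray, sigma: float, seed: _SeedLike = 0) -> np.ndarray:
    """Multiplicative speckle: ``I + W * I`` with ``W ~ N(0, sigma)``."""
    sigma = _check_sigma(sigma)
    x = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return x * (1.0 + rng.normal(0.0, sigma, size=x.shape))


def gaussian_smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel of std ``sigma`` voxels.

    Reflective boundaries; kernel truncated at 4 sigma. ``sigma = 0`` returns
    the input unchanged.
    """
    sigma = _check_sigma(sigma)
    x = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return x.copy()
    return ndimage.gaussian_filter(x, sigma, mode="reflect", truncate=4.0)


def degradation_sweep(image: np.ndarray, spec: DegradationSpec) -> list:
    """Ordered series of degraded images, one per grid magnitude.

    The first entry (sigma = 0) is bit-identical to the input; noise fields at
    the remaining magnitudes are independent draws seeded from
    ``(spec.seed, step_index)``.
    """
    series = []
    for i, sigma in enumerate(spec.sigma_grid):
        if spec.kind == "gaussian_noise":
            out = gaussian_noise(image, sigma, seed=[spec.seed, i])
        elif spec.kind == "speckle_noise":
            out = speckle_noise(image, sigma, seed=[spec.seed, i])
        else:
            out = gaussian_smooth(image, sigma)
        series.append(out)
    return series
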