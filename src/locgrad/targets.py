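"""Scalar regional target functions over predicted-class probabilities.

Both targets summarize the softmax probability of the *predicted* class at
each voxel of a region into one differentiable scalar:

* ``kl_target`` — the KL divergence between the per-voxel predicted-class
  probabilities ``p`` and a uniform reference ``q = 1/C``, normalized by the
  region size ``N``:  ``T_R = (1/N) sum_i p_i ln(p_i C)``. Large when the
  region is confidently predicted, zero when every voxel sits exactly at the
  ambiguous 1/C level.
* ``mean_probability`` — the plain mean of ``p`` over the region.

The analytic gradients w.r.t. ``p`` are exposed alongside the values; they
seed the localized backward pass of the gradient-scoring module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyRegionError

__all__ = ["RegionProbabilities", "kl_target", "kl_target_gradient",
           "mean_probability", "mean_probability_gradient", "EPS"]

#: lower clamp applied to probabilities before the logarithm
EPS = 1e-12


@dataclass(frozen=True)
class RegionProbabilities:
    """Predicted-class probabilities for the N voxels of one region."""

    p: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64).ravel()
        if p.size == 0:
            raise EmptyRegionError("region contains no voxels")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)

    @property
    def n_voxels(self) -> int:
        return int(self.p.size)

    @property
    def q_value(self) -> float:
        """Uniform reference probability 1/C."""
        return 1.0 / self.n_classes


def kl_target(rp: RegionProbabilities) -> float:
    """Region-size-normalized KL divergence to the uniform reference.

    ``T_R = (1/N) sum_i p_i ln(p_i / (1/C))`` with natural logarithm and the
    probabilities clamped to ``[EPS, 1]`` before the log.
    """
    p = np.clip(rp.p, EPS, 1.0)
    return float(np.mean(p * np.log(p * rp.n_classes)))


def kl_target_gradient(rp: RegionProbabilities) -> np.ndarray:
    """d T_R / d p_i = (ln(p_i C) + 1) / N, on the clamped probabilities."""
    p = np.clip(rp.p, EPS, 1.0)
    return (np.log(p * rp.n_classes) + 1.0) / rp.n_voxels


def mean_probability(rp: RegionProbabilities) -> float:
    """Mean predicted-class probability over the region: ``(1/N) sum_i p_i``."""
    return float(np.mean(rp.p))


def mean_probability_gradient(rp: RegionProbabilities) -> np.ndarray:
    return np.full(rp.n_voxels, 1.0 / rp.n_voxels)
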