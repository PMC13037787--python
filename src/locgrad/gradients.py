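"""Region-wise gradient scoring: the Local Gradients uncertainty score.

For each predicted region, a scalar regional target (KL-to-uniform or mean
probability) is computed from the model's probabilities inside the region and
backpropagated on its own, so the resulting parameter gradients describe the
sensitivity of *that region alone* to the trained weights. The L1 norm of the
gradients of selected decoder parameter groups is the Local Gradients score
(LG): high gradient response <=> high regional uncertainty.

Scoring is strictly post hoc — model weights and the predicted label map are
left untouched, and gradient buffers are re-zeroed between regions so scores
are independent of whatever else is in the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from . import targets as _t
from .errors import GridMismatchError
from .regions import Region, RegionSet

__all__ = [
    "DifferentiableModel",
    "ProbabilityMap",
    "UncertaintyRecord",
    "list_parameter_groups",
    "local_gradients_score",
    "score_all_regions",
    "block_l1_profile",
    "finite_difference_oracle",
]

_TARGETS = ("kl", "mp")


@runtime_checkable
class DifferentiableModel(Protocol):
    """Contract a segmentation model must satisfy to be scored.

    ``predict_proba`` maps an image to per-voxel class probabilities summing
    to one over the class axis (axis 0) and must be deterministic for fixed
    weights. ``parameter_groups`` exposes named parameter collections
    (decoder blocks, ``Block_<level>-<pair>``). ``gradient_from_probs``
    returns the flattened gradient of a scalar — given as its gradient w.r.t.
    the probabilities — over the named groups, zeroing gradient buffers
    before the backward pass.
    """

    n_classes: int

    def predict_proba(self, image: np.ndarray) -> np.ndarray: ...

    def parameter_groups(self): ...

    def gradient_from_probs(self, image: np.ndarray, dprobs: np.ndarray,
                            group_names: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel class probabilities plus voxel-spacing metadata."""

    probs: np.ndarray  # (C, *spatial)
    spacing: tuple

    @property
    def n_classes(self) -> int:
        return int(self.probs.shape[0])

    def label_map_values(self) -> np.ndarray:
        return np.argmax(self.probs, axis=0)


@dataclass
class UncertaintyRecord:
    """Raw and (optionally) normalized uncertainty values for one region."""

    region_id: int
    label: int
    n_voxels: int
    volume_cm3: float
    T_R: float
    MP: float
    KLD: float
    LG: float
    target_used: str = "kl"
    groups_used: tuple = ()
    U_LG: Optional[float] = None
    U_MP: Optional[float] = None
    U_KLD: Optional[float] = None
    extras: dict = field(default_factory=dict)


def list_parameter_groups(model: DifferentiableModel) -> list:
    """Ordered decoder parameter-group names, bottleneck -> output."""
    names = list(model.parameter_groups().keys())
    if not names:
        raise ValueError("model exposes an empty parameter-group registry")
    if len(set(names)) != len(names):
        raise ValueError("parameter-group names must be unique")
    return names


def _resolve_groups(model, groups) -> list:
    if groups is None and hasattr(model, "default_groups"):
        groups = model.default_groups()
    if not groups:
        raise ValueError("at least one parameter group must be selected")
    registry = set(list_parameter_groups(model))
    unknown = [g for g in groups if g not in registry]
    if unknown:
        raise KeyError(f"unknown parameter groups: {unknown}")
    return list(groups)


def _region_probs(probs: np.ndarray, region: Region) -> np.ndarray:
    spatial = probs.shape[1:]
    idx = region.voxel_indices
    if idx.shape[1] != len(spatial) or np.any(idx.max(axis=0) >= np.asarray(spatial)):
        raise GridMismatchError("region voxels fall outside the model-output grid")
    return probs[(region.label,) + tuple(idx.T)]


def _target_value_and_seed(p: np.ndarray, n_classes: int, target: str):
    rp = _t.RegionProbabilities(p, n_classes)
    if target == "kl":
        return _t.kl_target(rp), _t.kl_target_gradient(rp)
    if target == "mp":
        return _t.mean_probability(rp), _t.mean_probability_gradient(rp)
    raise ValueError(f"target must be one of {_TARGETS}")


def _seed_dprobs(probs: np.ndarray, region: Region, dT_dp: np.ndarray) -> np.ndarray:
    dprobs = np.zeros_like(probs)
    dprobs[(region.label,) + tuple(region.voxel_indices.T)] = dT_dp
    return dprobs


def local_gradients_score(model: DifferentiableModel, image: np.ndarray,
                          region: Region, target: str = "kl",
                          groups: Optional[Sequence[str]] = None) -> float:
    """LG score of one region: L1 norm of the targeted parameter gradients.

    The regional target is computed on the probabilities of the region's
    predicted class from a forward pass on the full image and backpropagated
    by itself; only gradients of the named groups enter the norm.
    """
    groups = _resolve_groups(model, groups)
    probs = model.predict_proba(image)
    p = _region_probs(probs, region)
    _, dT_dp = _target_value_and_seed(p, model.n_classes, target)
    g = model.gradient_from_probs(image, _seed_dprobs(probs, region, dT_dp), groups)
    return float(np.abs(g).sum())


def score_all_regions(model: DifferentiableModel, image: np.ndarray,
                      regions: RegionSet, target: str = "kl",
                      groups: Optional[Sequence[str]] = None) -> list:
    """One :class:`UncertaintyRecord` per region from a single forward pass.

    Raw MP and KLD baselines are filled from the same probabilities; LG uses
    the requested target. Gradient buffers are re-zeroed between regions, so
    each record equals an independent single-region call.
    """
    if len(regions) == 0:
        return []
    groups = _resolve_groups(model, groups)
    probs = model.predict_proba(image)
    records = []
    for region in regions:
        p = _region_probs(probs, region)
        rp = _t.RegionProbabilities(p, model.n_classes)
        kld = _t.kl_target(rp)
        mp = _t.mean_probability(rp)
        T, dT_dp = _target_value_and_seed(p, model.n_classes, target)
        g = model.gradient_from_probs(image, _seed_dprobs(probs, region, dT_dp), groups)
        records.append(UncertaintyRecord(
            region_id=region.region_id, label=region.label,
            n_voxels=region.n_voxels, volume_cm3=region.volume_cm3,
            T_R=T, MP=mp, KLD=kld, LG=float(np.abs(g).sum()),
            target_used=target, groups_used=tuple(groups),
        ))
    return records


def block_l1_profile(model: DifferentiableModel, image: np.ndarray,
                     region: Region, target: str = "kl") -> dict:
    """Per-block L1 gradient norm for one region's backward pass.

    Because the L1 norm is additive over disjoint coordinates, the LG score of
    any block configuration is the sum of its blocks' entries here; block
    sweeps therefore need only one backward pass per region and target.
    """
    all_groups = list_parameter_groups(model)
    probs = model.predict_proba(image)
    p = _region_probs(probs, region)
    _, dT_dp = _target_value_and_seed(p, model.n_classes, target)
    model.gradient_from_probs(image, _seed_dprobs(probs, region, dT_dp), all_groups)
    return {name: float(np.abs(model.group_gradient([name])).sum())
            for name in all_groups}


def finite_difference_oracle(model, image: np.ndarray, region: Region,
                             target: str = "kl",
                             groups: Optional[Sequence[str]] = None,
                             h: float = 1e-6) -> float:
    """Independent check of :func:`local_gradients_score` by central differences.

    Perturbs every parameter of the selected groups in place (restoring it
    exactly), re-running a full forward pass each time. Step size per
    parameter is ``h * max(1, |w|)``. Only viable for small models.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    groups = _resolve_groups(model, groups)

    def value() -> float:
        probs = model.predict_proba(image)
        p = _region_probs(probs, region)
        v, _ = _target_value_and_seed(p, model.n_classes, target)
        return v

    registry = model.parameter_groups()
    total = 0.0
    for name in groups:
        for arr in registry[name].values():
            flat = arr.ravel()
            for j in range(flat.size):
                orig = flat[j]
                step = h * max(1.0, abs(orig))
                flat[j] = orig + step
                f_plus = value()
                flat[j] = orig - step
                f_minus = value()
                flat[j] = orig
                deriv = (f_plus - f_minus) / (2.0 * step)
                if not np.isfinite(deriv):
                    raise ArithmeticError("non-finite target under perturbation")
                total += abs(deriv)
    # invalidate any stale forward cache left by the perturbed passes
    if hasattr(model, "_last_input"):
        model._last_input = None
    return total
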