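"""Localize, filter, match, and truth-label predicted regions from label maps.

A *region* is a connected component of one class of an integer label map.
Regions carry physical volumes (voxel count x voxel volume, in cm^3) so that
the standard small-object post-processing filter — drop predicted components
below a physical volume threshold — can be applied independent of resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyRegionError, FormatError, GridMismatchError, MetadataError

__all__ = [
    "LabelMap",
    "Region",
    "RegionSet",
    "RegionMatch",
    "extract_regions",
    "classify_detections",
    "majority_truth_class",
    "match_regions",
]

#: connectivity name -> scipy structuring-element order
_CONNECTIVITY = {"face": 1, "face-edge-corner": None}  # None -> full ndim


@dataclass(frozen=True)
class LabelMap:
    """Integer label volume (0 = background) with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.issubdtype(values.dtype, np.integer):
            if np.issubdtype(values.dtype, np.floating) and np.all(values == np.round(values)):
                values = values.astype(np.int32)
            else:
                raise FormatError("label map must hold integer labels")
        if values.min() < 0:
            raise FormatError("labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != values.ndim:
            raise MetadataError("spacing must give one edge length per axis")
        if any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise MetadataError("spacing must be strictly positive and finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class Region:
    """One connected component of a label map."""

    region_id: int
    label: int
    voxel_indices: np.ndarray  # (N, ndim), row-major sorted
    volume_cm3: float

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    def mask(self, shape: tuple) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxel_indices.T)] = True
        return m

    def bounding_box(self) -> tuple:
        """Half-open per-axis (start, stop) pairs, 0-based."""
        lo = self.voxel_indices.min(axis=0)
        hi = self.voxel_indices.max(axis=0) + 1
        return tuple((int(a), int(b)) for a, b in zip(lo, hi))


@dataclass
class RegionSet:
    """Regions extracted from one label map, plus the grid they live on."""

    shape: tuple
    spacing: tuple
    regions: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, region_id: int) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    def to_label_map(self) -> LabelMap:
        values = np.zeros(self.shape, dtype=np.int32)
        for r in self.regions:
            values[tuple(r.voxel_indices.T)] = r.label
        return LabelMap(values, self.spacing)

    def to_json(self) -> str:
        payload = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "coordinate_convention": "0-based voxel indices; half-open bounding boxes",
            "regions": [
                {
                    "region_id": r.region_id,
                    "label": int(r.label),
                    "n_voxels": r.n_voxels,
                    "volume_cm3": r.volume_cm3,
                    "bounding_box": [list(b) for b in r.bounding_box()],
                    "voxel_indices": r.voxel_indices.tolist(),
                }
                for r in self.regions
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RegionSet":
        payload = json.loads(text)
        regions = [
            Region(
                region_id=int(r["region_id"]),
                label=int(r["label"]),
                voxel_indices=np.asarray(r["voxel_indices"], dtype=np.intp),
                volume_cm3=float(r["volume_cm3"]),
            )
            for r in payload["regions"]
        ]
        return cls(tuple(payload["shape"]), tuple(payload["spacing"]), regions)


@dataclass(frozen=True)
class RegionMatch:
    """Overlap links from one baseline region into another region set."""

    source_id: int
    target_ids: tuple
    overlap_voxels: dict  # target_id -> shared voxel count

    @property
    def matched(self) -> bool:
        return len(self.target_ids) > 0


def _structure(ndim: int, connectivity: str) -> np.ndarray:
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    order = _CONNECTIVITY[connectivity]
    return ndimage.generate_binary_structure(ndim, ndim if order is None else order)


def extract_regions(label_map: LabelMap, min_volume_cm3: float = 0.0,
                    connectivity: str = "face") -> RegionSet:
    """Connected components of each nonzero class, volume-filtered.

    Components smaller than ``min_volume_cm3`` are dropped. Region ids are
    assigned deterministically in order of each component's first voxel in
    row-major order.
    """
    if min_volume_cm3 < 0:
        raise ValueError("min_volume_cm3 must be non-negative")
    structure = _structure(label_map.values.ndim, connectivity)
    vox_vol = label_map.voxel_volume_cm3
    found = []
    for cls in np.unique(label_map.values):
        if cls == 0:
            continue
        labeled, n = ndimage.label(label_map.values == cls, structure=structure)
        for comp in range(1, n + 1):
            idx = np.argwhere(labeled == comp)  # row-major sorted
            volume = idx.shape[0] * vox_vol
            if volume < min_volume_cm3:
                continue
            first = int(np.ravel_multi_index(idx[0], label_map.shape))
            found.append((first, int(cls), idx, volume))
    found.sort(key=lambda t: (t[0], t[1]))
    regions = [
        Region(region_id=i, label=cls, voxel_indices=idx, volume_cm3=vol)
        for i, (_, cls, idx, vol) in enumerate(found)
    ]
    return RegionSet(label_map.shape, label_map.spacing, regions)


def classify_detections(predicted: RegionSet, truth: LabelMap) -> dict:
    """TP/FP flag per predicted region.

    A region is a false positive iff it shares zero voxels with any nonzero
    truth voxel; a single shared voxel makes it a true positive.

    Returns ``{region_id: True}`` for TP, ``False`` for FP.
    """
    if tuple(predicted.shape) != tuple(truth.shape):
        raise GridMismatchError("predicted regions and truth live on different grids")
    flags = {}
    for r in predicted:
        overlap = truth.values[tuple(r.voxel_indices.T)]
        flags[r.region_id] = bool(np.any(overlap > 0))
    return flags


def majority_truth_class(region: Region, truth: LabelMap) -> Optional[int]:
    """Truth class with the most voxels inside the region.

    Background voxels do not vote when any nonzero class is present; ties
    break toward the smallest class index. Returns ``None`` (unmatched) for a
    region lying entirely on background.
    """
    if region.n_voxels == 0:
        raise EmptyRegionError("region has no voxels")
    if np.any(region.voxel_indices.max(axis=0) >= np.asarray(truth.shape)):
        raise GridMismatchError("region extends beyond the truth grid")
    counts = np.bincount(truth.values[tuple(region.voxel_indices.T)].ravel())
    counts[0] = 0
    if counts.sum() == 0:
        return None
    return int(np.argmax(counts))  # argmax returns the smallest index on ties


def match_regions(baseline: RegionSet, other: RegionSet) -> list:
    """Match every baseline region to all regions of ``other`` it overlaps.

    Greedy full-overlap enumeration: a baseline region is linked to each
    other-set region sharing at least one voxel, so splits (one-to-many) and
    merges (many-to-one) both appear in the match list. Baseline regions with
    no overlap come back with an empty target list (non-persisting).
    """
    if tuple(baseline.shape) != tuple(other.shape):
        raise GridMismatchError("region sets live on different grids")
    id_map = np.full(other.shape, -1, dtype=np.int64)
    for r in other:
        id_map[tuple(r.voxel_indices.T)] = r.region_id
    matches = []
    for r in baseline:
        hit = id_map[tuple(r.voxel_indices.T)]
        hit = hit[hit >= 0]
        ids, counts = np.unique(hit, return_counts=True)
        matches.append(RegionMatch(
            source_id=r.region_id,
            target_ids=tuple(int(i) for i in ids),
            overlap_voxels={int(i): int(c) for i, c in zip(ids, counts)},
        ))
    return matches
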