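"""P95 normalization of raw scores into direction-aligned uncertainty measures.

Raw LG, MP and KLD scores live on arbitrary, model-specific scales. Each is
divided by the 95th percentile of scores from a reference set of regions with
a priori assumed *low* uncertainty (e.g. confident validation predictions, or
true-positive regions). MP and KLD grow with confidence, so their normalized
forms are additionally negated; after normalization all three measures are
small for low-uncertainty regions and large for high-uncertainty ones:

    U_LG  =  LG  / P95{LG_low}
    U_MP  = -MP  / P95{MP_low}
    U_KLD = -KLD / P95{KLD_low}
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateCalibrationError
from .gradients import UncertaintyRecord

__all__ = ["CalibrationReference", "calibrate", "normalize_lg",
           "normalize_reversed", "apply_calibration", "save_references",
           "load_references"]

_MEASURES = ("lg", "mp", "kld")


@dataclass(frozen=True)
class CalibrationReference:
    """Normalization constant for one measure of one trained model."""

    measure: str          # "lg" | "mp" | "kld"
    p95: float            # percentile of the low-uncertainty score set
    percentile: float = 95.0
    source: str = ""      # description of the reference set
    n_scores: int = 0

    def __post_init__(self) -> None:
        if self.measure not in _MEASURES:
            raise ValueError(f"measure must be one of {_MEASURES}")
        if self.p95 <= 0 or not np.isfinite(self.p95):
            raise DegenerateCalibrationError(
                f"normalization constant must be positive, got {self.p95}")
        if self.n_scores < 1:
            raise ValueError("n_scores must be >= 1")


def calibrate(scores: Sequence[float], percentile: float = 95.0,
              measure: str = "lg", source: str = "") -> CalibrationReference:
    """Percentile constant from a set of low-uncertainty reference scores.

    Uses the linear-interpolation percentile convention (interpolates between
    the two nearest order statistics).
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    if scores.size == 0:
        raise ValueError("calibration requires at least one score")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    p95 = float(np.percentile(scores, percentile, method="linear"))
    return CalibrationReference(measure=measure, p95=p95, percentile=percentile,
                                source=source, n_scores=int(scores.size))


def normalize_lg(lg: float, ref: CalibrationReference) -> float:
    """U_LG = LG / P95{LG_low}; larger means more uncertain."""
    if ref.measure != "lg":
        raise ValueError("reference was calibrated for a different measure")
    return float(lg) / ref.p95


def normalize_reversed(score: float, ref: CalibrationReference) -> float:
    """Scale-reversed normalization for confidence-increasing raw measures.

    U = -score / P95, so that — as for U_LG — larger values mean larger
    uncertainty. Applies to MP and KLD.
    """
    if ref.measure not in ("mp", "kld"):
        raise ValueError("reversed normalization applies to mp and kld only")
    return -float(score) / ref.p95


def apply_calibration(records: "list[UncertaintyRecord]",
                      refs: "dict[str, CalibrationReference]") -> "list[UncertaintyRecord]":
    """Fill U_LG / U_MP / U_KLD on records in place; returns the list."""
    for rec in records:
        if "lg" in refs:
            rec.U_LG = normalize_lg(rec.LG, refs["lg"])
        if "mp" in refs:
            rec.U_MP = normalize_reversed(rec.MP, refs["mp"])
        if "kld" in refs:
            rec.U_KLD = normalize_reversed(rec.KLD, refs["kld"])
    return records


def save_references(refs: "dict[str, CalibrationReference]", path) -> None:
    payload = {m: asdict(r) for m, r in refs.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_references(path) -> "dict[str, CalibrationReference]":
    with open(path) as fh:
        payload = json.load(fh)
    return {m: CalibrationReference(**kw) for m, kw in payload.items()}
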