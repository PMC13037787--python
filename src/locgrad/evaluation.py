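"""Assessment computations for region-wise uncertainty measures.

Four families of computations:

* degradation response — track matched regions across a degradation sweep,
  volume-weighting split regions, and report per-magnitude percent
  differences relative to the non-degraded image (restricted to regions that
  persist at every magnitude);
* group comparisons — percent difference between the medians of two groups;
* false-positive filtering — ROC AUC (Mann–Whitney form, ties credited 0.5),
  the false-positive rate at the 95% sensitivity threshold (FPR95), and
  Wilcoxon rank tests, with FP regions as the positive class flagged by high
  uncertainty;
* block-configuration sensitivity — the FP-filtering metric grid over decoder
  block configurations for both regional targets, with and without gradients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .degradations import DegradationSpec, degradation_sweep
from .gradients import DifferentiableModel, block_l1_profile, score_all_regions
from .regions import LabelMap, RegionSet, classify_detections, extract_regions, match_regions

__all__ = [
    "UncertaintyTrack", "FilterMetrics", "build_uncertainty_tracks",
    "percent_diff_track", "percent_diff_groups", "median_percent_diff_curve",
    "roc_auc", "fpr_at_sensitivity", "rank_test", "filter_metrics",
    "default_block_configs", "block_sensitivity_sweep",
    "degradation_response", "fp_filtering",
]


# --------------------------------------------------------------------------- #
# degradation-response tracks                                                 #
# --------------------------------------------------------------------------- #

@dataclass
class UncertaintyTrack:
    """One baseline region's uncertainty across a degradation sweep.

    ``per_magnitude_U`` holds one value per grid magnitude (NaN where the
    region vanished); entry 0 corresponds to the non-degraded image. When a
    region splits, the matched regions' values are volume-weighted.
    """

    source_id: int
    baseline_U: float
    per_magnitude_U: np.ndarray
    persisting: bool


def build_uncertainty_tracks(baseline: RegionSet, baseline_scores: dict,
                             degraded: Sequence) -> list:
    """Construct per-region tracks from matched region sets.

    Parameters
    ----------
    baseline
        Regions predicted on the non-degraded image.
    baseline_scores
        ``{region_id: U}`` for the baseline regions.
    degraded
        One ``(RegionSet, {region_id: U})`` pair per sweep magnitude,
        including the sigma = 0 entry first.
    """
    per_mag_matches = [match_regions(baseline, regs) for regs, _ in degraded]
    tracks = []
    for k, region in enumerate(baseline):
        values = np.full(len(degraded), np.nan)
        for m, ((regs, scores), matches) in enumerate(zip(degraded, per_mag_matches)):
            match = matches[k]
            if not match.matched:
                continue
            vols = np.array([regs[t].volume_cm3 for t in match.target_ids])
            us = np.array([scores[t] for t in match.target_ids])
            values[m] = float(np.average(us, weights=vols))
        tracks.append(UncertaintyTrack(
            source_id=region.region_id,
            baseline_U=baseline_scores[region.region_id],
            per_magnitude_U=values,
            persisting=bool(np.all(np.isfinite(values))),
        ))
    return tracks


def percent_diff_track(track: UncertaintyTrack) -> np.ndarray:
    """Per-magnitude percent difference to the non-degraded value.

    ``100 * (U_sigma - U_0) / U_0`` for each magnitude. Only defined for
    persisting tracks with a nonzero baseline.
    """
    if not track.persisting:
        raise ValueError("percent differences are restricted to persisting tracks")
    if track.baseline_U == 0:
        raise ZeroDivisionError("percent difference undefined for a zero baseline")
    return 100.0 * (track.per_magnitude_U - track.baseline_U) / track.baseline_U


def median_percent_diff_curve(tracks: Sequence[UncertaintyTrack]) -> dict:
    """Median (and IQR) of per-track percent differences at each magnitude.

    Non-persisting tracks are excluded. Returns arrays keyed ``median``,
    ``q25``, ``q75`` plus the number of persisting tracks used.
    """
    diffs = np.array([percent_diff_track(t) for t in tracks
                      if t.persisting and t.baseline_U != 0])
    if diffs.size == 0:
        raise ValueError("no persisting tracks with nonzero baseline")
    return {
        "median": np.median(diffs, axis=0),
        "q25": np.percentile(diffs, 25, axis=0),
        "q75": np.percentile(diffs, 75, axis=0),
        "n_tracks": int(diffs.shape[0]),
    }


def percent_diff_groups(u_a: Sequence[float], u_b: Sequence[float]) -> float:
    """Percent difference between group medians: 100 (med A - med B) / med B."""
    a = np.asarray(list(u_a), dtype=np.float64)
    b = np.asarray(list(u_b), dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_b = np.median(b)
    if med_b == 0:
        raise ZeroDivisionError("percent difference undefined: median of B is zero")
    return float(100.0 * (np.median(a) - med_b) / med_b)


# --------------------------------------------------------------------------- #
# detection metrics                                                           #
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class FilterMetrics:
    """FP-vs-TP separation summary for one uncertainty measure."""

    auc: float
    fpr95: float
    p_value: float
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if not 0.0 <= self.fpr95 <= 1.0:
            raise ValueError("fpr95 must lie in [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


def _split_scores(scores, is_positive):
    s = np.asarray(list(scores), dtype=np.float64)
    flags = np.asarray(list(is_positive), dtype=bool)
    if s.shape != flags.shape:
        raise ValueError("scores and flags must align")
    pos, neg = s[flags], s[~flags]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc(scores: Sequence[float], is_positive: Sequence[bool]) -> float:
    """Probability that a random positive outscores a random negative.

    Mann–Whitney form: ties credited 0.5. Positives are the regions expected
    to score high (for FP filtering: the false positives).
    """
    pos, neg = _split_scores(scores, is_positive)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def fpr_at_sensitivity(scores: Sequence[float], is_positive: Sequence[bool],
                       sensitivity: float = 0.95) -> float:
    """Fraction of negatives at/above the threshold capturing the positives.

    The threshold is the highest score value at which at least ``sensitivity``
    of the positives are flagged (flagging rule: score >= threshold); of the
    thresholds meeting the sensitivity constraint it yields the lowest false
    positive rate.
    """
    pos, neg = _split_scores(scores, is_positive)
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must lie in (0, 1]")
    candidates = np.unique(np.concatenate([pos, neg]))[::-1]  # descending
    for thr in candidates:
        if np.mean(pos >= thr) >= sensitivity:
            return float(np.mean(neg >= thr))
    return 1.0  # unreachable: the lowest candidate flags everything


def rank_test(a: Sequence[float], b: Sequence[float], paired: bool = False) -> float:
    """Two-sided Wilcoxon test p-value (signed-rank if paired, else rank-sum).

    Thin contract over scipy.stats. The degenerate paired case of all-tied
    differences returns the sentinel p = 1.0 (no evidence of a difference).
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must align")
        if np.all(a == b):
            return 1.0
        return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def filter_metrics(scores: Sequence[float], is_fp: Sequence[bool],
                   sensitivity: float = 0.95) -> FilterMetrics:
    """AUC, FPR95 and rank-sum p for separating FP (positive) from TP regions."""
    pos, neg = _split_scores(scores, is_fp)
    return FilterMetrics(
        auc=roc_auc(scores, is_fp),
        fpr95=fpr_at_sensitivity(scores, is_fp, sensitivity),
        p_value=rank_test(pos, neg, paired=False),
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


# --------------------------------------------------------------------------- #
# block-configuration sensitivity sweep                                       #
# --------------------------------------------------------------------------- #

def default_block_configs(group_names: Sequence[str]) -> list:
    """Every block alone plus both blocks of each decoder level together.

    For a 5-level decoder (10 blocks) this yields the 15 configurations of
    the standard sensitivity layout.
    """
    names = list(group_names)
    configs = [[n] for n in names]
    levels: dict = {}
    for n in names:
        levels.setdefault(n.rsplit("-", 1)[0], []).append(n)
    configs.extend([blocks for blocks in levels.values() if len(blocks) > 1])
    return configs


def block_sensitivity_sweep(model: DifferentiableModel, images: Sequence,
                            regions: Sequence[RegionSet],
                            truth: Sequence[LabelMap],
                            group_configs: Optional[Sequence] = None,
                            targets: Sequence[str] = ("mp", "kl"),
                            sensitivity: float = 0.95) -> pd.DataFrame:
    """FP-filtering metric grid over decoder block configurations.

    For each (configuration, target) pair the LG scores are recomputed over
    all predicted regions and summarized by AUC / FPR95 / rank-sum p-value.
    Two no-gradient rows (raw MP and raw KLD, scale-reversed so high means
    uncertain) head the table. One backward pass per region and target serves
    every configuration, because the L1 norm is additive over blocks.
    """
    from .gradients import list_parameter_groups

    all_groups = list_parameter_groups(model)
    if group_configs is None:
        group_configs = default_block_configs(all_groups)
    group_configs = [list(c) for c in group_configs]
    for config in group_configs:
        unknown = [g for g in config if g not in all_groups]
        if unknown:
            raise KeyError(f"unknown parameter groups: {unknown}")

    from . import targets as _t
    from .gradients import _region_probs

    is_fp, mp_raw, kld_raw = [], [], []
    profiles: dict = {t: [] for t in targets}
    for image, regs, gt in zip(images, regions, truth):
        flags = classify_detections(regs, gt)
        probs = model.predict_proba(image)
        for region in regs:
            rp = _t.RegionProbabilities(_region_probs(probs, region),
                                        model.n_classes)
            is_fp.append(not flags[region.region_id])
            mp_raw.append(_t.mean_probability(rp))
            kld_raw.append(_t.kl_target(rp))
            for t in targets:
                profiles[t].append(block_l1_profile(model, image, region, target=t))

    rows = []
    for t, raw in (("mp", mp_raw), ("kl", kld_raw)):
        # the two no-gradient reference rows are always reported
        rev = [-v for v in raw]  # reversed scale: high = uncertain
        m = filter_metrics(rev, is_fp, sensitivity)
        rows.append(dict(target=t, blocks="none", gradient=False,
                         auc=m.auc, fpr95=m.fpr95, p_value=m.p_value))
    for config in group_configs:
        for t in targets:
            lg = [sum(prof[g] for g in config) for prof in profiles[t]]
            m = filter_metrics(lg, is_fp, sensitivity)
            rows.append(dict(target=t, blocks="+".join(config), gradient=True,
                             auc=m.auc, fpr95=m.fpr95, p_value=m.p_value))
    frame = pd.DataFrame(rows)
    frame.attrs["n_fp"] = int(np.sum(is_fp))
    frame.attrs["n_tp"] = int(len(is_fp) - np.sum(is_fp))
    return frame


# --------------------------------------------------------------------------- #
# experiment drivers                                                          #
# --------------------------------------------------------------------------- #

_MEASURE_SIGN = {"lg": 1.0, "mp": -1.0, "kld": -1.0}


def _direction_aligned_scores(records, measure: str) -> dict:
    raw = {"lg": "LG", "mp": "MP", "kld": "KLD"}[measure]
    return {r.region_id: _MEASURE_SIGN[measure] * getattr(r, raw) for r in records}


def degradation_response(model: DifferentiableModel, images: Sequence,
                         spacing: tuple, spec: DegradationSpec,
                         target: str = "kl",
                         groups: Optional[Sequence[str]] = None,
                         min_volume_cm3: float = 0.0,
                         connectivity: str = "face",
                         measures: Sequence[str] = ("lg", "mp", "kld")) -> dict:
    """Track uncertainty measures across a degradation sweep of each image.

    Regions are re-predicted on every degraded image, matched back to the
    non-degraded prediction, and volume-weighted over splits. Scores are
    direction-aligned (MP and KLD negated) but unnormalized — per-magnitude
    percent differences are invariant to the positive normalization constant.

    Returns ``{"sigma_grid": ..., measure: {"tracks": [...],
    "median_percent_diff": {...}}}``.
    """
    tracks: dict = {m: [] for m in measures}
    for image in images:
        series = degradation_sweep(image, spec)
        per_mag = []
        for degraded in series:
            lm = LabelMap(np.argmax(model.predict_proba(degraded), axis=0), spacing)
            regs = extract_regions(lm, min_volume_cm3, connectivity)
            records = score_all_regions(model, degraded, regs, target=target,
                                        groups=groups)
            per_mag.append((regs, records))
        baseline_regs, baseline_recs = per_mag[0]
        for m in measures:
            scored = [(regs, _direction_aligned_scores(recs, m))
                      for regs, recs in per_mag]
            tracks[m].extend(build_uncertainty_tracks(
                baseline_regs, scored[0][1], scored))
    out: dict = {"sigma_grid": spec.sigma_grid}
    for m in measures:
        usable = [t for t in tracks[m] if t.persisting and t.baseline_U != 0]
        out[m] = {"tracks": tracks[m],
                  "median_percent_diff": (median_percent_diff_curve(usable)
                                          if usable else None)}
    return out


def fp_filtering(model: DifferentiableModel, images: Sequence,
                 truth: Sequence[LabelMap], spacing: tuple,
                 target: str = "kl", groups: Optional[Sequence[str]] = None,
                 min_volume_cm3: float = 0.0, connectivity: str = "face",
                 sensitivity: float = 0.95) -> dict:
    """FP-vs-TP separation of U_LG, U_MP and U_KLD over predicted regions.

    Predicts regions on every image, labels them TP/FP against the ground
    truth, and summarizes each measure's separation. Returns the per-region
    table (records + flags) and a ``FilterMetrics`` per measure.
    """
    rows, records_all, flags_all = [], [], []
    for image, gt in zip(images, truth):
        lm = LabelMap(np.argmax(model.predict_proba(image), axis=0), spacing)
        regs = extract_regions(lm, min_volume_cm3, connectivity)
        if len(regs) == 0:
            continue
        flags = classify_detections(regs, gt)
        records = score_all_regions(model, image, regs, target=target, groups=groups)
        for region, rec in zip(regs, records):
            records_all.append(rec)
            flags_all.append(flags[region.region_id])
            rows.append(dict(region_id=rec.region_id, label=rec.label,
                             n_voxels=rec.n_voxels, volume_cm3=rec.volume_cm3,
                             LG=rec.LG, MP=rec.MP, KLD=rec.KLD,
                             is_tp=flags[rec.region_id]))
    table = pd.DataFrame(rows)
    is_fp = [not f for f in flags_all]
    metrics = {}
    for m in ("lg", "mp", "kld"):
        scores = [_MEASURE_SIGN[m] * getattr(r, {"lg": "LG", "mp": "MP",
                                                 "kld": "KLD"}[m])
                  for r in records_all]
        try:
            metrics[m] = filter_metrics(scores, is_fp, sensitivity)
        except ValueError:
            metrics[m] = None  # one class absent on this dataset
    return {"table": table, "metrics": metrics, "records": records_all,
            "is_fp": is_fp}
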