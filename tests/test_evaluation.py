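"""Metric implementations against brute-force oracles; track arithmetic."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from locgrad import (LabelMap, ToyUNet, build_uncertainty_tracks,
                     block_sensitivity_sweep, default_block_configs,
                     extract_regions, fpr_at_sensitivity,
                     median_percent_diff_curve, percent_diff_groups,
                     percent_diff_track, rank_test, roc_auc)
from locgrad.evaluation import UncertaintyTrack


# --------------------------------------------------------------------------- #
# oracles                                                                     #
# --------------------------------------------------------------------------- #

def pairwise_auc_oracle(scores, flags):
    pos = [s for s, f in zip(scores, flags) if f]
    neg = [s for s, f in zip(scores, flags) if not f]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def threshold_scan_fpr_oracle(scores, flags, sensitivity=0.95):
    pos = np.array([s for s, f in zip(scores, flags) if f])
    neg = np.array([s for s, f in zip(scores, flags) if not f])
    best = 1.0
    for t in np.unique(np.concatenate([pos, neg])):
        if np.mean(pos >= t) >= sensitivity:
            best = min(best, float(np.mean(neg >= t)))
    return best


# --------------------------------------------------------------------------- #
# percent differences and tracks                                              #
# --------------------------------------------------------------------------- #

class TestPercentDiffTrack:
    def test_simple_substitution(self):
        track = UncertaintyTrack(0, 1.0, np.array([1.0, 1.0, 1.2]), True)
        assert np.allclose(percent_diff_track(track), [0.0, 0.0, 20.0])

    def test_constant_track_is_identically_zero(self):
        track = UncertaintyTrack(0, 2.5, np.full(11, 2.5), True)
        assert np.all(percent_diff_track(track) == 0.0)

    def test_non_persisting_and_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_diff_track(UncertaintyTrack(0, 1.0, np.array([1.0, np.nan]), False))
        with pytest.raises(ZeroDivisionError):
            percent_diff_track(UncertaintyTrack(0, 0.0, np.zeros(3), True))

    def test_split_regions_volume_weighted(self):
        """A region splitting into volumes 2 and 3 cm^3 with U 1.0 and 2.0
        aggregates to 1.6 -> +60% against a baseline of 1."""
        spacing = (10.0, 10.0, 10.0)  # 1 cm^3 voxels
        base = np.zeros((6, 6, 1), dtype=np.int32)
        base[0, 0:5, 0] = 1
        baseline = extract_regions(LabelMap(base, spacing))
        split = np.zeros((6, 6, 1), dtype=np.int32)
        split[0, 0:2, 0] = 1   # 2 voxels = 2 cm^3
        split[0, 3:6, 0] = 1   # 3 voxels = 3 cm^3
        degraded = extract_regions(LabelMap(split, spacing))
        tracks = build_uncertainty_tracks(
            baseline, {0: 1.0},
            [(baseline, {0: 1.0}), (degraded, {0: 1.0, 1: 2.0})])
        (track,) = tracks
        assert track.persisting
        assert track.per_magnitude_U[1] == pytest.approx(1.6)
        assert percent_diff_track(track)[1] == pytest.approx(60.0)

    def test_vanished_region_marks_track_non_persisting(self):
        spacing = (1.0, 1.0)
        base = np.zeros((4, 4), dtype=np.int32)
        base[0, 0] = 1
        baseline = extract_regions(LabelMap(base, spacing))
        empty = extract_regions(LabelMap(np.zeros((4, 4), dtype=np.int32), spacing))
        (track,) = build_uncertainty_tracks(
            baseline, {0: 1.0}, [(baseline, {0: 1.0}), (empty, {})])
        assert not track.persisting
        assert np.isnan(track.per_magnitude_U[1])

    def test_median_curve_excludes_non_persisting(self):
        t1 = UncertaintyTrack(0, 1.0, np.array([1.0, 1.1]), True)
        t2 = UncertaintyTrack(1, 1.0, np.array([1.0, 1.3]), True)
        t3 = UncertaintyTrack(2, 1.0, np.array([1.0, np.nan]), False)
        curve = median_percent_diff_curve([t1, t2, t3])
        assert curve["n_tracks"] == 2
        assert curve["median"][1] == pytest.approx(20.0)


class TestPercentDiffGroups:
    def test_identical_groups(self):
        assert percent_diff_groups([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == 0.0

    def test_median_ratio(self):
        assert percent_diff_groups([1.5, 1.5], [1.0]) == pytest.approx(50.0)

    def test_matches_sorted_median_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(2.0, 1.0, size=13)
        b = rng.normal(1.0, 0.5, size=8) + 0.5
        med = lambda xs: (sorted(xs)[len(xs) // 2] if len(xs) % 2
                          else sum(sorted(xs)[len(xs) // 2 - 1:len(xs) // 2 + 1]) / 2)
        expected = 100.0 * (med(a) - med(b)) / med(b)
        assert percent_diff_groups(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            percent_diff_groups([1.0], [0.0])


# --------------------------------------------------------------------------- #
# detection metrics                                                           #
# --------------------------------------------------------------------------- #

class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_partial_overlap_case(self):
        assert roc_auc([0.9, 0.4, 0.5, 0.1],
                       [True, True, False, False]) == 0.75

    def test_matches_pairwise_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            flags = rng.uniform(size=n) < 0.4
            if flags.all() or not flags.any():
                continue
            assert roc_auc(scores, flags) == pytest.approx(
                pairwise_auc_oracle(scores, flags), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestFprAtSensitivity:
    def test_perfect_separation_gives_zero(self):
        assert fpr_at_sensitivity([3.0, 2.5, 1.0, 0.5],
                                  [True, True, False, False]) == 0.0

    def test_identical_scores_give_one(self):
        assert fpr_at_sensitivity([1.0] * 8, [True] * 4 + [False] * 4) == 1.0

    def test_matches_threshold_scan_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = 20
            scores = np.round(rng.normal(size=n), 1)
            flags = rng.uniform(size=n) < 0.5
            if flags.all() or not flags.any():
                continue
            assert fpr_at_sensitivity(scores, flags) == pytest.approx(
                threshold_scan_fpr_oracle(scores, flags), abs=1e-12)


@given(st.lists(st.floats(-5, 5), min_size=6, max_size=40),
       st.integers(0, 2 ** 30))
def test_metrics_invariant_under_monotone_transforms(raw, seed):
    rng = np.random.default_rng(seed)
    flags = rng.uniform(size=len(raw)) < 0.5
    if flags.all() or not flags.any():
        return
    # round to a 1e-3 lattice so the transforms stay injective in float64
    scores = np.round(np.asarray(raw), 3)
    for transform in (lambda x: 3.0 * x + 2.0, np.tanh, lambda x: x ** 3):
        assert roc_auc(transform(scores), flags) == pytest.approx(
            roc_auc(scores, flags), abs=1e-12)
        assert fpr_at_sensitivity(transform(scores), flags) == pytest.approx(
            fpr_at_sensitivity(scores, flags), abs=1e-12)


class TestRankTest:
    def test_identical_paired_samples_sentinel(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert rank_test(a, a, paired=True) == 1.0

    def test_strong_shift_detected(self):
        a = np.arange(10.0)
        assert rank_test(a, a + 100.0, paired=True) < 0.01
        assert rank_test(a, a + 100.0, paired=False) < 0.01

    def test_unpaired_matches_exact_permutation_enumeration(self):
        a = [1.2, 3.4, 0.5, 2.2]
        b = [4.1, 5.0, 2.9, 6.2, 3.9]
        pooled = np.array(a + b)
        n_a = len(a)
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2

        def u_stat(idx):
            grp = pooled[list(idx)]
            return sum(ranks[v] for v in grp) - n_a * (n_a + 1) / 2

        us = [u_stat(c) for c in
              itertools.combinations(range(len(pooled)), n_a)]
        us = np.array(us)
        p_le = np.mean(us <= obs)
        p_ge = np.mean(us >= obs)
        expected = min(1.0, 2 * min(p_le, p_ge))
        assert rank_test(a, b, paired=False) == pytest.approx(expected, rel=1e-9)


# --------------------------------------------------------------------------- #
# block-configuration sweep                                                   #
# --------------------------------------------------------------------------- #

def _sweep_inputs(model, n_images=3, size=16, seed=6):
    """Predicted regions on random images; alternate regions marked TP."""
    rng = np.random.default_rng(seed)
    images, regions, truths = [], [], []
    counter = 0
    for _ in range(n_images):
        img = rng.normal(size=(size, size))
        labels = np.argmax(model.predict_proba(img), axis=0)
        regs = extract_regions(LabelMap(labels.astype(np.int32), (1.0, 1.0)))
        if len(regs) == 0:
            continue
        truth = np.zeros((size, size), dtype=np.int32)
        for r in regs:  # every other region overlaps truth -> TP, rest -> FP
            if counter % 2 == 0:
                truth[tuple(r.voxel_indices[0])] = 1
            counter += 1
        images.append(img)
        regions.append(regs)
        truths.append(LabelMap(truth, (1.0, 1.0)))
    assert counter >= 2, "fixture needs at least two predicted regions"
    return images, regions, truths


class TestBlockSweep:
    def test_default_configs_cover_singletons_and_level_pairs(self):
        names = [f"Block_{l}-{p}" for l in range(5) for p in range(2)]
        configs = default_block_configs(names)
        assert len(configs) == 15  # 10 singletons + 5 level pairs
        assert ["Block_4-0", "Block_4-1"] in configs

    def test_grid_layout_single_config(self, small_unet):
        images, regions, truths = _sweep_inputs(small_unet)
        grid = block_sensitivity_sweep(small_unet, images, regions, truths,
                                       group_configs=[["Block_1-1"]],
                                       targets=("kl",))
        assert len(grid) == 3  # 1 gradient row + 2 no-gradient rows
        assert int((~grid.gradient).sum()) == 2

    def test_grid_cells_equal_independent_runs(self, small_unet):
        from locgrad import local_gradients_score, filter_metrics, classify_detections
        images, regions, truths = _sweep_inputs(small_unet)
        grid = block_sensitivity_sweep(small_unet, images, regions, truths,
                                       group_configs=[["Block_0-0"],
                                                      ["Block_1-0", "Block_1-1"]],
                                       targets=("kl", "mp"))
        for config in (["Block_0-0"], ["Block_1-0", "Block_1-1"]):
            for target in ("kl", "mp"):
                scores, flags = [], []
                for img, regs, gt in zip(images, regions, truths):
                    det = classify_detections(regs, gt)
                    for region in regs:
                        scores.append(local_gradients_score(
                            small_unet, img, region, target=target, groups=config))
                        flags.append(not det[region.region_id])
                m = filter_metrics(scores, flags)
                row = grid[(grid.blocks == "+".join(config))
                           & (grid.target == target)].iloc[0]
                assert row.auc == pytest.approx(m.auc, abs=1e-12)
                assert row.fpr95 == pytest.approx(m.fpr95, abs=1e-12)
                assert row.p_value == pytest.approx(m.p_value, rel=1e-9)
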