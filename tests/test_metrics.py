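"""Metric definitions checked against brute-force oracles and algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import directed_hausdorff as scipy_dhd

from hybridseg import (
    ConfusionCounts,
    LabelMask,
    bland_altman,
    confusion,
    dice,
    evaluate_cohort,
    evaluate_pair,
    hausdorff,
    jaccard,
    sensitivity_specificity,
    volumetric_similarity,
)

counts_st = st.tuples(
    st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6)
)


def make_mask(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelMask(np.asarray(arr, dtype=np.int16), spacing)


class TestConfusion:
    def test_identical_masks_have_no_errors(self, sphere):
        m = make_mask(sphere)
        c = confusion(m, m)
        assert (c.fp, c.fn) == (0, 0)
        assert c.tp == int(sphere.sum())

    def test_empty_prediction_counts_all_reference_as_missed(self, sphere):
        empty = make_mask(np.zeros_like(sphere, dtype=np.int16))
        c = confusion(empty, make_mask(sphere))
        assert (c.tp, c.fn) == (0, int(sphere.sum()))

    def test_toy_masks_match_brute_force_voxel_loop(self):
        pred = np.array([[[1, 0, 1], [0, 1, 0], [1, 1, 0]]], dtype=np.int16)
        ref = np.array([[[1, 1, 0], [0, 1, 0], [0, 1, 1]]], dtype=np.int16)
        c = confusion(make_mask(pred), make_mask(ref))
        tp = fp = fn = tn = 0
        for p, r in zip(pred.ravel(), ref.ravel()):
            tp += p and r
            fp += p and not r
            fn += (not p) and r
            tn += (not p) and (not r)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_grid_mismatch_raises(self, sphere):
        with pytest.raises(ValueError, match="shape"):
            confusion(make_mask(sphere), make_mask(sphere[:16]))


class TestOverlapScores:
    def test_perfect_counts_score_one(self):
        c = ConfusionCounts(10, 0, 0, 100)
        assert dice(c) == jaccard(c) == volumetric_similarity(c) == 1.0

    def test_no_overlap_scores_zero(self):
        assert dice(ConfusionCounts(0, 5, 3, 100)) == 0.0
        assert jaccard(ConfusionCounts(0, 5, 3, 100)) == 0.0

    def test_cohort_median_counts_evaluate_exactly(self):
        # frozen from direct evaluation of the printed formulas on
        # TP=174384, FP=19994, FN=13974
        c = ConfusionCounts(174384, 19994, 13974, 10**6)
        assert dice(c) == pytest.approx(0.9112495297, abs=1e-9)
        assert jaccard(c) == pytest.approx(0.8369682076, abs=1e-9)
        assert volumetric_similarity(c) == pytest.approx(0.9842711425, abs=1e-9)

    def test_both_empty_convention(self):
        c = ConfusionCounts(0, 0, 0, 1000)
        assert dice(c) == jaccard(c) == volumetric_similarity(c) == 1.0

    @settings(max_examples=1000, derandomize=True)
    @given(counts_st)
    def test_algebraic_identities_on_random_counts(self, tup):
        c = ConfusionCounts(*tup)
        d, j, v = dice(c), jaccard(c), volumetric_similarity(c)
        assert d == pytest.approx(2 * j / (1 + j), rel=1e-12)
        assert v >= d - 1e-12
        assert j <= d + 1e-12
        for s in (d, j, v):
            assert -1e-12 <= s <= 1 + 1e-12

    def test_dice_is_symmetric_in_pred_and_ref(self, sphere):
        rng = np.random.default_rng(0)
        a = make_mask(rng.random(sphere.shape) < 0.3)
        b = make_mask(sphere)
        assert dice(confusion(a, b)) == dice(confusion(b, a))


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(50, 3, 0, 100), (1.0, 100 / 103)),
            (ConfusionCounts(90, 5, 10, 100), (0.9, 100 / 105)),
            (ConfusionCounts(50, 0, 10, 100), (50 / 60, 1.0)),
        ],
    )
    def test_direct_ratios(self, counts, expected):
        assert sensitivity_specificity(counts) == pytest.approx(expected)

    def test_zero_denominator_flags_undefined(self):
        tpr, tnr = sensitivity_specificity(ConfusionCounts(0, 0, 0, 0))
        assert math.isnan(tpr) and math.isnan(tnr)


def brute_force_hausdorff(x, gt):
    """All-pairs max-min oracle, O(n·m)."""
    d = np.linalg.norm(x[:, None, :] - gt[None, :, :], axis=2)
    return d.min(axis=1).max(), d.min(axis=0).max()


class TestHausdorff:
    def test_identical_sets_give_zero(self, sphere):
        _, _, hd = hausdorff(sphere, sphere.copy())
        assert hd == 0.0

    def test_three_four_five_triangle(self):
        x = np.array([[0.0, 0.0, 0.0]])
        gt = np.array([[3.0, 4.0, 0.0]])
        assert hausdorff(x, gt)[2] == pytest.approx(5.0)

    def test_directed_distances_are_asymmetric(self):
        x = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        gt = np.array([[0.0, 0.0, 0.0]])
        h_xg, h_gx, hd = hausdorff(x, gt)
        assert (h_xg, h_gx, hd) == (10.0, 0.0, 10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        spacing = rng.uniform(0.5, 3.0, size=3)
        x = rng.integers(0, 30, size=(rng.integers(1, 200), 3))
        gt = rng.integers(0, 30, size=(rng.integers(1, 200), 3))
        h_xg, h_gx, hd = hausdorff(x, gt, spacing)
        b_xg, b_gx = brute_force_hausdorff(x * spacing, gt * spacing)
        assert h_xg == pytest.approx(b_xg, abs=1e-12)
        assert h_gx == pytest.approx(b_gx, abs=1e-12)
        assert hd == max(b_xg, b_gx)

    def test_agrees_with_scipy_on_point_sets(self):
        rng = np.random.default_rng(42)
        x = rng.integers(0, 20, size=(50, 3)).astype(float)
        gt = rng.integers(0, 20, size=(60, 3)).astype(float)
        h_xg, h_gx, _ = hausdorff(x, gt)
        assert h_xg == pytest.approx(scipy_dhd(x, gt)[0])
        assert h_gx == pytest.approx(scipy_dhd(gt, x)[0])

    def test_empty_set_raises(self, sphere):
        with pytest.raises(ValueError):
            hausdorff(np.zeros_like(sphere), sphere)

    def test_full_mask_equals_boundary_hd(self, sphere):
        # HD over all voxels equals HD over boundary voxels (oracle identity)
        shifted = np.roll(sphere, 3, axis=0)
        pts_a = np.argwhere(sphere).astype(float)
        pts_b = np.argwhere(shifted).astype(float)
        full = hausdorff(pts_a, pts_b)[2]
        surf = hausdorff(sphere, shifted)[2]
        assert surf == pytest.approx(full)


class TestBlandAltman:
    def test_identical_pairs_give_zero_bias_and_width(self):
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.bias == 0.0
        assert s.loa_low == s.loa_high == 0.0

    def test_hand_computed_example(self):
        s = bland_altman([1, 3, 5], [2, 3, 7])
        assert s.bias == pytest.approx(-1.0)
        assert s.loa_low == pytest.approx(-2.96)
        assert s.loa_high == pytest.approx(0.96)

    def test_constant_shift_moves_bias_not_width(self):
        rng = np.random.default_rng(1)
        a = rng.random(20)
        b = rng.random(20)
        s0 = bland_altman(a, b)
        s1 = bland_altman(a + 5.0, b)
        assert s1.bias == pytest.approx(s0.bias + 5.0)
        assert (s1.loa_high - s1.loa_low) == pytest.approx(s0.loa_high - s0.loa_low)

    def test_fewer_than_two_pairs_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestCohortEvaluation:
    def test_perfect_single_case_summary(self, sphere):
        m = make_mask(sphere)
        per_case, summary = evaluate_cohort([m], [m], [1])
        assert per_case.dice.tolist() == [1.0]
        row = summary.iloc[0]
        assert row.dice_mean == 1.0 and row.dice_sd == 0.0

    def test_union_region_equals_confusion_on_ored_masks(self, clean_aneurysm):
        truth = clean_aneurysm.truth
        pred = LabelMask(np.roll(truth.data, 1, axis=1), truth.spacing)
        per_case, _ = evaluate_cohort([pred], [truth], [1, 2], union_name="whole")
        union_row = per_case[per_case.region == "whole"].iloc[0]
        both = confusion(
            make_mask(pred.data > 0, truth.spacing), make_mask(truth.data > 0, truth.spacing)
        )
        assert union_row.tp == both.tp and union_row.fp == both.fp and union_row.fn == both.fn

    def test_summary_matches_per_case_aggregation(self):
        rng = np.random.default_rng(3)
        preds, refs = [], []
        for _ in range(10):
            base = rng.random((8, 8, 8)) < 0.4
            corrupt = base ^ (rng.random((8, 8, 8)) < 0.05)
            refs.append(make_mask(base))
            preds.append(make_mask(corrupt))
        per_case, summary = evaluate_cohort(preds, refs, [1])
        assert summary.iloc[0].dice_mean == pytest.approx(per_case.dice.mean())
        assert summary.iloc[0].dice_sd == pytest.approx(per_case.dice.std(ddof=1))
        assert summary.iloc[0].dice_median == pytest.approx(per_case.dice.median())

    def test_mismatched_lengths_raise(self, sphere):
        with pytest.raises(ValueError):
            evaluate_cohort([make_mask(sphere)], [], [1])


def test_report_invariants_on_random_pair():
    rng = np.random.default_rng(7)
    a = make_mask(rng.random((10, 10, 10)) < 0.3, (2.0, 1.0, 1.0))
    b = make_mask(rng.random((10, 10, 10)) < 0.3, (2.0, 1.0, 1.0))
    rep = evaluate_pair(a, b)
    assert rep.jaccard <= rep.dice <= rep.vs
    assert rep.hd_mm >= 0
    assert rep.measured_volume_mm3 == (rep.counts.tp + rep.counts.fp) * 2.0
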