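"""Dice / HD95 metrics, atlas-based segmentation, landmark reliability."""

import numpy as np
import pytest
from scipy.stats import norm

from fetatlas.core import DEFAULT_REGISTRY, GestationalAge, LandmarkSet
from fetatlas.evaluation import (
    classify_agreement,
    dice,
    hd95,
    reliability_analysis,
)


class TestDice:
    def test_identical(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlapping_cubes(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[0:2, 0:2, 0:2] = True  # 8 voxels
        b[0:2, 0:2, 1:3] = True  # 8 voxels, 4 shared
        assert dice(a, b) == pytest.approx(2 * 4 / 16)

    def test_both_empty_is_one(self):
        e = np.zeros((3, 3, 3), bool)
        assert dice(e, e) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6, 6)) > 0.5
        b = rng.random((6, 6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_monotone_under_erosion(self):
        from scipy.ndimage import binary_erosion

        m = np.zeros((16, 16, 16), bool)
        m[3:13, 3:13, 3:13] = True
        eroded, scores = m, []
        for _ in range(3):
            eroded = binary_erosion(eroded)
            scores.append(dice(m, eroded))
        assert all(a > b for a, b in zip(scores, scores[1:]))


def brute_force_hd95(a, b, spacing):
    """All-pairs percentile oracle over boundary voxels."""
    from scipy.ndimage import binary_erosion

    pa = np.argwhere(a & ~binary_erosion(a)) * spacing
    pb = np.argwhere(b & ~binary_erosion(b)) * spacing
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


class TestHD95:
    def test_identical_masks_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert hd95(m, m) == 0.0

    def test_translated_single_voxel(self):
        a = np.zeros((12, 6, 6), bool)
        b = np.zeros((12, 6, 6), bool)
        a[2, 3, 3], b[7, 3, 3] = True, True
        assert hd95(a, b, spacing=(1.0, 1.0, 1.0)) == pytest.approx(5.0)

    def test_nested_cubes_match_brute_force(self):
        a = np.zeros((14, 14, 14), bool)
        b = np.zeros((14, 14, 14), bool)
        a[2:12, 2:12, 2:12] = True
        b[4:10, 4:10, 4:10] = True  # gap of 2 voxels
        sp = np.array([1.0, 1.0, 1.0])
        assert hd95(a, b, sp) == pytest.approx(brute_force_hd95(a, b, sp))

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2:7, 2:7, 2:7] = True
        b[4:9, 3:9, 2:6] = True
        assert hd95(a, b) == hd95(b, a)

    def test_spacing_scales_distances(self):
        a = np.zeros((12, 6, 6), bool)
        b = np.zeros((12, 6, 6), bool)
        a[2, 3, 3], b[7, 3, 3] = True, True
        assert hd95(a, b, spacing=(0.8, 0.8, 0.8)) == pytest.approx(4.0)

    def test_empty_mask_rejected(self):
        m = np.zeros((4, 4, 4), bool)
        full = ~m
        with pytest.raises(ValueError):
            hd95(m, full)


class TestClassifyAgreement:
    @pytest.mark.parametrize(
        "pct,category",
        [
            (100.0, "Excellent"), (95.0, "Excellent"), (94.99, "Good"),
            (80.0, "Good"), (79.9, "Satisfactory"), (75.0, "Satisfactory"),
            (74.0, "Poor"), (0.0, "Poor"),
        ],
    )
    def test_thresholds(self, pct, category):
        assert classify_agreement(pct) == category


def _sessions(rng, n_vol, jitter_sd, ids=None, drop=None):
    ids = ids or DEFAULT_REGISTRY.retained_ids
    first, second = [], []
    for v in range(n_vol):
        base = {lid: rng.normal(0, 20, 3) for lid in ids}
        a = LandmarkSet(base)
        b_coords = {
            lid: p + rng.normal(0, jitter_sd, 3) for lid, p in base.items()
        }
        if drop and v in drop.get("volumes", ()):
            for lid in drop["ids"]:
                b_coords.pop(lid, None)
        first.append(a)
        second.append(LandmarkSet(b_coords))
    return first, second


class TestReliability:
    def test_identical_sessions_are_excellent(self):
        rng = np.random.default_rng(2)
        first, _ = _sessions(rng, 5, 0.0)
        report = reliability_analysis(first, [ls.copy() for ls in first], DEFAULT_REGISTRY)
        for lid in DEFAULT_REGISTRY.retained_ids:
            row = report[lid]
            assert row.mean_mm == 0.0
            assert row.agreement_probability_pct == 100.0
            assert row.category == "Excellent"

    def test_gaussian_percentiles(self):
        # distances engineered to have mean 1.0 and sd 0.5
        d = np.array([0.5, 1.5, 0.5, 1.5, 1.0, 1.0, 0.36754446796632, 1.63245553203368])
        d = d - d.mean() + 1.0
        d = (d - 1.0) / d.std(ddof=1) * 0.5 + 1.0
        first, second = [], []
        for dist in d:
            first.append(LandmarkSet({"PTP": [0.0, 0.0, 0.0]}))
            second.append(LandmarkSet({"PTP": [dist, 0.0, 0.0]}))
        report = reliability_analysis(first, second, DEFAULT_REGISTRY)
        row = report["PTP"]
        assert row.mean_mm == pytest.approx(1.0)
        assert row.sd_mm == pytest.approx(0.5)
        assert row.p95_mm == pytest.approx(1.0 + 1.6449 * 0.5, abs=1e-3)
        assert row.p75_mm <= row.p80_mm <= row.p95_mm

    def test_missing_ratio_counts_either_session(self):
        rng = np.random.default_rng(3)
        first, second = _sessions(
            rng, 10, 0.5, drop={"volumes": (0, 4, 7), "ids": ["LFOM"]}
        )
        report = reliability_analysis(first, second, DEFAULT_REGISTRY)
        assert report["LFOM"].missing_ratio_pct == pytest.approx(30.0)
        assert report["LFOM"].n_pairs == 7

    def test_too_few_pairs_flagged(self):
        first = [LandmarkSet({"PTP": [0, 0, 0]}), LandmarkSet({})]
        second = [LandmarkSet({"PTP": [0, 0, 0]}), LandmarkSet({})]
        report = reliability_analysis(first, second, DEFAULT_REGISTRY)
        assert report["PTP"].category is None
        assert report["PTP"].n_pairs == 1

    def test_unpaired_sessions_rejected(self):
        with pytest.raises(ValueError):
            reliability_analysis([LandmarkSet({})], [], DEFAULT_REGISTRY)

    def test_cube_agreement_matches_analytic_probability(self):
        """Empirical 3x3x3-cube agreement under isotropic Gaussian jitter
        matches the product of per-axis probabilities."""
        rng = np.random.default_rng(4)
        n, sd, voxel = 10_000, 0.6, 0.8
        deltas = rng.normal(0, sd, (n, 3))
        first = [LandmarkSet({"PTP": [0, 0, 0]}) for _ in range(n)]
        second = [LandmarkSet({"PTP": deltas[i]}) for i in range(n)]
        report = reliability_analysis(first, second, DEFAULT_REGISTRY, voxel_mm=voxel)
        p_axis = norm.cdf(voxel / sd) - norm.cdf(-voxel / sd)
        analytic = 100.0 * p_axis**3
        assert report["PTP"].empirical_cube_agreement_pct == pytest.approx(
            analytic, abs=2.0
        )


def test_segmentation_label_merge(refined_atlas, pipeline_config):
    """Self-segmentation propagates labels with the corpus callosum merged
    into white matter and no landmark use."""
    from fetatlas.core import Sample, SubjectMeta
    from fetatlas.evaluation import segment_with_atlas

    tp = refined_atlas
    subject = Sample(
        SubjectMeta("self", tp.target_ga, tp.operated),
        tp.image, tp.mask, tp.consensus_landmarks, tp.probmaps,
    )
    parc, scores, chosen = segment_with_atlas(
        subject, [tp], pipeline_config, reference=tp.parcellation
    )
    assert chosen is tp
    assert 8 not in np.unique(parc.data)
    assert scores is not None


def test_time_point_selection_prefers_nearest_then_younger(refined_atlas):
    from dataclasses import replace

    from fetatlas.evaluation import _select_time_point

    tp26 = refined_atlas
    tp28 = replace(refined_atlas, target_ga=GestationalAge.from_weeks_days(28))
    ga = GestationalAge.from_weeks_days(24, 2)
    assert _select_time_point([tp28, tp26], ga.days, False) is tp26
    # exact tie at 27w -> younger wins
    tie = GestationalAge.from_weeks_days(27).days
    assert _select_time_point([tp28, tp26], tie, False) is tp26
    with pytest.raises(ValueError):
        _select_time_point([tp26], ga.days, True)
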