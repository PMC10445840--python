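"""Temporal kernel weights and the group inclusion/exclusion rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetatlas.config import PipelineConfig
from fetatlas.core import DEFAULT_REGISTRY, GestationalAge, LandmarkSet, Sample, SubjectMeta, ga_from_weeks_days
from fetatlas.grouping import augment_group, build_groups, kernel_weight
from fetatlas.phantom import PhantomSpec, make_phantom


def _ga(days):
    return GestationalAge(days)


class TestKernelWeight:
    def test_peak_value(self):
        w = kernel_weight(_ga(182), _ga(182), sigma_days=3)
        assert w == pytest.approx(1.0 / (3.0 * math.sqrt(2 * math.pi)), abs=1e-6)
        assert w == pytest.approx(0.132981, abs=1e-6)

    def test_truncated_beyond_three_sigma(self):
        assert kernel_weight(_ga(192), _ga(182), sigma_days=3) == 0.0  # 10 days
        assert kernel_weight(_ga(191), _ga(182), sigma_days=3) > 0.0  # 9 days

    def test_missing_landmark_zeroes_weight(self):
        assert kernel_weight(_ga(182), _ga(182), 3, landmark_present=False) == 0.0

    @given(st.integers(min_value=0, max_value=15))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_monotonicity(self, delta):
        target = _ga(200)
        w_plus = kernel_weight(_ga(200 + delta), target, 3)
        w_minus = kernel_weight(_ga(200 - delta), target, 3)
        assert w_plus == w_minus
        assert w_plus <= kernel_weight(target, target, 3)
        if delta >= 1:
            assert w_plus <= kernel_weight(_ga(200 + delta - 1), target, 3)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            kernel_weight(_ga(1), _ga(1), sigma_days=0)


def _dummy_sample(days, operated=False, subject_id=None, lmks=True):
    """A metadata-only sample (tiny rasters) for grouping-rule tests."""
    from fetatlas.core import BrainMask, ImageVolume

    aff = np.eye(4)
    data = np.zeros((2, 2, 2))
    mask = np.ones((2, 2, 2), dtype=bool)
    lm = LandmarkSet(
        {lid: [0.0, 0.0, 0.0] for lid in DEFAULT_REGISTRY.retained_ids} if lmks else {}
    )
    sid = subject_id or f"s{days}{'op' if operated else ''}"
    return Sample(
        SubjectMeta(sid, GestationalAge(days), operated),
        ImageVolume(data, aff),
        BrainMask(mask, aff),
        lm,
    )


class TestBuildGroups:
    def test_small_group_dropped(self):
        cohort = [_dummy_sample(180), _dummy_sample(184)]
        cfg = PipelineConfig(week_range=(26, 26))
        assert build_groups(cohort, cfg) == []

    def test_bracketing_rule(self):
        # all members at or below 26 weeks: the 26-week group is rejected
        cohort = [_dummy_sample(d) for d in (175, 178, 182)]
        cfg = PipelineConfig(week_range=(26, 26))
        assert build_groups(cohort, cfg) == []

    def test_window_inclusive_at_nine_days(self):
        cohort = [_dummy_sample(182 - 9), _dummy_sample(182), _dummy_sample(182 + 9)]
        cfg = PipelineConfig(week_range=(26, 26))
        groups = build_groups(cohort, cfg)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_member_beyond_window_excluded(self):
        cohort = [_dummy_sample(172), _dummy_sample(182), _dummy_sample(190)]
        cfg = PipelineConfig(week_range=(26, 26))
        groups = build_groups(cohort, cfg)
        assert groups == []  # only 2 members left inside the window

    def test_statuses_never_mixed(self):
        cohort = [
            _dummy_sample(178), _dummy_sample(182, subject_id="a"), _dummy_sample(186),
            _dummy_sample(178, operated=True), _dummy_sample(182, operated=True, subject_id="b"),
            _dummy_sample(186, operated=True),
        ]
        cfg = PipelineConfig(week_range=(26, 26))
        groups = build_groups(cohort, cfg)
        assert len(groups) == 2
        for g in groups:
            assert all(m.sample.meta.operated == g.operated for m in g.members)

    def test_order_independence(self):
        cohort = [_dummy_sample(d, subject_id=f"s{i}") for i, d in enumerate((175, 180, 182, 185, 189))]
        cfg = PipelineConfig(week_range=(25, 27))
        a = build_groups(cohort, cfg)
        b = build_groups(list(reversed(cohort)), cfg)
        assert [(g.target_ga.days, g.operated, [m.sample.meta.subject_id for m in g.members]) for g in a] == [
            (g.target_ga.days, g.operated, [m.sample.meta.subject_id for m in g.members]) for g in b
        ]

    def test_rules_recheck(self):
        cohort = [_dummy_sample(d, subject_id=f"s{i}") for i, d in enumerate((175, 182, 189))]
        cfg = PipelineConfig(week_range=(26, 26))
        (group,) = build_groups(cohort, cfg)
        assert group.check_rules(cfg.window_days, cfg.min_group_size)


@pytest.fixture(scope="module")
def phantom_group():
    samples = []
    for i, days in enumerate((178, 182, 186)):
        spec = PhantomSpec(
            ga=GestationalAge(days), noise_sd=5.0, seed=i,
            grid_shape=(32, 32, 32), spacing=1.5,
        )
        samples.append(make_phantom(spec, subject_id=f"p{i}"))
    cfg = PipelineConfig(week_range=(26, 26))
    (group,) = build_groups(samples, cfg)
    return group


class TestAugmentGroup:
    def test_cardinality_doubles(self, phantom_group):
        aug = augment_group(phantom_group, DEFAULT_REGISTRY)
        assert len(aug) == 2 * len(phantom_group)
        assert sum(m.augmented for m in aug.members) == len(phantom_group)

    def test_five_members_become_ten(self):
        samples = []
        for i, days in enumerate((175, 178, 182, 186, 189)):
            spec = PhantomSpec(
                ga=GestationalAge(days), noise_sd=0.0, seed=i,
                grid_shape=(32, 32, 32), spacing=1.5,
            )
            samples.append(make_phantom(spec, subject_id=f"q{i}"))
        cfg = PipelineConfig(week_range=(26, 26))
        (group,) = build_groups(samples, cfg)
        assert len(group) == 5
        assert len(augment_group(group, DEFAULT_REGISTRY)) == 10

    def test_weights_preserved(self, phantom_group):
        aug = augment_group(phantom_group, DEFAULT_REGISTRY)
        orig = [m.weight for m in aug.members if not m.augmented]
        flip = [m.weight for m in aug.members if m.augmented]
        assert orig == flip

    def test_flipped_landmarks_match_flip_operator(self, phantom_group):
        from fetatlas.core import flip_landmarks, mid_sagittal_plane_x

        aug = augment_group(phantom_group, DEFAULT_REGISTRY)
        originals = [m for m in aug.members if not m.augmented]
        flipped = [m for m in aug.members if m.augmented]
        for o, f in zip(originals, flipped):
            plane = mid_sagittal_plane_x(o.sample.image)
            expected = flip_landmarks(o.sample.landmarks, DEFAULT_REGISTRY, plane)
            assert f.sample.landmarks == expected

    def test_flipped_image_is_mirror(self, phantom_group):
        aug = augment_group(phantom_group, DEFAULT_REGISTRY)
        o = next(m for m in aug.members if not m.augmented)
        f = next(m for m in aug.members if m.augmented)
        np.testing.assert_array_equal(f.sample.image.data, o.sample.image.data[::-1])
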