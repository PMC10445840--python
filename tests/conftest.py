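"""Shared fixtures: small phantoms and a fully built atlas time point."""

from __future__ import annotations

import numpy as np
import pytest

from fetatlas.config import PipelineConfig
from fetatlas.core import DEFAULT_REGISTRY, GestationalAge, Sample, SubjectMeta
from fetatlas.grouping import augment_group, build_groups
from fetatlas.phantom import PhantomSpec, make_phantom, perturb_phantom
from fetatlas.pipeline import initialize_atlas, refine_atlas


@pytest.fixture(scope="session")
def small_phantom() -> Sample:
    """A 48^3, 1 mm phantom at 26 weeks with realistic noise."""
    spec = PhantomSpec(
        ga=GestationalAge.from_weeks_days(26),
        noise_sd=8.0,
        seed=1,
        grid_shape=(48, 48, 48),
        spacing=1.0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom() -> Sample:
    """An exactly mirror-symmetric phantom (no noise)."""
    spec = PhantomSpec(
        ga=GestationalAge.from_weeks_days(25),
        noise_sd=0.0,
        seed=0,
        grid_shape=(48, 48, 48),
        spacing=1.0,
    )
    return make_phantom(spec)


def _make_group_samples(seed: int = 0):
    """Three phantom subjects bracketing 26 weeks with subject variability."""
    rng = np.random.default_rng(seed)
    samples = []
    for i, days in enumerate([177, 182, 187]):
        ga = GestationalAge(days)
        spec = PhantomSpec(
            ga=ga, noise_sd=8.0, seed=10 + i, grid_shape=(48, 48, 48),
            spacing=1.0, severity=0.5,
        )
        s = make_phantom(spec, subject_id=f"sub-{i}")
        sc = rng.uniform(0.96, 1.04, 3)
        tr = rng.uniform(-1.0, 1.0, 3)
        s2, _ = perturb_phantom(s, scale=sc, translation=tr, seed=100 + i)
        samples.append(
            Sample(SubjectMeta(f"sub-{i}", ga, False), s2.image, s2.mask,
                   s2.landmarks, s2.probmaps)
        )
    return samples


@pytest.fixture(scope="session")
def group_samples():
    return _make_group_samples()


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig(week_range=(26, 26), refinement_iterations=1)


@pytest.fixture(scope="session")
def augmented_group(group_samples, pipeline_config):
    groups = build_groups(group_samples, pipeline_config)
    assert len(groups) == 1
    return augment_group(groups[0], DEFAULT_REGISTRY)


@pytest.fixture(scope="session")
def initialized_atlas(augmented_group, pipeline_config):
    return initialize_atlas(augmented_group, pipeline_config)


@pytest.fixture(scope="session")
def refined_atlas(initialized_atlas, augmented_group, pipeline_config):
    """One refinement pass over the phantom group (registration-based)."""
    return refine_atlas(initialized_atlas, augmented_group, pipeline_config)
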