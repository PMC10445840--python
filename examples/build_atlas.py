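"""Build one spatio-temporal atlas time point from a phantom group.

Generates three phantom subjects bracketing 26 weeks, groups them with
the temporal kernel rules, applies flip augmentation, runs the
landmark-driven Procrustes initialization and one registration-based
refinement pass, and prints the atlas properties.
"""

import numpy as np

from fetatlas import DEFAULT_REGISTRY, GestationalAge, PipelineConfig
from fetatlas.core import Sample, SubjectMeta
from fetatlas.grouping import augment_group, build_groups
from fetatlas.phantom import PhantomSpec, make_phantom, perturb_phantom
from fetatlas.pipeline import initialize_atlas, refine_atlas

rng = np.random.default_rng(0)
samples = []
for i, days in enumerate([177, 182, 187]):
    ga = GestationalAge(days)
    spec = PhantomSpec(ga=ga, noise_sd=8.0, seed=10 + i, grid_shape=(48, 48, 48), spacing=1.0)
    s = make_phantom(spec, subject_id=f"sub-{i}")
    s2, _ = perturb_phantom(
        s, scale=rng.uniform(0.96, 1.04, 3), translation=rng.uniform(-1, 1, 3), seed=100 + i
    )
    samples.append(Sample(SubjectMeta(f"sub-{i}", ga, False), s2.image, s2.mask, s2.landmarks, s2.probmaps))

config = PipelineConfig(week_range=(26, 26), refinement_iterations=1)
(group,) = build_groups(samples, config)
print(f"group at {group.target_ga}: {len(group)} members, "
      f"weights {[round(m.weight, 4) for m in group.members]}")
group = augment_group(group, DEFAULT_REGISTRY)
print(f"after right-left flip augmentation: {len(group)} members")

atlas = initialize_atlas(group, config)
print(f"initialized atlas grid {atlas.image.shape}, "
      f"mirror-symmetric: {np.array_equal(atlas.image.data, atlas.image.data[::-1])}")
atlas = refine_atlas(atlas, group, config)

inside = atlas.image.data[atlas.mask.data]
print(f"refined atlas: in-mask intensity mean {inside.mean():.0f}, sd {inside.std():.0f}")
print(f"parcellation labels present: {sorted(np.unique(atlas.parcellation.data).tolist())}")
print(f"brain volume: {atlas.mask.volume_mm3 / 1000:.1f} cm^3")
print(
    "\nThe atlas is the time-weighted, exactly mirror-symmetric average of the\n"
    "Procrustes-aligned and then non-linearly registered members; labels 1-8\n"
    "are the eight tissue classes, 0 is background."
)
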