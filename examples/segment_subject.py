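"""Segment a new subject by atlas propagation and score it.

Builds a single-group phantom atlas, generates an unseen subject at a
nearby gestational age, registers the atlas to it without landmarks
(as in prospective use), propagates the parcellation, and prints
per-tissue Dice and HD95 against the subject's ground-truth labels.
"""

import numpy as np

from fetatlas import DEFAULT_REGISTRY, GestationalAge, PipelineConfig
from fetatlas.averaging import argmax_parcellation
from fetatlas.core import ImageVolume, Sample, SubjectMeta
from fetatlas.evaluation import segment_with_atlas
from fetatlas.grouping import augment_group, build_groups
from fetatlas.phantom import PhantomSpec, make_phantom, perturb_phantom
from fetatlas.pipeline import initialize_atlas

samples = []
for i, days in enumerate([177, 182, 187]):
    spec = PhantomSpec(ga=GestationalAge(days), noise_sd=8.0, seed=20 + i,
                       grid_shape=(48, 48, 48), spacing=1.0)
    samples.append(make_phantom(spec, subject_id=f"sub-{i}"))

config = PipelineConfig(week_range=(26, 26), refinement_iterations=0)
(group,) = build_groups(samples, config)
atlas_tp = initialize_atlas(augment_group(group, DEFAULT_REGISTRY), config)
print(f"atlas time point: {atlas_tp.name}")

# an unseen subject at 26w+2d with its own anatomy
spec = PhantomSpec(ga=GestationalAge.from_weeks_days(26, 2), noise_sd=8.0, seed=99,
                   grid_shape=(48, 48, 48), spacing=1.0, severity=0.6)
subject = make_phantom(spec, subject_id="new-subject")
subject, _ = perturb_phantom(subject, scale=(1.03, 0.98, 1.0), translation=(1, -1, 0))
truth_labels = ImageVolume(
    subject.probmaps.data.argmax(0).astype(np.int16), subject.image.affine
)

parcellation, scores, chosen = segment_with_atlas(
    subject, [atlas_tp], config, reference=truth_labels
)
print(f"selected time point: {chosen.name} (nearest week, matching status)")
print(scores.to_frame().round(3).to_string(index=False))
print(
    "\nDice is the volume overlap (1 = perfect); HD95 the 95th-percentile\n"
    "surface distance in mm. The corpus callosum is merged into white matter\n"
    "before scoring, leaving seven tissue classes plus the whole brain."
)
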