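"""Age/status groups and truncated temporal Gaussian kernel weights.

Each atlas time point is computed from a group of sessions that share an
operation status and lie within a fixed window (default 9 days = 3 sigma)
of a whole-week target gestational age.  Within a group, sessions are
weighted by a truncated Gaussian kernel in the age difference, so the
window and the kernel truncation coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Sequence

from .core import GestationalAge, LandmarkRegistry, Sample, flip_image, flip_landmarks, mid_sagittal_plane_x

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig

__all__ = ["kernel_weight", "GroupMember", "Group", "build_groups", "augment_group"]


def kernel_weight(
    ga: GestationalAge,
    target: GestationalAge,
    sigma_days: float = 3.0,
    landmark_present: bool = True,
) -> float:
    """Truncated Gaussian kernel weight for a session at ``ga`` toward ``target``.

    Returns 0 when the landmark is missing or when ``|GA - GA_target|``
    exceeds 3 sigma; otherwise the Gaussian density
    ``exp(-0.5 (dGA/sigma)^2) / (sqrt(2 pi) sigma)``.
    """
    if sigma_days <= 0:
        raise ValueError("sigma_days must be positive")
    if not landmark_present:
        return 0.0
    dga = abs(ga.days - target.days)
    if dga > 3.0 * sigma_days:
        return 0.0
    return math.exp(-0.5 * (dga / sigma_days) ** 2) / (math.sqrt(2.0 * math.pi) * sigma_days)


@dataclass
class GroupMember:
    sample: Sample
    weight: float
    augmented: bool = False  # True for a flip-augmented copy


@dataclass
class Group:
    """Sessions contributing to one (week, operation status) atlas time point."""

    target_ga: GestationalAge
    operated: bool
    members: List[GroupMember] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_original(self) -> int:
        return sum(1 for m in self.members if not m.augmented)

    def check_rules(self, window_days: int, min_size: int) -> bool:
        """Re-check the inclusion, size and bracketing rules for this group."""
        originals = [m for m in self.members if not m.augmented]
        if len(originals) < min_size:
            return False
        gas = [m.sample.meta.ga.days for m in originals]
        t = self.target_ga.days
        if any(abs(g - t) > window_days for g in gas):
            return False
        if not (any(g > t for g in gas) and any(g < t for g in gas)):
            return False
        if any(m.sample.meta.operated != self.operated for m in self.members):
            return False
        return all(m.weight > 0 for m in self.members)


def build_groups(samples: Sequence[Sample], config: "PipelineConfig") -> List[Group]:
    """Construct retained (week, status) groups from a cohort of samples.

    Candidate groups are formed at each whole week of ``config.week_range``
    for both operation statuses.  A session joins a candidate when its age
    lies within ``window_days`` (inclusive) of the target.  A candidate is
    retained only if it has at least ``min_group_size`` members before
    augmentation and contains members strictly above and strictly below
    the target age; a member exactly at the target counts as neither.
    """
    if not samples:
        raise ValueError("empty cohort")
    groups: List[Group] = []
    lo, hi = config.week_range
    for week in range(lo, hi + 1):
        target = GestationalAge.from_weeks_days(week)
        for operated in (False, True):
            members = []
            for s in sorted(
                (s for s in samples if s.meta.operated == operated),
                key=lambda s: (s.meta.subject_id, s.meta.session_id),
            ):
                dga = abs(s.meta.ga.days - target.days)
                if dga <= config.window_days:
                    w = kernel_weight(s.meta.ga, target, config.sigma_days)
                    if w > 0:
                        members.append(GroupMember(s, w))
            g = Group(target, operated, members)
            gas = [m.sample.meta.ga.days for m in members]
            if len(members) < config.min_group_size:
                continue
            if not (any(x > target.days for x in gas) and any(x < target.days for x in gas)):
                continue
            groups.append(g)
    return groups


def _flip_sample(sample: Sample, registry: LandmarkRegistry) -> Sample:
    plane_x = mid_sagittal_plane_x(sample.image)
    probmaps = sample.probmaps.flipped() if sample.probmaps is not None else None
    return Sample(
        meta=sample.meta,
        image=flip_image(sample.image),
        mask=flip_image(sample.mask),
        landmarks=flip_landmarks(sample.landmarks, registry, plane_x),
        probmaps=probmaps,
    )


def augment_group(group: Group, registry: LandmarkRegistry) -> Group:
    """Right-left flip augmentation: duplicate every member as its mirror.

    Flipped copies keep their temporal weight and are flagged
    ``augmented=True``; the originals come first.
    """
    flipped = [
        GroupMember(_flip_sample(m.sample, registry), m.weight, augmented=True)
        for m in group.members
        if not m.augmented
    ]
    return Group(group.target_ga, group.operated, list(group.members) + flipped)
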