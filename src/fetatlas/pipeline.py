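"""Per-group atlas construction: Procrustes initialization, time-weighted
symmetric averaging, and iterative registration-based refinement."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .averaging import (
    ProbabilityMaps,
    argmax_parcellation,
    normalize_intensity,
    weighted_symmetric_average,
    weighted_symmetric_average_probmaps,
)
from .config import PipelineConfig
from .core import (
    DEFAULT_REGISTRY,
    BrainMask,
    GestationalAge,
    ImageVolume,
    LandmarkRegistry,
    LandmarkSet,
    Sample,
)
from .grouping import Group, augment_group, build_groups, kernel_weight
from .procrustes import landmark_array, solve_wgp
from .registration import apply_transform, register_ffd
from .resample import resample_to_consensus

logger = logging.getLogger(__name__)

__all__ = ["AtlasTimePoint", "initialize_atlas", "refine_atlas", "build_spatiotemporal_atlas"]


@dataclass
class AtlasTimePoint:
    """The atlas volume for one (gestational week, operation status) group."""

    target_ga: GestationalAge
    operated: bool
    image: ImageVolume
    mask: BrainMask
    probmaps: ProbabilityMaps
    parcellation: ImageVolume
    consensus_landmarks: LandmarkSet
    provenance: Dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        status = "operated" if self.operated else "notoperated"
        return f"week{self.target_ga.weeks:02d}_{status}"


def _landmark_weight_matrix(group: Group, ids: Sequence[str], sigma_days: float) -> np.ndarray:
    """Temporal x missingness weight matrix for the Procrustes stage."""
    n, K = len(group.members), len(ids)
    W = np.zeros((n, K))
    for i, m in enumerate(group.members):
        for k, lid in enumerate(ids):
            W[i, k] = kernel_weight(
                m.sample.meta.ga,
                group.target_ga,
                sigma_days,
                landmark_present=lid in m.sample.landmarks,
            )
    return W


def _consensus_grid(
    aligned_corners: np.ndarray, spacing: np.ndarray, midline_x: float, pad_voxels: int = 5
) -> Tuple[Tuple[int, int, int], np.ndarray]:
    """Voxelize the consensus frame on a padded bounding box.

    The x range is symmetrized about the consensus midline so that the
    grid's central sagittal plane coincides with it; the averaged atlas is
    then exactly mirror-symmetric on its own grid.
    """
    lo = aligned_corners.min(axis=0) - pad_voxels * spacing
    hi = aligned_corners.max(axis=0) + pad_voxels * spacing
    half_x = max(midline_x - lo[0], hi[0] - midline_x)
    lo[0], hi[0] = midline_x - half_x, midline_x + half_x
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = lo
    # re-centre x so the grid mid-plane is exactly the midline
    affine[0, 3] = midline_x - spacing[0] * (shape[0] - 1) / 2.0
    return tuple(int(n) for n in shape), affine


def _mask_corners(sample: Sample) -> np.ndarray:
    idx = np.argwhere(sample.mask.data)
    if idx.size == 0:
        raise ValueError(f"empty mask for {sample.meta.subject_id}")
    lo, hi = idx.min(axis=0).astype(float), idx.max(axis=0).astype(float)
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    return sample.mask.voxel_to_physical(corners)


def _procrustes_align(
    group: Group, config: PipelineConfig, registry: LandmarkRegistry
):
    """Solve the weighted Procrustes problem and pull members onto its frame."""
    ids = registry.retained_ids
    W = _landmark_weight_matrix(group, ids, config.sigma_days)
    if np.any(W.sum(axis=0) <= 0):
        missing = [ids[k] for k in np.nonzero(W.sum(axis=0) <= 0)[0]]
        raise ValueError(
            f"landmarks never annotated in group {group.target_ga}: {missing}"
        )
    X = landmark_array([m.sample.landmarks for m in group.members], ids)
    result = solve_wgp(X, W, landmark_ids=ids)

    corners = np.concatenate(
        [
            result.transforms[i].apply(_mask_corners(m.sample))
            for i, m in enumerate(group.members)
        ]
    )
    midline_x = float(result.consensus[:, 0].mean())
    spacing = group.members[0].sample.image.spacing
    shape, affine = _consensus_grid(corners, spacing, midline_x)

    aligned: List[Sample] = []
    for i, m in enumerate(group.members):
        s = resample_to_consensus(m.sample, result.transforms[i], shape, affine)
        img = normalize_intensity(s.image, s.mask, config.target_mean, config.target_sd)
        aligned.append(Sample(s.meta, img, s.mask, s.landmarks, s.probmaps))
    weights = [m.weight for m in group.members]
    return aligned, weights, result, shape, affine, midline_x


def _symmetrized_consensus(
    consensus: LandmarkSet, registry: LandmarkRegistry, plane_x: float
) -> LandmarkSet:
    """Average each consensus landmark with its mirrored partner."""
    out = LandmarkSet()
    for lid, p in consensus.coords.items():
        partner = registry.partner(lid)
        q = consensus.get(partner)
        if q is None:
            out[lid] = p
            continue
        mirrored = q.copy()
        mirrored[0] = 2.0 * plane_x - mirrored[0]
        out[lid] = 0.5 * (p + mirrored)
    return out


def _average_members(
    members: Sequence[Sample], weights: Sequence[float], affine: np.ndarray
) -> Tuple[ImageVolume, BrainMask, ProbabilityMaps]:
    image = weighted_symmetric_average([m.image for m in members], weights)
    mask_f = weighted_symmetric_average(
        [ImageVolume(m.mask.data.astype(float), m.mask.affine) for m in members], weights
    )
    mask = BrainMask(mask_f.data > 0.5, affine.copy())
    probmaps = weighted_symmetric_average_probmaps(
        [m.probmaps for m in members], weights
    )
    return image, mask, probmaps


def initialize_atlas(
    group: Group,
    config: Optional[PipelineConfig] = None,
    registry: LandmarkRegistry = DEFAULT_REGISTRY,
) -> AtlasTimePoint:
    """Landmark-only initialization of one atlas time point.

    Builds the temporal/missingness landmark weight matrix, solves the
    weighted generalized Procrustes problem, resamples all members onto
    the consensus frame, normalizes intensities and computes weighted
    symmetric averages of images, masks and probability maps.  Image
    intensity plays no role in the alignment.
    """
    config = config or PipelineConfig()
    if any(m.sample.probmaps is None for m in group.members):
        raise ValueError("all group members need probability maps")
    aligned, weights, wgp, shape, affine, midline_x = _procrustes_align(
        group, config, registry
    )
    image, mask, probmaps = _average_members(aligned, weights, affine)
    consensus = _symmetrized_consensus(
        wgp.consensus_landmarks(), registry, midline_x
    )
    parcellation = argmax_parcellation(probmaps)
    logger.info(
        "initialized %s: %d members, Procrustes objective %.4g (%d iters)",
        group.target_ga, len(group.members), wgp.objective, wgp.iterations,
    )
    return AtlasTimePoint(
        target_ga=group.target_ga,
        operated=group.operated,
        image=image,
        mask=mask,
        probmaps=probmaps,
        parcellation=parcellation,
        consensus_landmarks=consensus,
        provenance={
            "members": [
                (m.sample.meta.subject_id, m.sample.meta.session_id, m.weight, m.augmented)
                for m in group.members
            ],
            "procrustes_objective": wgp.objective,
            "procrustes_iterations": wgp.iterations,
            "refinement_iterations": 0,
        },
    )


def refine_atlas(
    atlas: AtlasTimePoint,
    group: Group,
    config: Optional[PipelineConfig] = None,
    registry: LandmarkRegistry = DEFAULT_REGISTRY,
) -> AtlasTimePoint:
    """Registration-based sharpening of an initialized atlas time point.

    Each (Procrustes-aligned) member is registered non-linearly to the
    current atlas with the landmark-regularized objective, the warped
    members are re-averaged, and the procedure repeats
    ``config.refinement_iterations`` times.  Consensus landmarks are kept
    fixed at the Procrustes solution.
    """
    config = config or PipelineConfig()
    aligned, weights, wgp, shape, affine, midline_x = _procrustes_align(
        group, config, registry
    )
    current = atlas
    for it in range(config.refinement_iterations):
        warped_members: List[Sample] = []
        for member in aligned:
            try:
                transform = register_ffd(
                    current, member, weights=config.reg, use_landmarks=True,
                    seed=config.seed,
                )
            except Exception as exc:  # identify the failing member
                raise RuntimeError(
                    f"registration failed for {member.meta.subject_id}/"
                    f"{member.meta.session_id} in group {group.target_ga}: {exc}"
                ) from exc
            img = apply_transform(transform, member.image, "linear")
            msk = apply_transform(transform, member.mask, "linear")
            pm = apply_transform(transform, member.probmaps, "linear")
            warped_members.append(Sample(member.meta, img, BrainMask(msk.data, msk.affine), member.landmarks, pm))
        image, mask, probmaps = _average_members(
            warped_members, weights, current.image.affine
        )
        current = AtlasTimePoint(
            target_ga=atlas.target_ga,
            operated=atlas.operated,
            image=image,
            mask=mask,
            probmaps=probmaps,
            parcellation=argmax_parcellation(probmaps),
            consensus_landmarks=atlas.consensus_landmarks,
            provenance={**atlas.provenance, "refinement_iterations": it + 1},
        )
    return current


def build_spatiotemporal_atlas(
    samples: Sequence[Sample],
    config: Optional[PipelineConfig] = None,
    registry: LandmarkRegistry = DEFAULT_REGISTRY,
) -> List[AtlasTimePoint]:
    """Full pipeline: grouping, per-group initialization, refinement, parcellation.

    Groups are processed independently; a failure in one group is logged
    and the others continue.  An empty retained set is an error.
    """
    config = config or PipelineConfig()
    groups = build_groups(samples, config)
    if not groups:
        raise ValueError("no retained group: cohort too sparse for the grouping rules")
    atlas: List[AtlasTimePoint] = []
    errors: List[str] = []
    for group in groups:
        try:
            aug = augment_group(group, registry)
            tp = initialize_atlas(aug, config, registry)
            if config.refinement_iterations > 0:
                tp = refine_atlas(tp, aug, config, registry)
            atlas.append(tp)
        except Exception as exc:
            msg = f"group {group.target_ga} operated={group.operated}: {exc}"
            errors.append(msg)
            logger.error("skipping %s", msg)
    if not atlas:
        raise ValueError("all groups failed: " + "; ".join(errors))
    return atlas
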