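"""Atlas-based segmentation scoring and landmark reliability statistics.

Segmentation quality is measured with the Dice overlap and the 95th
percentile Hausdorff surface distance.  Intra-rater landmark reliability
follows a Gaussian model of repeat-annotation distances: percentiles are
``mean + z_q * sd`` and the probability that a repeat placement falls
within an agreement radius classifies each landmark as Excellent
(>= 95%), Good (>= 80%), Satisfactory (>= 75%) or Poor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from scipy.stats import norm

from .averaging import TISSUE_LABELS
from .config import PipelineConfig
from .core import ImageVolume, LandmarkRegistry, LandmarkSet, Sample
from .pipeline import AtlasTimePoint
from .registration import apply_transform, register_ffd

__all__ = [
    "dice",
    "hd95",
    "SegmentationScores",
    "segment_with_atlas",
    "LandmarkReliability",
    "ReliabilityReport",
    "reliability_analysis",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks score 1."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def _boundary_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    boundary = mask & ~binary_erosion(mask)
    return np.argwhere(boundary) * spacing


def hd95(a: np.ndarray, b: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """95th-percentile symmetric Hausdorff distance between mask surfaces, mm."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("hd95 requires two nonempty masks")
    spacing = np.asarray(spacing, dtype=float)
    pa = _boundary_points(a, spacing)
    pb = _boundary_points(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


@dataclass
class SegmentationScores:
    """Per-structure Dice (fraction) and HD95 (mm) of a propagated parcellation."""

    per_structure: Dict[str, Tuple[float, Optional[float]]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"structure": k, "dice": v[0], "hd95_mm": v[1]}
                for k, v in self.per_structure.items()
            ]
        )

    def dice_of(self, structure: str) -> float:
        return self.per_structure[structure][0]


def _select_time_point(
    atlas: Sequence[AtlasTimePoint], ga_days: int, operated: bool
) -> AtlasTimePoint:
    candidates = [tp for tp in atlas if tp.operated == operated]
    if not candidates:
        raise ValueError(f"no atlas time point with operated={operated}")
    return min(candidates, key=lambda tp: (abs(tp.target_ga.days - ga_days), tp.target_ga.days))


def segment_with_atlas(
    subject: Sample,
    atlas: Sequence[AtlasTimePoint],
    config: Optional[PipelineConfig] = None,
    reference: Optional[ImageVolume] = None,
) -> Tuple[ImageVolume, Optional[SegmentationScores], AtlasTimePoint]:
    """Segment a subject by registering and propagating an atlas parcellation.

    The time point with matching operation status and nearest target age
    is chosen (ties go to the younger); registration uses image intensity
    only (no landmarks); labels propagate by nearest neighbour; the
    corpus-callosum label is merged into white matter, leaving seven
    evaluated tissue classes plus the whole brain.
    """
    config = config or PipelineConfig()
    tp = _select_time_point(atlas, subject.meta.ga.days, subject.meta.operated)
    transform = register_ffd(
        subject, tp, weights=config.reg, use_landmarks=False, seed=config.seed
    )
    propagated = apply_transform(transform, tp.parcellation, "nearest")
    labels = propagated.data.copy()
    labels[labels == 8] = 1  # corpus callosum merged into white matter
    parcellation = ImageVolume(labels, propagated.affine)
    scores = None
    if reference is not None:
        ref = reference.data.copy()
        ref[ref == 8] = 1
        spacing = subject.image.spacing
        per: Dict[str, Tuple[float, Optional[float]]] = {}
        whole_a, whole_b = labels > 0, ref > 0
        per["brain"] = (
            dice(whole_a, whole_b),
            hd95(whole_a, whole_b, spacing) if whole_a.sum() and whole_b.sum() else None,
        )
        for lab in range(1, 8):
            a, b = labels == lab, ref == lab
            h = hd95(a, b, spacing) if a.sum() and b.sum() else None
            per[TISSUE_LABELS[lab]] = (dice(a, b), h)
        scores = SegmentationScores(per)
    return parcellation, scores, tp


@dataclass
class LandmarkReliability:
    landmark_id: str
    n_pairs: int
    missing_ratio_pct: float
    mean_mm: Optional[float]
    sd_mm: Optional[float]
    p75_mm: Optional[float]
    p80_mm: Optional[float]
    p95_mm: Optional[float]
    agreement_probability_pct: Optional[float]
    empirical_cube_agreement_pct: Optional[float]
    category: Optional[str]


@dataclass
class ReliabilityReport:
    rows: List[LandmarkReliability]
    agreement_radius_mm: float

    def __getitem__(self, landmark_id: str) -> LandmarkReliability:
        for r in self.rows:
            if r.landmark_id == landmark_id:
                return r
        raise KeyError(landmark_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def classify_agreement(agreement_probability_pct: float) -> str:
    """Map an agreement probability (%) to a reliability category."""
    if agreement_probability_pct >= 95.0:
        return "Excellent"
    if agreement_probability_pct >= 80.0:
        return "Good"
    if agreement_probability_pct >= 75.0:
        return "Satisfactory"
    return "Poor"


def reliability_analysis(
    first: Sequence[LandmarkSet],
    second: Sequence[LandmarkSet],
    registry: LandmarkRegistry,
    voxel_mm: float = 0.8,
    agreement_radius_mm: Optional[float] = None,
    min_pairs: int = 2,
) -> ReliabilityReport:
    """Intra-rater reliability of repeated landmark annotations.

    ``first`` and ``second`` are paired rating sessions over the same
    volumes.  The default agreement radius is ``sqrt(3) * voxel_mm``, the
    circumscribed sphere of the 3x3x3-voxel agreement cube; the Gaussian
    distance model and the cube predicate are both reported.
    """
    if len(first) != len(second):
        raise ValueError("rating sessions must be paired")
    n_vol = len(first)
    if n_vol == 0:
        raise ValueError("no rated volumes")
    radius = agreement_radius_mm if agreement_radius_mm is not None else math.sqrt(3.0) * voxel_mm
    rows: List[LandmarkReliability] = []
    for lid in registry.ids:
        dists, cube_hits = [], []
        n_missing = 0
        for a, b in zip(first, second):
            pa, pb = a.get(lid), b.get(lid)
            if pa is None or pb is None:
                n_missing += 1
                continue
            diff = np.abs(pa - pb)
            dists.append(float(np.linalg.norm(pa - pb)))
            cube_hits.append(bool(np.all(diff <= voxel_mm + 1e-9)))
        missing_pct = 100.0 * n_missing / n_vol
        if len(dists) < min_pairs:
            rows.append(
                LandmarkReliability(lid, len(dists), missing_pct, None, None, None,
                                    None, None, None, None, None)
            )
            continue
        d = np.asarray(dists)
        mean = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd > 0:
            pcts = {q: mean + float(norm.ppf(q / 100.0)) * sd for q in (75, 80, 95)}
            agree = 100.0 * float(norm.cdf((radius - mean) / sd))
        else:
            pcts = {q: mean for q in (75, 80, 95)}
            agree = 100.0 if mean <= radius else 0.0
        rows.append(
            LandmarkReliability(
                landmark_id=lid,
                n_pairs=len(dists),
                missing_ratio_pct=missing_pct,
                mean_mm=mean,
                sd_mm=sd,
                p75_mm=pcts[75],
                p80_mm=pcts[80],
                p95_mm=pcts[95],
                agreement_probability_pct=agree,
                empirical_cube_agreement_pct=100.0 * float(np.mean(cube_hits)),
                category=classify_agreement(agree),
            )
        )
    return ReliabilityReport(rows, radius)
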