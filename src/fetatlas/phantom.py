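"""Growth-consistent 3D brain phantoms with analytically known landmarks.

The phantom is a nested-ellipsoid model of a fetal brain with enlarged
lateral ventricles: a white-matter interior wrapped in a cortical
grey-matter rim and an extra-axial CSF rim, containing two ventricle
lobes, a deep-grey-matter core, a corpus-callosum bridge, a posterior
cerebellum and a brainstem cylinder — the eight tissue classes of the
atlas parcellation.  The base shape is exactly mirror-symmetric about the
grid's central sagittal plane, the whole brain scales linearly with
gestational age, and the retained anatomical landmarks sit at closed-form
loci (ventricle anterior tips, posterior tectum pole, cerebellar-brainstem
junctions, deep-grey lateral borders), so every pipeline stage can be
tested against exact ground truth.

It emulates geometry and contrast only — no acquisition physics, motion,
or anatomical detail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .averaging import N_TISSUES, ProbabilityMaps
from .core import (
    BrainMask,
    GestationalAge,
    ImageVolume,
    LandmarkSet,
    Sample,
    SubjectMeta,
)
from .procrustes import ScalingTransform
from .resample import resample_probmaps, resample_volume, sample_at_physical

__all__ = ["PhantomSpec", "PerturbationTruth", "make_phantom", "perturb_phantom", "make_cohort"]

# Base geometry at growth scale 1 (mm offsets from the grid centre;
# x: left->right, y: posterior->anterior, z: inferior->superior).
_BRAIN_HALF = np.array([11.0, 14.0, 10.0])
_CSF_FRAC = 0.90  # inner boundary of the extra-axial CSF rim
_CORTEX_FRAC = 0.80  # inner boundary of the cortical rim
_VENT_CENTRE = np.array([3.5, 1.0, 2.0])  # right lobe; left is mirrored
_VENT_HALF = np.array([2.0, 4.5, 2.2])
_DGM_CENTRE = np.array([0.0, 0.5, -2.5])
_DGM_HALF = np.array([4.5, 3.5, 2.0])
_CC_CENTRE = np.array([0.0, 1.0, 4.5])
_CC_HALF = np.array([1.2, 4.0, 0.8])
_CB_CENTRE = np.array([0.0, -7.0, -4.0])
_CB_HALF = np.array([5.0, 2.5, 2.0])
_BS_Y, _BS_R, _BS_Z = -3.5, 2.0, (-8.0, 1.0)  # brainstem cylinder

_TISSUE_MEANS = {0: 10.0, 1: 400.0, 2: 650.0, 3: 300.0, 4: 680.0, 5: 250.0, 6: 280.0, 7: 330.0, 8: 430.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic recipe for one phantom brain."""

    ga: GestationalAge
    operated: bool = False
    severity: float = 0.5  # ventricle enlargement factor in [0, 1]
    noise_sd: float = 10.0
    bias_amplitude: float = 0.0  # low-order multiplicative bias field
    seed: int = 0
    grid_shape: Tuple[int, int, int] = (64, 72, 64)
    spacing: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")


def growth_scale(ga: GestationalAge) -> float:
    """Linear brain growth factor: 1.0 at 21 weeks to 1.8 at 34 weeks."""
    return 1.0 + 0.8 * (ga.days / 7.0 - 21.0) / 13.0


def _grid_affine(shape: Tuple[int, int, int], spacing: float) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    # centre the physical origin on the grid centre so the phantom is
    # grid-centred and exactly mirror-symmetric about the mid-sagittal plane
    aff[:3, 3] = -spacing * (np.array(shape) - 1) / 2.0
    return aff


def _ellipsoid(pts: np.ndarray, centre: np.ndarray, half: np.ndarray) -> np.ndarray:
    return (((pts - centre) / half) ** 2).sum(axis=-1) <= 1.0


def _vent_half(severity: float) -> np.ndarray:
    return _VENT_HALF * (1.0 + 0.8 * severity)


def phantom_labels(spec: PhantomSpec) -> np.ndarray:
    """Analytic tissue label map (0 background, 1..8 tissues)."""
    s = growth_scale(spec.ga)
    shape, spacing = spec.grid_shape, spec.spacing
    half_extent = spacing * (np.array(shape) - 1) / 2.0
    if np.any(s * _BRAIN_HALF + 1.0 > half_extent):
        raise ValueError(
            f"grid {shape} at {spacing} mm too small for the brain at {spec.ga}"
        )
    aff = _grid_affine(shape, spacing)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    pts = idx * spacing + aff[:3, 3]  # physical, centred at 0

    r2 = (((pts / (s * _BRAIN_HALF)) ** 2)).sum(axis=-1)
    labels = np.zeros(shape, dtype=np.int16)
    labels[r2 <= 1.0] = 4  # extra-axial CSF rim
    labels[r2 <= _CSF_FRAC**2] = 5  # cortical grey matter rim
    interior = r2 <= _CORTEX_FRAC**2
    labels[interior] = 1  # white matter

    def carve(region: np.ndarray, label: int) -> None:
        labels[region & interior] = label

    bs = (pts[..., 0] ** 2 + (pts[..., 1] - s * _BS_Y) ** 2 <= (s * _BS_R) ** 2) & (
        (pts[..., 2] >= s * _BS_Z[0]) & (pts[..., 2] <= s * _BS_Z[1])
    )
    carve(bs, 7)
    carve(_ellipsoid(pts, s * _CB_CENTRE, s * _CB_HALF), 3)
    carve(_ellipsoid(pts, s * _DGM_CENTRE, s * _DGM_HALF), 6)
    carve(_ellipsoid(pts, s * _CC_CENTRE, s * _CC_HALF), 8)
    vh = s * _vent_half(spec.severity)
    right = _ellipsoid(pts, s * _VENT_CENTRE, vh)
    left = _ellipsoid(pts, s * _VENT_CENTRE * np.array([-1, 1, 1]), vh)
    carve(right | left, 2)
    return labels


def phantom_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Closed-form loci of the seven retained landmarks, in physical mm."""
    s = growth_scale(spec.ga)
    vh = _vent_half(spec.severity)
    tip_r = _VENT_CENTRE + np.array([0.0, vh[1], 0.0])  # anterior ventricle tip
    loci = {
        "RALV": tip_r,
        "LALV": tip_r * np.array([-1, 1, 1]),
        "PTP": np.array([0.0, _BS_Y - _BS_R, 0.0]),  # posterior tectum pole
        "RCB": np.array([_BS_R, -5.0, -4.0]),
        "LCB": np.array([-_BS_R, -5.0, -4.0]),
        "RFOM": _DGM_CENTRE + np.array([_DGM_HALF[0], 0.0, 0.0]),
        "LFOM": _DGM_CENTRE - np.array([_DGM_HALF[0], 0.0, 0.0]),
    }
    return LandmarkSet({k: s * v for k, v in loci.items()})


def make_phantom(spec: PhantomSpec, subject_id: Optional[str] = None) -> Sample:
    """Build a phantom sample: image, mask, one-hot probability maps, landmarks."""
    labels = phantom_labels(spec)
    aff = _grid_affine(spec.grid_shape, spec.spacing)
    rng = np.random.default_rng(spec.seed)
    image = np.vectorize(_TISSUE_MEANS.get, otypes=[float])(labels)
    if spec.bias_amplitude > 0:
        pts = np.stack(
            np.meshgrid(*[np.linspace(-1, 1, n) for n in spec.grid_shape], indexing="ij"),
            axis=-1,
        )
        coeffs = rng.uniform(-1, 1, size=3)
        bias = 1.0 + spec.bias_amplitude * (pts * coeffs).sum(axis=-1)
        image = image * bias
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    meta = SubjectMeta(
        subject_id=subject_id or f"phantom-{spec.seed}",
        ga=spec.ga,
        operated=spec.operated,
        session_id="ses-01",
    )
    return Sample(
        meta=meta,
        image=ImageVolume(image, aff),
        mask=BrainMask(labels > 0, aff),
        landmarks=phantom_landmarks(spec),
        probmaps=ProbabilityMaps.from_labels(labels, aff, n_classes=N_TISSUES + 1),
    )


@dataclass
class PerturbationTruth:
    """The exact forward transform applied by :func:`perturb_phantom`.

    Forward map: ``phi(x) = A(x) + D(x)`` with ``A`` a scaling transform
    and ``D`` a smooth displacement field sampled on the original grid
    (zero when no warp was requested).
    """

    scaling: ScalingTransform
    warp_field: Optional[np.ndarray]  # (nx, ny, nz, 3) mm, or None
    grid_affine: np.ndarray

    def _warp_at(self, pts: np.ndarray) -> np.ndarray:
        if self.warp_field is None:
            return np.zeros_like(pts)
        vol = lambda c: ImageVolume(self.warp_field[..., c], self.grid_affine)
        return np.stack(
            [sample_at_physical(vol(c), pts, order=1) for c in range(3)], axis=-1
        )

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return self.scaling.apply(pts) + self._warp_at(pts)

    def invert(self, pts: np.ndarray, iters: int = 30, tol: float = 1e-10) -> np.ndarray:
        """Fixed-point inversion of the forward map (small warps only)."""
        pts = np.asarray(pts, dtype=float)
        inv = self.scaling.inverse()
        x = inv.apply(pts)
        for _ in range(iters):
            x_new = inv.apply(pts - self._warp_at(x))
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        return x


def perturb_phantom(
    sample: Sample,
    scale: Sequence[float] = (1.0, 1.0, 1.0),
    translation: Sequence[float] = (0.0, 0.0, 0.0),
    smooth_warp_amplitude: float = 0.0,
    drop_landmarks: Iterable[str] = (),
    seed: int = 0,
) -> Tuple[Sample, PerturbationTruth]:
    """Apply a known scaling + translation + smooth warp to a sample.

    Scaling is about the grid's physical centre.  The image, mask,
    probability maps and landmarks are transformed consistently and the
    exact forward transform is returned.  The warp amplitude must be
    small enough to keep the deformation invertible.
    """
    img = sample.image
    shape = img.data.shape
    centre = img.voxel_to_physical((np.array(shape, dtype=float) - 1) / 2.0)
    s = np.asarray(scale, dtype=float)
    t = np.asarray(translation, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scale components must be positive")
    # A(x) = diag(s) (x - c) + c + t  ==  diag(s) x + (c + t - diag(s) c)
    scaling = ScalingTransform(s, centre + t - s * centre)

    warp = None
    if smooth_warp_amplitude > 0:
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=shape + (3,))
        smooth = np.stack(
            [gaussian_filter(raw[..., c], sigma=6.0) for c in range(3)], axis=-1
        )
        mags = np.linalg.norm(smooth, axis=-1)
        warp = smooth * (smooth_warp_amplitude / max(mags.max(), 1e-12))
        spacing = img.spacing
        max_grad = max(
            np.max(np.abs(np.gradient(warp[..., c], spacing[a], axis=a)))
            for c in range(3)
            for a in range(3)
        )
        if max_grad >= 0.5:
            raise ValueError("requested warp is too large to stay invertible")

    truth = PerturbationTruth(scaling, warp, img.affine.copy())

    # invert the forward map once on the shared grid; every raster reuses it
    from .resample import grid_physical_points

    grid_pts = grid_physical_points(shape, img.affine).reshape(-1, 3)
    inv_pts = truth.invert(grid_pts)

    def phys_map(pts: np.ndarray) -> np.ndarray:
        return inv_pts
    image = resample_volume(img, shape, img.affine, phys_map)
    mask = resample_volume(sample.mask, shape, img.affine, phys_map)
    probmaps = (
        resample_probmaps(sample.probmaps, shape, img.affine, phys_map)
        if sample.probmaps is not None
        else None
    )
    dropped = set(drop_landmarks)
    unknown = dropped - set(sample.landmarks.present_ids)
    landmarks = LandmarkSet(
        {
            k: truth.apply(v)
            for k, v in sample.landmarks.coords.items()
            if k not in dropped
        }
    )
    if unknown:
        raise KeyError(f"cannot drop absent landmarks: {sorted(unknown)}")
    out = Sample(sample.meta, image, BrainMask(mask.data, mask.affine), landmarks, probmaps)
    return out, truth


def make_cohort(
    n_subjects: int,
    ga_range: Tuple[int, int] = (22, 30),
    operated_split: float = 0.5,
    longitudinal: bool = False,
    seed: int = 0,
    grid_shape: Tuple[int, int, int] = (64, 72, 64),
    spacing: float = 0.8,
    noise_sd: float = 10.0,
) -> Tuple[pd.DataFrame, List[Sample]]:
    """Generate a reproducible phantom cohort with per-subject trajectories.

    Operated subjects carry a surgery age of about 25 weeks and are only
    imaged after it; severity is a persistent per-subject trait.  With
    ``longitudinal=True`` subjects receive up to three sessions at
    strictly increasing gestational ages.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    lo, hi = ga_range
    if lo > hi:
        raise ValueError("empty ga_range")
    rng = np.random.default_rng(seed)
    rows, samples = [], []
    for si in range(n_subjects):
        subject_id = f"sub-{si:03d}"
        operated = bool(rng.random() < operated_split)
        severity = float(rng.uniform(0.2, 0.8))
        surgery_days = int(rng.integers(24 * 7, 26 * 7)) if operated else 0
        ga_lo = max(lo * 7, surgery_days + 1) if operated else lo * 7
        ga_hi = hi * 7 + 6
        if ga_lo > ga_hi:
            ga_lo = ga_hi - 7
        n_sessions = int(rng.integers(2, 4)) if longitudinal else 1
        days = np.sort(rng.choice(np.arange(ga_lo, ga_hi + 1), size=n_sessions, replace=False))
        for ses_i, d in enumerate(days, start=1):
            ga = GestationalAge(int(d))
            spec = PhantomSpec(
                ga=ga,
                operated=operated,
                severity=severity,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                grid_shape=grid_shape,
                spacing=spacing,
            )
            sample = make_phantom(spec, subject_id=subject_id)
            # per-session anatomical variation: small anisotropic scale and shift
            sc = rng.uniform(0.95, 1.05, size=3)
            tr = rng.uniform(-1.5, 1.5, size=3)
            sample, _ = perturb_phantom(
                sample, scale=sc, translation=tr, seed=int(rng.integers(0, 2**31 - 1))
            )
            meta = SubjectMeta(subject_id, ga, operated, f"ses-{ses_i:02d}")
            sample = Sample(meta, sample.image, sample.mask, sample.landmarks, sample.probmaps)
            rows.append(
                {
                    "subject_id": subject_id,
                    "session_id": meta.session_id,
                    "ga_weeks": ga.weeks,
                    "ga_days": ga.extra_days,
                    "operated": operated,
                    "severity": severity,
                }
            )
            samples.append(sample)
    return pd.DataFrame(rows), samples
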