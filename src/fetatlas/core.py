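"""Core domain types for spatio-temporal fetal brain atlas construction.

The package works in physical RAS millimetre coordinates throughout: the
first axis of every raster is the left-to-right axis, so the "central
sagittal plane" of a volume is the physical mid-plane of the grid along
axis 0.  Gestational age is stored as an integer number of days and is
presented as weeks + days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

__all__ = [
    "GestationalAge",
    "ga_from_weeks_days",
    "SubjectMeta",
    "ImageVolume",
    "BrainMask",
    "RegistryEntry",
    "LandmarkRegistry",
    "DEFAULT_REGISTRY",
    "LandmarkSet",
    "Sample",
    "flip_image",
    "flip_landmarks",
    "mid_sagittal_plane_x",
]

MAX_GA_DAYS = 320


@dataclass(frozen=True, order=True)
class GestationalAge:
    """Gestational age stored as a total number of days."""

    days: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.days) <= MAX_GA_DAYS):
            raise ValueError(f"gestational age out of range: {self.days} days")
        object.__setattr__(self, "days", int(self.days))

    @property
    def weeks(self) -> int:
        return self.days // 7

    @property
    def extra_days(self) -> int:
        return self.days % 7

    @classmethod
    def from_weeks_days(cls, weeks: int, extra_days: int = 0) -> "GestationalAge":
        if weeks < 0:
            raise ValueError("weeks must be non-negative")
        if not (0 <= extra_days <= 6):
            raise ValueError("extra_days must be in 0..6")
        return cls(7 * weeks + extra_days)

    def __str__(self) -> str:
        return f"{self.weeks}w+{self.extra_days}d"


def ga_from_weeks_days(weeks: int, extra_days: int = 0) -> GestationalAge:
    """Build a :class:`GestationalAge` from a weeks + days presentation."""
    return GestationalAge.from_weeks_days(weeks, extra_days)


@dataclass(frozen=True)
class SubjectMeta:
    """Identity and clinical status of one imaging session."""

    subject_id: str
    ga: GestationalAge
    operated: bool
    session_id: str = "ses-01"


@dataclass
class ImageVolume:
    """A 3D scalar grid with a voxel-index -> physical-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self):
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def physical_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine[:3, :3])
        return (pts - self.affine[:3, 3]) @ inv.T

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.affine.copy())

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


class BrainMask(ImageVolume):
    """A binary grid sharing an :class:`ImageVolume`'s grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data) > 0

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))


@dataclass(frozen=True)
class RegistryEntry:
    landmark_id: str
    name: str
    laterality: str  # "left" | "right" | "midline"
    mirror_partner_id: str
    retained: bool
    label: int  # NIfTI label value in the label-map dialect


class LandmarkRegistry:
    """The fixed protocol registry of anatomical landmarks.

    Eleven landmarks are defined; the four involving the cavum septi
    pellucidi proved unreliable and are kept in the registry with
    ``retained=False`` so that reliability analyses can still refer to
    them.
    """

    def __init__(self, entries: Iterable[RegistryEntry]):
        self.entries: List[RegistryEntry] = list(entries)
        self._by_id = {e.landmark_id: e for e in self.entries}
        self._by_label = {e.label: e for e in self.entries}
        self._validate()

    def _validate(self) -> None:
        if len(self._by_id) != len(self.entries):
            raise ValueError("duplicate landmark ids in registry")
        for e in self.entries:
            p = self._by_id.get(e.mirror_partner_id)
            if p is None:
                raise ValueError(f"{e.landmark_id}: unknown mirror partner")
            if e.laterality == "midline":
                if p is not e:
                    raise ValueError(f"{e.landmark_id}: midline must self-pair")
            elif e.laterality == "left":
                if p.laterality != "right":
                    raise ValueError(f"{e.landmark_id}: partner must be right")
            elif e.laterality == "right":
                if p.laterality != "left":
                    raise ValueError(f"{e.landmark_id}: partner must be left")
            else:
                raise ValueError(f"bad laterality {e.laterality!r}")
            if p.mirror_partner_id != e.landmark_id:
                raise ValueError(f"{e.landmark_id}: pairing not symmetric")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, landmark_id: str) -> bool:
        return landmark_id in self._by_id

    def __getitem__(self, landmark_id: str) -> RegistryEntry:
        return self._by_id[landmark_id]

    @property
    def ids(self) -> List[str]:
        return [e.landmark_id for e in self.entries]

    @property
    def retained_ids(self) -> List[str]:
        return [e.landmark_id for e in self.entries if e.retained]

    def by_label(self, label: int) -> RegistryEntry:
        return self._by_label[label]

    def partner(self, landmark_id: str) -> str:
        return self._by_id[landmark_id].mirror_partner_id

    def to_table(self):
        """Dump the registry as a pandas DataFrame (TSV-ready)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "landmark_id": e.landmark_id,
                    "name": e.name,
                    "laterality": e.laterality,
                    "mirror_partner_id": e.mirror_partner_id,
                    "retained": e.retained,
                    "label": e.label,
                }
                for e in self.entries
            ]
        )


def _default_registry() -> LandmarkRegistry:
    spec = [
        # id, name, laterality, partner, retained
        ("RALV", "anterior horn of the right lateral ventricle", "right", "LALV", True),
        ("LALV", "anterior horn of the left lateral ventricle", "left", "RALV", True),
        ("PTP", "posterior tectum plate", "midline", "PTP", True),
        ("LCB", "left cerebellar-brainstem junction", "left", "RCB", True),
        ("RCB", "right cerebellar-brainstem junction", "right", "LCB", True),
        ("LFOM", "left deep grey border at foramen of Monro", "left", "RFOM", True),
        ("RFOM", "right deep grey border at foramen of Monro", "right", "LFOM", True),
        ("LACSP", "left deep grey border at anterior CSP line", "left", "RACSP", False),
        ("RACSP", "right deep grey border at anterior CSP line", "right", "LACSP", False),
        ("LPCSP", "left deep grey border at posterior CSP line", "left", "RPCSP", False),
        ("RPCSP", "right deep grey border at posterior CSP line", "right", "LPCSP", False),
    ]
    return LandmarkRegistry(
        RegistryEntry(lid, name, lat, partner, retained, label)
        for label, (lid, name, lat, partner, retained) in enumerate(spec, start=1)
    )


DEFAULT_REGISTRY = _default_registry()


class LandmarkSet:
    """Named 3D physical points with explicit missingness.

    A landmark absent from :attr:`coords` is missing.  Coordinates are
    physical mm 3-vectors.
    """

    def __init__(self, coords: Optional[Mapping[str, np.ndarray]] = None):
        self.coords: Dict[str, np.ndarray] = {}
        if coords:
            for k, v in coords.items():
                self[k] = v

    def __setitem__(self, landmark_id: str, point: np.ndarray) -> None:
        point = np.asarray(point, dtype=float).reshape(3)
        self.coords[landmark_id] = point

    def __getitem__(self, landmark_id: str) -> np.ndarray:
        return self.coords[landmark_id]

    def __contains__(self, landmark_id: str) -> bool:
        return landmark_id in self.coords

    def __len__(self) -> int:
        return len(self.coords)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        if set(self.coords) != set(other.coords):
            return False
        return all(np.allclose(self.coords[k], other.coords[k]) for k in self.coords)

    @property
    def present_ids(self) -> List[str]:
        return list(self.coords)

    def get(self, landmark_id: str) -> Optional[np.ndarray]:
        return self.coords.get(landmark_id)

    def subset(self, ids: Iterable[str]) -> "LandmarkSet":
        return LandmarkSet({k: v for k, v in self.coords.items() if k in set(ids)})

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` (3-vector -> 3-vector) to every present landmark."""
        return LandmarkSet({k: fn(v) for k, v in self.coords.items()})

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.coords)

    def __repr__(self) -> str:
        return f"LandmarkSet({sorted(self.coords)})"


@dataclass
class Sample:
    """One imaging session: image, mask, landmarks, optional tissue maps."""

    meta: SubjectMeta
    image: ImageVolume
    mask: BrainMask
    landmarks: LandmarkSet
    probmaps: Optional["ProbabilityMaps"] = None  # noqa: F821 (averaging module)

    def __post_init__(self) -> None:
        if not self.image.same_grid(self.mask):
            raise ValueError("image and mask must share one grid")


def _require_axis_aligned(affine: np.ndarray) -> None:
    R = np.asarray(affine)[:3, :3]
    off = R - np.diag(np.diag(R))
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(np.diag(R)))):
        raise ValueError(
            "affine axes are oblique; reorient to a canonical RAS grid before flipping"
        )
    if np.any(np.diag(R) <= 0):
        raise ValueError("affine is not in RAS orientation (negative axis direction)")


def mid_sagittal_plane_x(image: ImageVolume) -> float:
    """Physical x coordinate of the grid's central sagittal plane.

    Defined as the mid-plane of the grid along the left-right axis,
    halfway between the first and last voxel centres.
    """
    _require_axis_aligned(image.affine)
    n0 = image.data.shape[0]
    centre_idx = np.array([(n0 - 1) / 2.0, 0.0, 0.0])
    return float(image.voxel_to_physical(centre_idx)[0])


def flip_image(image: ImageVolume) -> ImageVolume:
    """Mirror a volume about its grid's central sagittal plane (operator S).

    Applying it twice returns the original volume voxelwise.
    """
    _require_axis_aligned(image.affine)
    flipped = np.ascontiguousarray(image.data[::-1, :, :])
    cls = BrainMask if isinstance(image, BrainMask) else ImageVolume
    return cls(flipped, image.affine.copy())


def flip_landmarks(
    lmks: LandmarkSet, registry: LandmarkRegistry, plane_x: float
) -> LandmarkSet:
    """Reflect landmarks about the sagittal plane ``x = plane_x``.

    Left/right ids are swapped through their registry mirror partner;
    midline ids keep their id.  Missingness follows the swapped id.
    """
    out = LandmarkSet()
    for lid, pt in lmks.coords.items():
        if lid not in registry:
            raise KeyError(f"landmark id {lid!r} not in registry")
        mirrored = pt.copy()
        mirrored[0] = 2.0 * plane_x - mirrored[0]
        out[registry.partner(lid)] = mirrored
    return out
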