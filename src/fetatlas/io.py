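"""Readers and writers: NIfTI rasters, landmark files, cohorts, atlas folders.

Volumes are reoriented to canonical RAS on load so that the package's
left-right flip convention (first axis) holds everywhere.  Landmarks come
in two dialects: an integer NIfTI label map in which voxel value ``v``
marks landmark ``v`` (possibly as a small blob, whose physical centroid
is used), and a TSV with columns ``id, x_mm, y_mm, z_mm``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .averaging import ProbabilityMaps, TISSUE_LABELS
from .core import (
    DEFAULT_REGISTRY,
    BrainMask,
    GestationalAge,
    ImageVolume,
    LandmarkRegistry,
    LandmarkSet,
    Sample,
    SubjectMeta,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_landmarks",
    "write_landmarks",
    "read_probmaps",
    "write_probmaps",
    "read_cohort",
    "write_cohort",
    "write_atlas",
    "write_sample",
]


def read_volume(path) -> ImageVolume:
    """Load a NIfTI volume, reoriented to canonical RAS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ImageVolume(data.astype(np.float64), np.asarray(img.affine))


def read_mask(path) -> BrainMask:
    v = read_volume(path)
    return BrainMask(v.data > 0.5, v.affine)


def write_volume(volume: ImageVolume, path, dtype=None) -> None:
    data = volume.data
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


def read_landmarks(
    path, registry: LandmarkRegistry = DEFAULT_REGISTRY, dialect: Optional[str] = None
) -> LandmarkSet:
    """Read landmarks from a label-map NIfTI or a TSV of physical points.

    The dialect is inferred from the file suffix when not given.  In the
    label-map dialect multiple voxels may carry one label; the landmark
    is placed at their physical centroid.  Ids absent from the file are
    missing.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt", ".csv") else "labelmap"
    if dialect == "labelmap":
        vol = read_volume(path)
        labels = np.round(vol.data).astype(int)
        out = LandmarkSet()
        for lab in np.unique(labels):
            if lab == 0:
                continue
            try:
                entry = registry.by_label(int(lab))
            except KeyError:
                raise ValueError(f"label value {lab} outside the landmark registry")
            idx = np.argwhere(labels == lab).astype(float)
            out[entry.landmark_id] = vol.voxel_to_physical(idx).mean(axis=0)
        return out
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df["id"].duplicated().any():
            dups = df["id"][df["id"].duplicated()].tolist()
            raise ValueError(f"duplicate landmark ids in {path}: {dups}")
        out = LandmarkSet()
        for _, row in df.iterrows():
            if row["id"] not in registry:
                raise ValueError(f"unknown landmark id {row['id']!r}")
            out[row["id"]] = np.array([row["x_mm"], row["y_mm"], row["z_mm"]])
        return out
    raise ValueError(f"unknown landmark dialect {dialect!r}")


def write_landmarks(
    lmks: LandmarkSet,
    path,
    registry: LandmarkRegistry = DEFAULT_REGISTRY,
    dialect: Optional[str] = None,
    grid_like: Optional[ImageVolume] = None,
) -> None:
    """Write landmarks as TSV or as a single-voxel-per-label NIfTI map."""
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt", ".csv") else "labelmap"
    if dialect == "tsv":
        rows = [
            {"id": lid, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]}
            for lid, p in sorted(lmks.coords.items())
        ]
        pd.DataFrame(rows, columns=["id", "x_mm", "y_mm", "z_mm"]).to_csv(
            path, sep="\t", index=False
        )
        return
    if grid_like is None:
        raise ValueError("labelmap dialect needs a reference grid")
    labels = np.zeros(grid_like.shape, dtype=np.int16)
    for lid, p in lmks.coords.items():
        vox = np.round(grid_like.physical_to_voxel(p)).astype(int)
        if np.any(vox < 0) or np.any(vox >= np.array(grid_like.shape)):
            continue  # landmark fell outside the raster
        labels[tuple(vox)] = registry[lid].label
    write_volume(ImageVolume(labels, grid_like.affine), path, dtype=np.int16)


def read_probmaps(paths: Sequence, n_classes: int = len(TISSUE_LABELS) + 1) -> ProbabilityMaps:
    """Stack per-class probability NIfTIs (class 0 = background first)."""
    vols = [read_volume(p) for p in paths]
    if len(vols) != n_classes:
        raise ValueError(f"expected {n_classes} class maps, got {len(vols)}")
    return ProbabilityMaps(np.stack([v.data for v in vols]), vols[0].affine)


def write_probmaps(probmaps: ProbabilityMaps, directory, prefix: str = "probmap") -> List[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(probmaps.n_classes):
        p = directory / f"{prefix}_class{c:02d}.nii.gz"
        write_volume(probmaps.class_volume(c), p, dtype=np.float32)
        paths.append(p)
    return paths


_COHORT_COLUMNS = [
    "subject_id", "session_id", "ga_weeks", "ga_days", "operated",
    "image", "mask", "landmarks", "probmaps",
]


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(
    path, registry: LandmarkRegistry = DEFAULT_REGISTRY, load_data: bool = True
) -> Tuple[pd.DataFrame, List[Sample]]:
    """Load a cohort TSV and (optionally) all referenced files.

    Paths in the table are resolved relative to the table's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _COHORT_COLUMNS[:5] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    if df.duplicated(subset=["subject_id", "session_id"]).any():
        raise ValueError("duplicate (subject_id, session_id) rows in cohort")
    samples: List[Sample] = []
    root = path.parent
    for _, row in df.iterrows():
        ga = GestationalAge.from_weeks_days(int(row["ga_weeks"]), int(row["ga_days"]))
        if not load_data:
            continue
        image = read_volume(root / row["image"])
        mask = read_mask(root / row["mask"])
        lmks = read_landmarks(root / row["landmarks"], registry)
        probmaps = None
        if "probmaps" in row and isinstance(row["probmaps"], str) and row["probmaps"]:
            pm_dir = root / row["probmaps"]
            paths = sorted(pm_dir.glob("*_class*.nii.gz"))
            probmaps = read_probmaps(paths)
        meta = SubjectMeta(
            str(row["subject_id"]), ga, bool(row["operated"]), str(row["session_id"])
        )
        samples.append(Sample(meta, image, mask, lmks, probmaps))
    return df, samples


def write_sample(sample: Sample, directory, registry: LandmarkRegistry = DEFAULT_REGISTRY) -> Dict[str, str]:
    """Write one sample's rasters and landmarks into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(sample.image, directory / "srr.nii.gz", dtype=np.float32)
    write_volume(sample.mask, directory / "mask.nii.gz", dtype=np.uint8)
    write_landmarks(sample.landmarks, directory / "lmks.tsv", registry, dialect="tsv")
    rel: Dict[str, str] = {
        "image": f"{directory.name}/srr.nii.gz",
        "mask": f"{directory.name}/mask.nii.gz",
        "landmarks": f"{directory.name}/lmks.tsv",
    }
    if sample.probmaps is not None:
        write_probmaps(sample.probmaps, directory / "probmaps")
        rel["probmaps"] = f"{directory.name}/probmaps"
    return rel


def write_atlas(atlas, out_dir, registry: LandmarkRegistry = DEFAULT_REGISTRY) -> List[Path]:
    """Write atlas time points as per-group folders.

    Each folder holds ``srr.nii.gz`` (average image), ``mask.nii.gz``,
    ``parcellation.nii.gz``, ``lmks.nii.gz`` (consensus landmark label
    map) plus a TSV dialect of the landmarks and a provenance manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    folders = []
    label_rows = [{"label": k, "name": v} for k, v in TISSUE_LABELS.items()]
    pd.DataFrame(label_rows).to_csv(out_dir / "parcellation_labels.tsv", sep="\t", index=False)
    registry.to_table().to_csv(out_dir / "landmark_registry.tsv", sep="\t", index=False)
    for tp in atlas:
        folder = out_dir / tp.name
        folder.mkdir(parents=True, exist_ok=True)
        write_volume(tp.image, folder / "srr.nii.gz", dtype=np.float32)
        write_volume(tp.mask, folder / "mask.nii.gz", dtype=np.uint8)
        write_volume(tp.parcellation, folder / "parcellation.nii.gz", dtype=np.int16)
        write_landmarks(
            tp.consensus_landmarks, folder / "lmks.nii.gz", registry,
            dialect="labelmap", grid_like=tp.image,
        )
        write_landmarks(tp.consensus_landmarks, folder / "lmks.tsv", registry, dialect="tsv")
        members = pd.DataFrame(
            tp.provenance.get("members", []),
            columns=["subject_id", "session_id", "weight", "augmented"],
        )
        members.to_csv(folder / "members.tsv", sep="\t", index=False)
        folders.append(folder)
    return folders
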