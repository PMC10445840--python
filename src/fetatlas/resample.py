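"""Grid resampling helpers shared by the Procrustes and registration stages."""

from __future__ import annotations

from typing import Callable, Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .core import BrainMask, ImageVolume, Sample
from .averaging import ProbabilityMaps
from .procrustes import ScalingTransform

__all__ = [
    "sample_at_physical",
    "grid_physical_points",
    "resample_volume",
    "resample_to_consensus",
]


def sample_at_physical(
    image: ImageVolume, pts: np.ndarray, order: int = 1, cval: float = 0.0
) -> np.ndarray:
    """Sample an image at physical mm points (..., 3) with spline interpolation."""
    pts = np.asarray(pts, dtype=float)
    vox = image.physical_to_voxel(pts.reshape(-1, 3))
    vals = map_coordinates(
        image.data.astype(float), vox.T, order=order, mode="constant", cval=cval
    )
    return vals.reshape(pts.shape[:-1])


def grid_physical_points(shape: Tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """Physical coordinates of all voxel centres of a grid, shape (*grid, 3)."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"), axis=-1
    )
    return idx @ np.asarray(affine, dtype=float)[:3, :3].T + np.asarray(affine)[:3, 3]


def resample_volume(
    image: ImageVolume,
    ref_shape: Tuple[int, int, int],
    ref_affine: np.ndarray,
    phys_map: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    order: int = 1,
) -> ImageVolume:
    """Pull an image back onto a reference grid.

    ``phys_map`` maps output physical points to input physical points
    (identity when omitted).  Binary masks are interpolated linearly and
    re-thresholded at 0.5.
    """
    pts = grid_physical_points(ref_shape, ref_affine).reshape(-1, 3)
    if phys_map is not None:
        pts = phys_map(pts)
    is_mask = isinstance(image, BrainMask)
    vals = sample_at_physical(image, pts, order=0 if order == 0 else order)
    vals = vals.reshape(ref_shape)
    if is_mask:
        return BrainMask(vals > 0.5, np.asarray(ref_affine, dtype=float))
    return ImageVolume(vals, np.asarray(ref_affine, dtype=float))


def resample_probmaps(
    probmaps: ProbabilityMaps,
    ref_shape: Tuple[int, int, int],
    ref_affine: np.ndarray,
    phys_map: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> ProbabilityMaps:
    """Linearly resample each class map, then renormalize voxelwise.

    Voxels that fall entirely outside the source (class-sum 0) are set to
    pure background.
    """
    out = np.stack(
        [
            resample_volume(probmaps.class_volume(c), ref_shape, ref_affine, phys_map).data
            for c in range(probmaps.n_classes)
        ]
    )
    total = out.sum(axis=0)
    empty = total <= 1e-12
    out[:, empty] = 0.0
    out[0, empty] = 1.0
    total = out.sum(axis=0)
    out /= total
    return ProbabilityMaps(out, np.asarray(ref_affine, dtype=float))


def resample_to_consensus(
    sample: Sample,
    transform: ScalingTransform,
    ref_shape: Tuple[int, int, int],
    ref_affine: np.ndarray,
) -> Sample:
    """Map a sample into the consensus frame of a Procrustes solution.

    The output value at physical point ``y`` is the input sampled at
    ``M^-1 (y - t)``; landmarks are mapped forward as ``M x + t``.
    """
    inv = transform.inverse()
    phys_map = inv.apply
    image = resample_volume(sample.image, ref_shape, ref_affine, phys_map)
    mask = resample_volume(sample.mask, ref_shape, ref_affine, phys_map)
    probmaps = (
        resample_probmaps(sample.probmaps, ref_shape, ref_affine, phys_map)
        if sample.probmaps is not None
        else None
    )
    landmarks = sample.landmarks.transformed(transform.apply)
    return Sample(sample.meta, image, BrainMask(mask.data, mask.affine), landmarks, probmaps)
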