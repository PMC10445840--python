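"""Intensity normalization and time-weighted, left-right-symmetric averaging.

The weighted symmetric average of a stack of co-registered volumes is

    I_avg = (1 / 2N) * sum_i w_i (I_i + S(I_i))

where ``S`` mirrors a volume about the central sagittal plane of its grid.
As printed, the formula preserves intensity scale only when the weights
sum to ``N``; the weights are therefore renormalized to sum to ``N``
before averaging, making the operator a convex combination of symmetrized
volumes.  The output is exactly ``S``-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .core import BrainMask, ImageVolume, flip_image

__all__ = [
    "TISSUE_LABELS",
    "ProbabilityMaps",
    "normalize_intensity",
    "weighted_symmetric_average",
    "weighted_symmetric_average_probmaps",
    "argmax_parcellation",
]

# Parcellation label table (0 = background).  All eight classes are
# bilaterally self-symmetric, so mirroring a map does not permute classes.
TISSUE_LABELS: Dict[int, str] = {
    1: "white_matter",
    2: "ventricles",
    3: "cerebellum",
    4: "extra_axial_csf",
    5: "cortical_grey_matter",
    6: "deep_grey_matter",
    7: "brainstem",
    8: "corpus_callosum",
}
N_TISSUES = len(TISSUE_LABELS)


class ProbabilityMaps:
    """Per-class tissue probability grids (8 tissues + background).

    ``data`` has shape (n_classes, *grid); class 0 is background.  Values
    lie in [0, 1] and sum to 1 over classes at every voxel.
    """

    def __init__(self, data: np.ndarray, affine: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.affine = np.asarray(affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ProbabilityMaps data must be (n_classes, nx, ny, nz)")

    @property
    def n_classes(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self):
        return self.data.shape[1:]

    def class_volume(self, c: int) -> ImageVolume:
        return ImageVolume(self.data[c], self.affine)

    def is_normalized(self, atol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.data.sum(axis=0) - 1.0) <= atol))

    def flipped(self) -> "ProbabilityMaps":
        out = np.stack([flip_image(self.class_volume(c)).data for c in range(self.n_classes)])
        return ProbabilityMaps(out, self.affine.copy())

    def copy(self) -> "ProbabilityMaps":
        return ProbabilityMaps(self.data.copy(), self.affine.copy())

    @classmethod
    def from_labels(cls, labels: np.ndarray, affine: np.ndarray, n_classes: int = N_TISSUES + 1) -> "ProbabilityMaps":
        """One-hot probability maps from an integer label volume."""
        labels = np.asarray(labels)
        data = np.stack([(labels == c).astype(float) for c in range(n_classes)])
        return cls(data, affine)


def normalize_intensity(
    image: ImageVolume,
    mask: BrainMask,
    target_mean: float = 2000.0,
    target_sd: float = 500.0,
) -> ImageVolume:
    """Linear intensity transform setting in-mask mean/sd to target values.

    The same affine transform ``a * I + b`` is applied everywhere,
    including outside the mask.
    """
    if not image.same_grid(mask):
        raise ValueError("image and mask must share one grid")
    inside = image.data[mask.data]
    if inside.size == 0:
        raise ValueError("empty brain mask")
    mu = float(inside.mean())
    sd = float(inside.std())
    if sd <= 0:
        raise ValueError("constant image inside the mask: normalization undefined")
    a = target_sd / sd
    b = target_mean - a * mu
    return ImageVolume(a * image.data.astype(float) + b, image.affine.copy())


def _normalized_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a nonempty 1D sequence")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return w * (w.size / total)


def weighted_symmetric_average(
    images: Sequence[ImageVolume], weights: Sequence[float]
) -> ImageVolume:
    """Time-weighted average of volumes and their sagittal mirrors."""
    if len(images) != len(weights):
        raise ValueError("images and weights length mismatch")
    w = _normalized_weights(weights)
    ref = images[0]
    acc = np.zeros(ref.data.shape, dtype=float)
    for img, wi in zip(images, w):
        if not img.same_grid(ref):
            raise ValueError("all volumes must share one grid")
        acc += wi * (img.data.astype(float) + flip_image(img).data.astype(float))
    out = acc / (2.0 * len(images))
    # guarantee exact S-invariance against floating-point asymmetry
    out = 0.5 * (out + out[::-1, :, :])
    return ImageVolume(out, ref.affine.copy())


def weighted_symmetric_average_probmaps(
    probmaps: Sequence[ProbabilityMaps], weights: Sequence[float]
) -> ProbabilityMaps:
    """Per-class symmetric weighted average of normalized probability maps."""
    if len(probmaps) != len(weights):
        raise ValueError("probmaps and weights length mismatch")
    for p in probmaps:
        if not p.is_normalized(atol=1e-5):
            raise ValueError("input probability maps must sum to 1 at every voxel")
    ref = probmaps[0]
    out = np.zeros_like(ref.data)
    for c in range(ref.n_classes):
        avg = weighted_symmetric_average(
            [p.class_volume(c) for p in probmaps], weights
        )
        out[c] = avg.data
    # renormalize away rounding error only; the average of normalized maps
    # is normalized up to float arithmetic
    total = out.sum(axis=0)
    out = out / np.where(total > 0, total, 1.0)
    return ProbabilityMaps(out, ref.affine.copy())


def argmax_parcellation(probmaps: ProbabilityMaps) -> ImageVolume:
    """Per-voxel label of the maximal class; ties go to the lowest index."""
    labels = np.argmax(probmaps.data, axis=0).astype(np.int16)
    return ImageVolume(labels, probmaps.affine.copy())
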