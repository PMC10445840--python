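"""Landmark-regularized non-linear registration on a cubic B-spline FFD.

The transform maps fixed-image (subject) physical points to moving-image
(atlas) physical points as ``phi(x) = A x + u(x)``, where ``A`` is an
affine initialization and ``u`` a displacement field parameterized by
cubic B-spline coefficients on a regular control lattice (default 3 mm
spacing).  The registration cost is

    - a_lncc * LNCC(F, M o phi)
    + a_lmks * sum_k ||phi(x_k^fixed) - x_k^moving||^2
    + a_be * BE(u) + a_le * LE(u)

with LNCC the mean over in-mask voxels of the squared local correlation
coefficient (Gaussian-window local moments), BE the mean squared second
spatial derivative of the displacement and LE the mean squared Frobenius
norm of the symmetric displacement-Jacobian, both evaluated on the
control lattice.  Optimization is coarse-to-fine L-BFGS with analytic
gradients for every term (the image-gradient factor of the similarity
term uses sampled central differences of the moving image).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize

from .averaging import ProbabilityMaps
from .config import RegWeights
from .core import BrainMask, ImageVolume, LandmarkSet, Sample
from .resample import grid_physical_points

__all__ = [
    "FFDTransform",
    "lncc_similarity",
    "regularization_energy",
    "registration_cost",
    "fit_affine_init",
    "register_ffd",
    "apply_transform",
]


def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel with support (-2, 2)."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1.0
    out[m1] = (4.0 - 6.0 * t[m1] ** 2 + 3.0 * t[m1] ** 3) / 6.0
    m2 = (t >= 1.0) & (t < 2.0)
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


def _axis_basis(coords: np.ndarray, n_ctrl: int) -> sp.csr_matrix:
    """1-D B-spline evaluation matrix from lattice coords to sample values."""
    base = np.floor(coords).astype(int)
    rows, cols, vals = [], [], []
    for off in range(-1, 3):
        idx = base + off
        w = _bspline3(coords - idx)
        ok = (idx >= 0) & (idx < n_ctrl)
        rows.append(np.nonzero(ok)[0])
        cols.append(idx[ok])
        vals.append(w[ok])
    M = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), n_ctrl),
    )
    return M.tocsr()


def _sep_apply(mats: Sequence[sp.spmatrix], arr: np.ndarray) -> np.ndarray:
    """Apply one sparse matrix per axis to a 3D array (separable tensor op)."""
    for ax, M in enumerate(mats):
        arr = np.moveaxis(arr, ax, 0)
        shp = arr.shape
        arr = (M @ arr.reshape(shp[0], -1)).reshape((M.shape[0],) + shp[1:])
        arr = np.moveaxis(arr, 0, ax)
    return arr


@dataclass
class FFDTransform:
    """Cubic B-spline free-form deformation composed with an affine init.

    ``coeffs`` (ncx, ncy, ncz, 3) are B-spline coefficients of the
    displacement in mm over a lattice with ``origin``/``ctrl_spacing``
    in fixed-image physical space.  The transform is the identity when
    the coefficients are zero and the affine is the identity.
    """

    coeffs: np.ndarray
    origin: np.ndarray
    ctrl_spacing: np.ndarray
    affine_init: np.ndarray  # 4x4, fixed physical -> moving physical
    fixed_shape: Tuple[int, int, int]
    fixed_affine: np.ndarray

    @classmethod
    def identity_like(
        cls,
        fixed: ImageVolume,
        ctrl_spacing_mm: float = 3.0,
        affine_init: Optional[np.ndarray] = None,
    ) -> "FFDTransform":
        lo = fixed.voxel_to_physical(np.zeros(3))
        hi = fixed.voxel_to_physical(np.array(fixed.shape, dtype=float) - 1)
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        spacing = np.full(3, float(ctrl_spacing_mm))
        origin = lo - spacing
        n_ctrl = np.floor((hi - origin) / spacing).astype(int) + 3
        coeffs = np.zeros(tuple(n_ctrl) + (3,))
        if affine_init is None:
            affine_init = np.eye(4)
        return cls(coeffs, origin, spacing, np.asarray(affine_init, float),
                   tuple(fixed.shape), fixed.affine.copy())

    @property
    def lattice_shape(self) -> Tuple[int, int, int]:
        return self.coeffs.shape[:3]

    def _lattice_coords(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) / self.ctrl_spacing

    def displacement_at(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate the B-spline displacement at physical points (N, 3)."""
        B = self.point_basis(pts)
        return B @ self.coeffs.reshape(-1, 3)

    def point_basis(self, pts: np.ndarray) -> sp.csr_matrix:
        """Sparse (N, n_ctrl) B-spline basis matrix at physical points."""
        lat = self._lattice_coords(np.asarray(pts, float).reshape(-1, 3))
        n = lat.shape[0]
        shape = self.lattice_shape
        base = np.floor(lat).astype(int)
        rows, cols, vals = [], [], []
        for off in product(range(-1, 3), repeat=3):
            idx = base + np.array(off)
            w = np.prod(_bspline3(lat - idx), axis=1)
            ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
            flat = np.ravel_multi_index(tuple(idx[ok].T), shape)
            rows.append(np.nonzero(ok)[0])
            cols.append(flat)
            vals.append(w[ok])
        M = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, int(np.prod(shape))),
        )
        return M.tocsr()

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map fixed-space physical points to moving-space physical points."""
        pts = np.asarray(pts, dtype=float)
        flat = pts.reshape(-1, 3)
        A = self.affine_init
        out = flat @ A[:3, :3].T + A[:3, 3] + self.displacement_at(flat)
        return out.reshape(pts.shape)


def lncc_similarity(
    fixed: ImageVolume,
    warped: ImageVolume,
    mask: BrainMask,
    kernel_sd_mm: float = 6.0,
) -> float:
    """Mean squared local correlation coefficient over the mask, in [0, 1]."""
    if not fixed.same_grid(warped) or not fixed.same_grid(mask):
        raise ValueError("fixed, warped and mask must share one grid")
    if kernel_sd_mm <= 0:
        raise ValueError("kernel_sd_mm must be positive")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    sigma = kernel_sd_mm / fixed.spacing
    val, _ = _lncc_value_grad(
        fixed.data.astype(float), warped.data.astype(float),
        mask.data.astype(float), sigma, need_grad=False,
    )
    return val


def _lncc_value_grad(
    F: np.ndarray,
    W: np.ndarray,
    m: np.ndarray,
    sigma_vox: np.ndarray,
    eps: float = 1e-6,
    need_grad: bool = True,
):
    """LNCC value and its gradient with respect to the warped image.

    Local moments use window-normalized Gaussian smoothing
    (``S(x) = K(x) / K(1)`` with ``K`` a zero-padded Gaussian), which
    keeps the local correlation exactly invariant under affine intensity
    rescaling even near the grid boundary; the gradient uses the matching
    adjoint ``S^T(q) = K(q / K(1))``.
    """
    K = lambda x: gaussian_filter(x, sigma_vox, mode="constant")
    k = np.maximum(K(np.ones_like(F)), 1e-12)
    S = lambda x: K(x) / k
    muF, muW = S(F), S(W)
    A = S(F * W) - muF * muW
    B = S(F * F) - muF**2
    C = S(W * W) - muW**2
    Bc = np.maximum(B, eps)
    Cc = np.maximum(C, eps)
    rho2 = A * A / (Bc * Cc)
    Nm = m.sum()
    val = float((rho2 * m).sum() / Nm)
    if not need_grad:
        return val, None
    ST = lambda x: K(x / k)
    q1 = m * (2.0 * A / (Bc * Cc))
    q2 = m * (A * A / (Bc * Cc * Cc)) * (C > eps)
    g = F * ST(q1) - ST(q1 * muF) - 2.0 * W * ST(q2) + 2.0 * ST(q2 * muW)
    return val, g / Nm


def _lattice_diff_ops(shape: Tuple[int, int, int], spacing: np.ndarray):
    """Interior finite-difference operators on the control lattice.

    Returns (first_derivative_ops, bending_normal_matrix, n_interior);
    all operators map the flattened lattice to the common interior grid.
    """
    if any(n < 3 for n in shape):
        return None
    mats_e, mats_d1, mats_d2 = [], [], []
    for n, h in zip(shape, spacing):
        rows = np.arange(n - 2)
        e = sp.coo_matrix((np.ones(n - 2), (rows, rows + 1)), shape=(n - 2, n)).tocsr()
        d1 = sp.coo_matrix(
            (
                np.concatenate([-np.ones(n - 2), np.ones(n - 2)]) / (2.0 * h),
                (np.concatenate([rows, rows]), np.concatenate([rows, rows + 2])),
            ),
            shape=(n - 2, n),
        ).tocsr()
        d2 = sp.coo_matrix(
            (
                np.concatenate([np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)]) / h**2,
                (np.tile(rows, 3), np.concatenate([rows, rows + 1, rows + 2])),
            ),
            shape=(n - 2, n),
        ).tocsr()
        mats_e.append(e)
        mats_d1.append(d1)
        mats_d2.append(d2)

    def kron3(ms):
        return sp.kron(ms[0], sp.kron(ms[1], ms[2])).tocsr()

    d1_ops = []
    for p in range(3):
        d1_ops.append(kron3([mats_d1[a] if a == p else mats_e[a] for a in range(3)]))
    M_be = None
    for p in range(3):
        for q in range(3):
            if p == q:
                O = kron3([mats_d2[a] if a == p else mats_e[a] for a in range(3)])
            else:
                O = kron3(
                    [mats_d1[a] if a in (p, q) else mats_e[a] for a in range(3)]
                )
            OtO = (O.T @ O).tocsr()
            M_be = OtO if M_be is None else M_be + OtO
    n_int = int(np.prod([n - 2 for n in shape]))
    return d1_ops, M_be, n_int


def regularization_energy(transform: FFDTransform) -> Tuple[float, float]:
    """(bending, linear) energies of the displacement on the control lattice."""
    ops = _lattice_diff_ops(transform.lattice_shape, transform.ctrl_spacing)
    if ops is None:
        return 0.0, 0.0
    d1_ops, M_be, n_int = ops
    C = transform.coeffs.reshape(-1, 3)
    bending = sum(float(C[:, d] @ (M_be @ C[:, d])) for d in range(3)) / n_int
    linear = 0.0
    J = [[d1_ops[p] @ C[:, q] for q in range(3)] for p in range(3)]
    for p in range(3):
        for q in range(3):
            Spq = 0.5 * (J[p][q] + J[q][p])
            linear += float((Spq**2).sum())
    return bending, linear / n_int


def _landmarks_of(obj) -> Optional[LandmarkSet]:
    for attr in ("landmarks", "consensus_landmarks"):
        lm = getattr(obj, attr, None)
        if lm is not None:
            return lm
    return None


def _shared_landmarks(fixed_obj, moving_obj) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    lf, lm = _landmarks_of(fixed_obj), _landmarks_of(moving_obj)
    if lf is None or lm is None:
        return np.zeros((0, 3)), np.zeros((0, 3)), []
    ids = sorted(set(lf.present_ids) & set(lm.present_ids))
    xf = np.array([lf[i] for i in ids]).reshape(-1, 3)
    xm = np.array([lm[i] for i in ids]).reshape(-1, 3)
    return xf, xm, ids


class _LevelCost:
    """Cost and analytic gradient of the registration objective at one level."""

    def __init__(
        self,
        fixed_image: ImageVolume,
        fixed_mask: BrainMask,
        moving_image: ImageVolume,
        transform: FFDTransform,
        weights: RegWeights,
        lmks_fixed: np.ndarray,
        lmks_moving: np.ndarray,
    ):
        self.transform = transform
        self.weights = weights
        self.F = fixed_image.data.astype(float)
        self.m = fixed_mask.data.astype(float)
        if self.m.sum() == 0:
            raise ValueError("empty fixed mask")
        self.sigma_vox = weights.lncc_kernel_sd_mm / fixed_image.spacing
        self.grid_shape = fixed_image.shape
        pts = grid_physical_points(fixed_image.shape, fixed_image.affine).reshape(-1, 3)
        A = transform.affine_init
        self.A_pts = pts @ A[:3, :3].T + A[:3, 3]
        # separable per-axis B-spline evaluation matrices (axis-aligned grid)
        self.B_axis = []
        for a in range(3):
            n_vox = fixed_image.shape[a]
            phys = fixed_image.affine[a, a] * np.arange(n_vox) + fixed_image.affine[a, 3]
            coords = (phys - transform.origin[a]) / transform.ctrl_spacing[a]
            self.B_axis.append(_axis_basis(coords, transform.lattice_shape[a]))
        self.moving = moving_image
        self.M_inv = np.linalg.inv(moving_image.affine)
        self.Mdata = moving_image.data.astype(float)
        sp_mov = moving_image.spacing
        self.Mgrad = [
            np.gradient(self.Mdata, sp_mov[a], axis=a) for a in range(3)
        ]
        ops = _lattice_diff_ops(transform.lattice_shape, transform.ctrl_spacing)
        self.reg_ops = ops
        self.lmks_fixed = lmks_fixed
        self.lmks_moving = lmks_moving
        if len(lmks_fixed):
            self.Bl = transform.point_basis(lmks_fixed)
            self.A_lmks = lmks_fixed @ A[:3, :3].T + A[:3, 3]
        else:
            self.Bl = None

    def _to_moving_vox(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.M_inv[:3, :3].T + self.M_inv[:3, 3]

    def __call__(self, theta: np.ndarray):
        w = self.weights
        lat_shape = self.transform.lattice_shape
        C = theta.reshape(lat_shape + (3,))
        u = np.stack(
            [_sep_apply(self.B_axis, C[..., d]) for d in range(3)], axis=-1
        )
        warped_pts = self.A_pts + u.reshape(-1, 3)
        vox = self._to_moving_vox(warped_pts)
        W = map_coordinates(self.Mdata, vox.T, order=1, mode="constant").reshape(self.grid_shape)
        lncc, dW = _lncc_value_grad(self.F, W, self.m, self.sigma_vox)
        cost = -w.alpha_lncc * lncc
        grad_lat = np.zeros(lat_shape + (3,))
        for d in range(3):
            gd = map_coordinates(self.Mgrad[d], vox.T, order=1, mode="constant").reshape(
                self.grid_shape
            )
            dense = -w.alpha_lncc * dW * gd
            grad_lat[..., d] = _sep_apply([M.T for M in self.B_axis], dense)

        if self.Bl is not None and w.alpha_lmks > 0:
            u_l = self.Bl @ C.reshape(-1, 3)
            r = self.A_lmks + u_l - self.lmks_moving
            cost += w.alpha_lmks * float((r**2).sum())
            grad_lat += (2.0 * w.alpha_lmks * (self.Bl.T @ r)).reshape(lat_shape + (3,))

        if self.reg_ops is not None and (w.alpha_be > 0 or w.alpha_le > 0):
            d1_ops, M_be, n_int = self.reg_ops
            Cf = C.reshape(-1, 3)
            if w.alpha_be > 0:
                for d in range(3):
                    Mc = M_be @ Cf[:, d]
                    cost += w.alpha_be * float(Cf[:, d] @ Mc) / n_int
                    grad_lat[..., d] += (2.0 * w.alpha_be / n_int) * Mc.reshape(lat_shape)
            if w.alpha_le > 0:
                J = [[d1_ops[p] @ Cf[:, q] for q in range(3)] for p in range(3)]
                le = 0.0
                gle = np.zeros_like(Cf)
                for p in range(3):
                    for q in range(3):
                        Spq = 0.5 * (J[p][q] + J[q][p])
                        le += float((Spq**2).sum())
                        gle[:, q] += d1_ops[p].T @ Spq
                cost += w.alpha_le * le / n_int
                grad_lat += (2.0 * w.alpha_le / n_int) * gle.reshape(lat_shape + (3,))
        return cost, grad_lat.ravel()


def registration_cost(
    subject: Sample,
    atlas,
    transform: FFDTransform,
    weights: Optional[RegWeights] = None,
    use_landmarks: bool = True,
) -> Tuple[float, Dict[str, float]]:
    """Evaluate the full registration objective and its components."""
    weights = weights or RegWeights()
    xf, xm, ids = _shared_landmarks(subject, atlas) if use_landmarks else (
        np.zeros((0, 3)), np.zeros((0, 3)), [],
    )
    machine = _LevelCost(
        subject.image, subject.mask, atlas.image, transform, weights, xf, xm
    )
    u = np.stack(
        [_sep_apply(machine.B_axis, transform.coeffs[..., d]) for d in range(3)], axis=-1
    )
    warped_pts = machine.A_pts + u.reshape(-1, 3)
    vox = machine._to_moving_vox(warped_pts)
    W = map_coordinates(machine.Mdata, vox.T, order=1, mode="constant").reshape(
        machine.grid_shape
    )
    lncc, _ = _lncc_value_grad(machine.F, W, machine.m, machine.sigma_vox, need_grad=False)
    bending, linear = regularization_energy(transform)
    lmk_term = 0.0
    if len(xf):
        phi = transform.apply_points(xf)
        lmk_term = float(((phi - xm) ** 2).sum())
    cost = (
        -weights.alpha_lncc * lncc
        + weights.alpha_lmks * lmk_term
        + weights.alpha_be * bending
        + weights.alpha_le * linear
    )
    return cost, {
        "lncc": lncc,
        "landmark": lmk_term,
        "bending": bending,
        "linear": linear,
        "alpha_lncc": weights.alpha_lncc,
    }


def fit_affine_init(subject: Sample, atlas, use_landmarks: bool = True) -> np.ndarray:
    """Initial affine (scaling + translation) mapping subject to atlas space.

    With at least four shared landmarks, a per-axis least-squares fit of
    scale and translation; otherwise moment matching of the brain masks
    (centroids and per-axis second-moment ratios).
    """
    if use_landmarks:
        xf, xm, ids = _shared_landmarks(subject, atlas)
        if len(ids) >= 4:
            A = np.eye(4)
            for d in range(3):
                x, y = xf[:, d], xm[:, d]
                var = x.var()
                if var > 1e-12:
                    s = ((x - x.mean()) * (y - y.mean())).mean() / var
                    if s <= 1e-6:
                        s = 1.0
                else:
                    s = 1.0
                A[d, d] = s
                A[d, 3] = y.mean() - s * x.mean()
            return A
    # mask-moment fallback
    ms, ma = subject.mask, atlas.mask
    if ms.n_voxels == 0 or getattr(ma, "n_voxels", 0) == 0:
        raise ValueError("affine initialization needs landmarks or nonempty masks")

    def moments(mask: BrainMask):
        idx = np.argwhere(mask.data).astype(float)
        pts = mask.voxel_to_physical(idx)
        c = pts.mean(axis=0)
        v = ((pts - c) ** 2).mean(axis=0)
        return c, v

    cs, vs = moments(ms)
    ca, va = moments(ma)
    s = np.sqrt(va / np.maximum(vs, 1e-12))
    A = np.eye(4)
    A[:3, :3] = np.diag(s)
    A[:3, 3] = ca - s * cs
    return A


def _downsample(image: ImageVolume, factor: int, smooth: bool = True) -> ImageVolume:
    if factor == 1:
        return image
    data = image.data.astype(float)
    if smooth:
        data = gaussian_filter(data, sigma=factor / 2.0, mode="nearest")
    data = data[::factor, ::factor, ::factor]
    aff = image.affine.copy()
    aff[:3, :3] *= factor
    return ImageVolume(data, aff)


def register_ffd(
    subject: Sample,
    atlas,
    weights: Optional[RegWeights] = None,
    use_landmarks: bool = True,
    seed: int = 0,
    max_iter_per_level: Sequence[int] = (40, 30, 25),
) -> FFDTransform:
    """Coarse-to-fine FFD registration of a subject to an atlas time point.

    Returns the transform mapping subject physical coordinates to atlas
    physical coordinates.  The optimization is deterministic; ``seed`` is
    accepted for interface uniformity.
    """
    weights = weights or RegWeights()
    affine0 = fit_affine_init(subject, atlas, use_landmarks=use_landmarks)
    xf_all, xm_all, ids = _shared_landmarks(subject, atlas) if use_landmarks else (
        np.zeros((0, 3)), np.zeros((0, 3)), [],
    )
    levels = weights.pyramid_levels
    prev: Optional[FFDTransform] = None
    transform: Optional[FFDTransform] = None
    for level in range(levels - 1, -1, -1):
        factor = 2**level
        fixed_img = _downsample(subject.image, factor)
        mask_ds = BrainMask(subject.mask.data[::factor, ::factor, ::factor], fixed_img.affine)
        mov_img = (
            ImageVolume(
                gaussian_filter(atlas.image.data.astype(float), sigma=factor / 2.0, mode="nearest"),
                atlas.image.affine,
            )
            if factor > 1
            else atlas.image
        )
        spacing_mm = weights.grid_spacing_mm * factor
        transform = FFDTransform.identity_like(fixed_img, spacing_mm, affine0)
        transform.fixed_shape = tuple(subject.image.shape)
        transform.fixed_affine = subject.image.affine.copy()
        if prev is not None:
            # initialize from the coarser level: displacement values at the
            # new control points serve as the new coefficients
            lat_pts = grid_physical_points(
                transform.lattice_shape,
                np.vstack(
                    [
                        np.hstack([np.diag(transform.ctrl_spacing), transform.origin[:, None]]),
                        [0, 0, 0, 1],
                    ]
                ),
            ).reshape(-1, 3)
            transform.coeffs = prev.displacement_at(lat_pts).reshape(
                transform.lattice_shape + (3,)
            )
        machine = _LevelCost(
            fixed_img, mask_ds, mov_img, transform, weights, xf_all, xm_all
        )
        res = minimize(
            machine,
            transform.coeffs.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": int(max_iter_per_level[min(level, len(max_iter_per_level) - 1)]),
                     "ftol": 1e-9, "gtol": 1e-7},
        )
        if not np.isfinite(res.fun):
            raise FloatingPointError("non-finite registration cost")
        transform.coeffs = res.x.reshape(transform.lattice_shape + (3,))
        prev = transform
    assert transform is not None
    return transform


def apply_transform(transform: FFDTransform, obj, mode: str = "linear"):
    """Resample a moving-space object onto the transform's fixed grid.

    ``mode`` is "linear" for images and probability maps, "nearest" for
    label volumes, and "forward-points" to map fixed-space points (or a
    LandmarkSet) into moving space.
    """
    if mode == "forward-points":
        if isinstance(obj, LandmarkSet):
            return obj.transformed(lambda p: transform.apply_points(p))
        return transform.apply_points(np.asarray(obj, dtype=float))
    pts = grid_physical_points(transform.fixed_shape, transform.fixed_affine).reshape(-1, 3)
    warped = transform.apply_points(pts)
    if isinstance(obj, ProbabilityMaps):
        if mode != "linear":
            raise ValueError("probability maps require linear interpolation")
        inv = np.linalg.inv(obj.affine)
        vox = warped @ inv[:3, :3].T + inv[:3, 3]
        out = np.stack(
            [
                map_coordinates(obj.data[c], vox.T, order=1, mode="constant").reshape(
                    transform.fixed_shape
                )
                for c in range(obj.n_classes)
            ]
        )
        total = out.sum(axis=0)
        empty = total <= 1e-12
        out[:, empty] = 0.0
        out[0, empty] = 1.0
        out /= out.sum(axis=0)
        return ProbabilityMaps(out, transform.fixed_affine.copy())
    if not isinstance(obj, ImageVolume):
        raise TypeError(f"cannot warp object of type {type(obj)!r} with mode {mode!r}")
    order = {"linear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown mode {mode!r}")
    inv = np.linalg.inv(obj.affine)
    vox = warped @ inv[:3, :3].T + inv[:3, 3]
    vals = map_coordinates(obj.data, vox.T, order=order, mode="constant").reshape(
        transform.fixed_shape
    )
    if isinstance(obj, BrainMask):
        return BrainMask(vals > 0.5, transform.fixed_affine.copy())
    return ImageVolume(vals, transform.fixed_affine.copy())
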