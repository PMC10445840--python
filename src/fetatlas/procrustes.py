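"""Weighted generalized Procrustes alignment with missing landmarks.

Aligns ``n`` landmark configurations with per-sample anisotropic scaling
transforms ``x -> diag(scale) x + translation`` to a free consensus
configuration ``g``, minimizing

    1/2 sum_i sum_k w_ik || M_i x_ik + t_i - g_k ||^2

subject to two gauge-fixing constraints on the consensus: its centroid
equals the centroid of the weighted per-landmark means of the raw data,
and its mean squared deviation about the centroid (the "size" of the
system) equals that of the weighted raw-landmark means.  A zero weight
encodes a missing landmark (or a session outside the temporal window),
so missing data contribute nothing to the objective.

The problem is solved by alternating least squares:

* transform step — for each sample, per-axis weighted linear regression
  of (scale, translation) against the current consensus (closed form);
* consensus step — exact minimization over ``g`` of the weighted
  least-squares pull toward the transformed landmarks subject to both
  constraints (a one-dimensional secular equation solved by bracketed
  root finding).

Both steps are exact block minimizations, so the objective trace is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .core import LandmarkSet

__all__ = [
    "ScalingTransform",
    "WGPResult",
    "landmark_array",
    "wgp_objective",
    "solve_wgp",
]


@dataclass
class ScalingTransform:
    """Anisotropic scaling plus translation: ``x -> diag(scale) x + translation``."""

    scale: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if np.any(self.scale <= 0):
            raise ValueError("scale components must be positive")

    @classmethod
    def identity(cls) -> "ScalingTransform":
        return cls(np.ones(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) * self.scale + self.translation

    def inverse(self) -> "ScalingTransform":
        return ScalingTransform(1.0 / self.scale, -self.translation / self.scale)

    def apply_landmarks(self, lmks: LandmarkSet) -> LandmarkSet:
        return lmks.transformed(self.apply)


@dataclass
class WGPResult:
    transforms: List[ScalingTransform]
    consensus: np.ndarray  # (K, 3)
    landmark_ids: List[str]
    objective: float
    objective_trace: List[float]
    iterations: int
    converged: bool
    barycenter_residual: float
    size_residual: float

    def consensus_landmarks(self) -> LandmarkSet:
        return LandmarkSet({lid: g for lid, g in zip(self.landmark_ids, self.consensus)})


def landmark_array(
    landmark_sets: Sequence[LandmarkSet], ids: Sequence[str]
) -> np.ndarray:
    """Stack landmark sets into an (n, K, 3) array with NaN for missing."""
    n, K = len(landmark_sets), len(ids)
    X = np.full((n, K, 3), np.nan)
    for i, ls in enumerate(landmark_sets):
        for k, lid in enumerate(ids):
            p = ls.get(lid)
            if p is not None:
                X[i, k] = p
    return X


def wgp_objective(
    X: np.ndarray,
    W: np.ndarray,
    transforms: Sequence[ScalingTransform],
    consensus: np.ndarray,
) -> float:
    """Evaluate 1/2 sum_ik w_ik ||M_i x_ik + t_i - g_k||^2.

    Entries with zero weight contribute nothing even when the landmark is
    missing (NaN); a positive weight on a missing landmark is an error.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    consensus = np.asarray(consensus, dtype=float)
    n, K, _ = X.shape
    if W.shape != (n, K):
        raise ValueError("weight matrix shape mismatch")
    missing = np.isnan(X).any(axis=2)
    if np.any((W > 0) & missing):
        raise ValueError("positive weight on a missing landmark")
    total = 0.0
    for i in range(n):
        Y = transforms[i].apply(np.where(missing[i][:, None], 0.0, X[i]))
        r = Y - consensus
        total += 0.5 * float(np.sum(W[i][:, None] * r**2))
    return total


def _weighted_landmark_means(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """x_bar_k = sum_i w_ik x_ik / sum_i w_ik, ignoring missing entries."""
    Xz = np.where(np.isnan(X), 0.0, X)
    num = np.einsum("ik,ikd->kd", W, Xz)
    den = W.sum(axis=0)
    if np.any(den <= 0):
        raise ValueError("every landmark must carry positive weight in at least one sample")
    return num / den[:, None]


def _axis_fit(
    x: np.ndarray,
    g: np.ndarray,
    w: np.ndarray,
    prev: Tuple[float, float],
    min_scale: float = 0.5,
    max_scale: float = 2.0,
):
    """Best (scale, offset) for one sample along one axis; never worse than prev.

    The scale is confined to ``[min_scale, max_scale]``, the plausible
    range of relative anatomical scaling within a group; outside slopes
    take the boundary optimum of the bounded quadratic.  Falls back to
    scale 1 with the weighted mean residual as offset when the axis is
    degenerate (fewer than two positively weighted landmarks or no
    spread along the axis).
    """

    def cost(m: float, t: float) -> float:
        return 0.5 * float(np.sum(w * (m * x + t - g) ** 2))

    sw = w.sum()
    xm = float(np.sum(w * x) / sw)
    gm = float(np.sum(w * g) / sw)
    candidates = [prev, (1.0, gm - xm)]
    var = float(np.sum(w * (x - xm) ** 2) / sw)
    if np.count_nonzero(w > 0) >= 2 and var > 1e-12:
        m = float(np.sum(w * (x - xm) * (g - gm)) / sw) / var
        m = min(max(m, min_scale), max_scale)  # boundary optimum on the box
        candidates.append((m, gm - m * xm))
    return min(candidates, key=lambda mt: cost(*mt))


def _constrained_consensus(
    ybar: np.ndarray, Wk: np.ndarray, centroid: np.ndarray, s_star: float
) -> np.ndarray:
    """Exact solution of min sum_k W_k ||g_k - ybar_k||^2 under both constraints.

    With h_k = g_k - centroid, stationarity gives
    ``h_k = (W_k a_k - mu) / (W_k + lam)`` where ``a_k = ybar_k - centroid``
    and ``mu`` enforces the zero-mean constraint; ``lam`` solves the
    secular equation matching the size constraint.
    """
    K = len(Wk)
    if s_star <= 0:
        return np.tile(centroid, (K, 1))
    a = ybar - centroid

    def h_of(lam: float) -> np.ndarray:
        denom = Wk + lam
        mu = (Wk[:, None] * a / denom[:, None]).sum(axis=0) / (1.0 / denom).sum()
        return (Wk[:, None] * a - mu[None, :]) / denom[:, None]

    def phi(lam: float) -> float:
        h = h_of(lam)
        return float((h**2).sum() / K) - s_star

    lam_min = -float(Wk.min())
    h = None
    eps = 1e-6 * max(float(Wk.max()), 1.0)
    lo = lam_min + eps
    # as lam -> lam_min+ the smallest-weight term blows up, so phi(lo) > 0
    # generically; shrink eps if the bracket does not open
    for _ in range(12):
        if phi(lo) > 0:
            break
        eps *= 0.1
        lo = lam_min + eps
    else:
        lo = None
    if lo is not None:
        hi = max(1.0, float(Wk.max()))
        for _ in range(80):
            if phi(hi) < 0:
                break
            hi *= 4.0
        else:
            hi = None
        if hi is not None:
            lam = brentq(phi, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
            h = h_of(lam)
    if h is None:  # hard case; fall back to centring + isotropic rescale
        h = a - a.mean(axis=0)
        norm = float((h**2).sum() / K)
        h = h * np.sqrt(s_star / norm) if norm > 0 else h
    # exact projection onto both constraints to kill residual float error
    h = h - h.mean(axis=0)
    norm = float((h**2).sum() / K)
    if norm > 0:
        h = h * np.sqrt(s_star / norm)
    return centroid + h


def _fit_transforms(
    Xz: np.ndarray,
    W: np.ndarray,
    g: np.ndarray,
    prev: Optional[List[ScalingTransform]] = None,
    min_scale: float = 0.5,
    max_scale: float = 2.0,
) -> List[ScalingTransform]:
    """Closed-form per-sample transform step against a fixed consensus."""
    n = Xz.shape[0]
    out: List[ScalingTransform] = []
    for i in range(n):
        wi = W[i]
        if prev is not None:
            scale = prev[i].scale.copy()
            trans = prev[i].translation.copy()
        else:
            scale, trans = np.ones(3), np.zeros(3)
        if np.any(wi > 0):
            for d in range(3):
                scale[d], trans[d] = _axis_fit(
                    Xz[i, :, d], g[:, d], wi, (scale[d], trans[d]), min_scale, max_scale
                )
        out.append(ScalingTransform(scale, trans))
    return out


def _polish_transforms(Xz, W, transforms0, centroid, s_star, min_scale=0.5, max_scale=2.0):
    """Gradient-based refinement over the transforms.

    The constrained-optimal consensus for fixed transforms is available
    in closed form (see :func:`_constrained_consensus`), so eliminating
    ``g`` leaves a smooth unconstrained problem in the 6n transform
    parameters whose gradient follows from the envelope theorem.  This
    escapes the shallow zig-zag valley of plain alternation.
    """
    from scipy.optimize import minimize as _minimize

    n = Xz.shape[0]
    Wk = W.sum(axis=0)

    def unpack(theta):
        M = theta[: 3 * n].reshape(n, 3)
        T = theta[3 * n :].reshape(n, 3)
        return M, T

    def fun(theta):
        M, T = unpack(theta)
        Y = Xz * M[:, None, :] + T[:, None, :]
        ybar = np.einsum("ik,ikd->kd", W, Y) / Wk[:, None]
        g = _constrained_consensus(ybar, Wk, centroid, s_star)
        R = Y - g[None, :, :]
        obj = 0.5 * float(np.sum(W[:, :, None] * R**2))
        gM = np.einsum("ik,ikd->id", W, R * Xz)
        gT = np.einsum("ik,ikd->id", W, R)
        return obj, np.concatenate([gM.ravel(), gT.ravel()])

    theta0 = np.concatenate(
        [
            np.stack([t.scale for t in transforms0]).ravel(),
            np.stack([t.translation for t in transforms0]).ravel(),
        ]
    )
    bounds = [(min_scale, max_scale)] * (3 * n) + [(None, None)] * (3 * n)
    res = _minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-12},
    )
    M, T = unpack(res.x)
    return [ScalingTransform(M[i], T[i]) for i in range(n)]


def _solve_single(
    X: np.ndarray,
    W: np.ndarray,
    init_transforms: List[ScalingTransform],
    centroid: np.ndarray,
    s_star: float,
    xbar: np.ndarray,
    tol: float,
    max_iter: int,
    polish: bool,
    min_scale: float = 0.5,
    max_scale: float = 2.0,
):
    """One ALS run (plus optional polish) from a given initialization."""
    n, K, _ = X.shape
    missing = np.isnan(X).any(axis=2)
    Xz = np.where(missing[:, :, None], 0.0, X)
    transforms = list(init_transforms)
    g = xbar.copy()
    trace: List[float] = [wgp_objective(X, W, transforms, g)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (a) per-sample, per-axis closed-form transform update
        transforms = _fit_transforms(Xz, W, g, transforms, min_scale, max_scale)
        # (b) exact constrained consensus update
        Y = np.stack([transforms[i].apply(Xz[i]) for i in range(n)])
        Wk = W.sum(axis=0)
        ybar = np.einsum("ik,ikd->kd", W, Y) / Wk[:, None]
        g = _constrained_consensus(ybar, Wk, centroid, s_star)

        obj = wgp_objective(X, W, transforms, g)
        if not np.isfinite(obj):
            raise FloatingPointError("non-finite Procrustes objective")
        prev = trace[-1]
        trace.append(obj)
        if prev - obj < -1e-9 * max(prev, 1.0):  # pragma: no cover - by construction
            raise AssertionError("ALS objective increased")
        if prev - obj <= tol * max(prev, 1.0):
            converged = True
            break
    if polish:
        transforms_p = _polish_transforms(Xz, W, transforms, centroid, s_star, min_scale, max_scale)
        Y = np.stack([t.apply(Xz[i]) for i, t in enumerate(transforms_p)])
        Wk = W.sum(axis=0)
        ybar = np.einsum("ik,ikd->kd", W, Y) / Wk[:, None]
        g_p = _constrained_consensus(ybar, Wk, centroid, s_star)
        obj_p = wgp_objective(X, W, transforms_p, g_p)
        if obj_p <= trace[-1]:
            g, transforms = g_p, transforms_p
            trace.append(obj_p)
            converged = True
    return transforms, g, trace, it, converged


def solve_wgp(
    landmarks: Sequence[LandmarkSet] | np.ndarray,
    weights: np.ndarray,
    landmark_ids: Optional[Sequence[str]] = None,
    tol: float = 1e-10,
    max_iter: int = 200,
    n_starts: int = 12,
    polish: bool = True,
    seed: int = 0,
    min_scale: float = 0.5,
    max_scale: float = 2.0,
) -> WGPResult:
    """Weighted generalized Procrustes via multi-start ALS with polish.

    Parameters
    ----------
    landmarks
        Either a sequence of :class:`LandmarkSet` (with ``landmark_ids``
        giving the column order) or an (n, K, 3) array with NaN marking
        missing landmarks.
    weights
        Non-negative (n, K) weight matrix; zero marks a missing or
        temporally excluded landmark.  Every column must have at least
        one positive entry.
    n_starts
        The first start uses identity transforms; further starts perturb
        the initial transforms deterministically (seeded) to escape the
        shallow valleys the alternating scheme can stall in.
    polish
        After ALS, refine the transforms with a gradient-based solver
        (the constrained-optimal consensus is eliminated in closed form).
    min_scale, max_scale
        Box bounds on every scale component, covering plausible relative
        anatomical scaling; they rule out degenerate partial collapse of
        the configuration along an axis.
    """
    if isinstance(landmarks, np.ndarray):
        X = np.asarray(landmarks, dtype=float)
        ids = list(landmark_ids) if landmark_ids is not None else [
            f"lmk{k}" for k in range(X.shape[1])
        ]
    else:
        if landmark_ids is None:
            raise ValueError("landmark_ids required with LandmarkSet inputs")
        ids = list(landmark_ids)
        X = landmark_array(landmarks, ids)
    W = np.asarray(weights, dtype=float)
    n, K, _ = X.shape
    if W.shape != (n, K):
        raise ValueError("weight matrix shape mismatch")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    missing = np.isnan(X).any(axis=2)
    if np.any((W > 0) & missing):
        raise ValueError("positive weight on a missing landmark")
    if np.any(W.sum(axis=0) <= 0):
        raise ValueError("a landmark carries no positive weight in any sample")

    xbar = _weighted_landmark_means(X, W)
    centroid = xbar.mean(axis=0)
    s_star = float(((xbar - centroid) ** 2).sum() / K)

    rng = np.random.default_rng(seed)
    spread = float(np.sqrt(max(s_star, 1e-12)))
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            init = [ScalingTransform.identity() for _ in range(n)]
        elif start % 2 == 1:
            # local starts around the identity
            init = [
                ScalingTransform(
                    np.clip(np.exp(rng.normal(0.0, 0.25, 3)), min_scale, max_scale),
                    rng.normal(0.0, 0.5 * spread, 3),
                )
                for _ in range(n)
            ]
        else:
            # wide starts spanning the whole scale box
            init = [
                ScalingTransform(
                    np.exp(rng.uniform(np.log(min_scale), np.log(max_scale), 3)),
                    rng.normal(0.0, spread, 3),
                )
                for _ in range(n)
            ]
        transforms, g, trace, it, conv = _solve_single(
            X, W, init, centroid, s_star, xbar, tol, max_iter, polish, min_scale, max_scale
        )
        if best is None or trace[-1] < best[2][-1] - 1e-12 * max(1.0, best[2][-1]):
            best = (transforms, g, trace, it, conv)
    transforms, g, trace, it, converged = best

    gc = g.mean(axis=0)
    bary_res = float(np.linalg.norm(gc - centroid))
    size = float(((g - gc) ** 2).sum() / K)
    size_res = abs(size - s_star) / max(s_star, 1e-300) if s_star > 0 else 0.0
    return WGPResult(
        transforms=transforms,
        consensus=g,
        landmark_ids=ids,
        objective=trace[-1],
        objective_trace=trace,
        iterations=it,
        converged=converged,
        barycenter_residual=bary_res,
        size_residual=size_res,
    )
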