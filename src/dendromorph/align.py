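"""Population and per-dendrite alignment to a retinotopic frame, and scaling.

The dendrite populations live on a curved neuropil layer well approximated by
a spherical cap.  Global alignment (i) moves the origin to the centre of a
least-squares sphere fit, (ii) rotates the pooled principal axes so PC1 lies
on the polar (dorsal-ventral, y) axis and PC2 on the equatorial
(anterior-posterior, x) axis, and (iii) disambiguates the four remaining
half-turn symmetries with dorsal/anterior anchor landmarks, so dorsal maps to
y > 0 and anterior to x > 0.

Per-dendrite alignment uses a Huber-weighted robust covariance (a single long
outreaching section should not swing the eigenvectors), rotates into the
eigenbasis with each eigenvector flipped towards its positive target axis
(minimal rotation), and centres on the dendrite root.

Two scaling schemes: a population-level isotropic scale 1/(mu + 3*sigma) of
the leading eigenvalue statistics, and per-dendrite unit-variance scaling
1/sqrt(var) along each eigen-axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.stats import chi2

from .trees import NeuronTree

__all__ = [
    "SphereFit",
    "AlignmentFrame",
    "fit_sphere",
    "robust_covariance",
    "align_dendrite",
    "align_population",
    "scale_dendrite",
    "variance_explained",
    "pc1_axis_angle",
    "pc1_axis_angle_signed",
]

#: default Huber tuning constant (95% efficiency at the Gaussian)
HUBER_C = 1.345

_AXES = np.eye(3)
# target basis vector per principal component: PC1 -> y, PC2 -> x, PC3 -> z
_TARGET_FOR_PC = (1, 0, 2)


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


@dataclass
class AlignmentFrame:
    """Rigid rotation + translation with the eigen-structure that produced it."""

    rotation: np.ndarray
    translation: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, ordered by descending eigenvalue
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) @ self.rotation.T


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Algebraic least-squares sphere fit (linear in centre and radius)."""
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 4:
        raise ValueError("need at least 4 points for a sphere fit")
    A = np.column_stack([2 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate sphere fit (coplanar or collinear points)")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate sphere fit (non-positive radius)")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(p - center, axis=1) - radius
    return SphereFit(center, radius, float(np.sqrt(np.mean(resid**2))))


@lru_cache(maxsize=None)
def _huber_consistency(c: float, dim: int) -> float:
    """Gaussian consistency factor for the Huber-weighted scatter.

    The weighted estimate converges to Sigma * E[w r^2] / (dim * E[w]) at
    the normal model; dividing by this factor makes it unbiased there.
    """
    r_med = np.sqrt(chi2.ppf(0.5, df=dim))

    def w2(q):  # q = squared Mahalanobis radius; scatter uses squared weights
        return np.minimum(1.0, c * r_med / np.sqrt(q)) ** 2

    num = quad(lambda q: w2(q) * q * chi2.pdf(q, dim), 0, np.inf)[0]
    den = quad(lambda q: w2(q) * chi2.pdf(q, dim), 0, np.inf)[0]
    return num / (dim * den)


def robust_covariance(
    points: np.ndarray, c: float = HUBER_C, tol: float = 1e-8, max_iter: int = 100
):
    """Huber-type M-estimate of location and covariance.

    Weights ``w(r) = min(1, c/r)`` on Mahalanobis radii normalized so the
    median radius is ~1 under normality; iterated to convergence.  The
    location uses ``w`` and the scatter ``w**2`` (the standard Huber
    M-scatter, whose per-point influence on the covariance is bounded by
    ``c**2``), with a Gaussian consistency correction so clean data
    reproduce the classical estimate.  Returns ``(mean, covariance)``;
    falls back to the classical estimate with a warning when the weighted
    covariance goes rank-deficient.
    """
    p = np.asarray(points, dtype=float)
    if p.shape[0] < 4:
        raise ValueError("need at least 4 points")
    dim = p.shape[1]
    mean = p.mean(axis=0)
    cov = np.cov(p.T)
    r_med = np.sqrt(chi2.ppf(0.5, df=dim))
    w = np.ones(len(p))
    for _ in range(max_iter):
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient weighted covariance; classical fallback")
            return p.mean(axis=0), np.cov(p.T)
        d = p - mean
        r = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", d, inv, d), 0.0)) / r_med
        w_new = np.minimum(1.0, c / np.maximum(r, 1e-300))
        mean = (w_new[:, None] * p).sum(axis=0) / w_new.sum()
        d = p - mean
        w2 = w_new**2
        cov = (w2[:, None] * d).T @ d / w2.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    if np.linalg.matrix_rank(cov) < dim:
        warnings.warn("rank-deficient weighted covariance; classical fallback")
        return p.mean(axis=0), np.cov(p.T)
    return mean, cov / _huber_consistency(c, dim)


def _eig_descending(cov: np.ndarray):
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return np.maximum(vals[order], 0.0), vecs[:, order]


def _rotation_from_eigvecs(vecs: np.ndarray) -> np.ndarray:
    """Proper rotation sending PC1 -> y, PC2 -> x, PC3 -> z.

    Each eigenvector is first flipped towards its positive target basis
    vector (minimal rotation); if that leaves an improper basis the
    least-aligned eigenvector is flipped back to restore det = +1.
    """
    v = vecs.copy()
    dots = np.empty(3)
    for pc in range(3):
        dots[pc] = v[:, pc] @ _AXES[_TARGET_FOR_PC[pc]]
        if dots[pc] < 0:
            v[:, pc] = -v[:, pc]
            dots[pc] = -dots[pc]
    R = np.zeros((3, 3))
    for pc in range(3):
        R[_TARGET_FOR_PC[pc], :] = v[:, pc]
    if np.linalg.det(R) < 0:
        pc = int(np.argmin(np.abs(dots)))
        R[_TARGET_FOR_PC[pc], :] = -R[_TARGET_FOR_PC[pc], :]
    return R


def align_dendrite(
    dendrite: NeuronTree, huber_c: float = HUBER_C, robust: bool = True
):
    """Rotate a dendrite into its (robust) eigenbasis, centred on its root.

    Returns ``(aligned_tree, AlignmentFrame)``.  After alignment the major
    axis of the point cloud lies along y, the second along x and the third
    (layer depth) along z.
    """
    ids, pts = dendrite.coords()
    if len(ids) < 4:
        raise ValueError("need at least 4 nodes to align")
    if robust:
        _, cov = robust_covariance(pts, c=huber_c)
    else:
        cov = np.cov(pts.T)
    vals, vecs = _eig_descending(cov)
    if vals[1] <= 0:
        raise ValueError("degenerate covariance (collinear nodes)")
    R = _rotation_from_eigvecs(vecs)
    frame = AlignmentFrame(R, dendrite.pos(dendrite.root).copy(), vals, vecs)
    out = dendrite.copy()
    for v, p in zip(ids, frame.apply(pts)):
        out.graph.nodes[v]["pos"] = p
    return NeuronTree(out.graph, out.root, validate=False), frame


def align_population(points_by_dendrite: dict, anchors: dict):
    """Global rigid alignment of a dendrite population to the DV/AP frame.

    Parameters
    ----------
    points_by_dendrite
        Mapping dendrite id -> (n_i, 3) node coordinate array.
    anchors
        ``{"dorsal": p, "ventral": p, "anterior": p, "posterior": p}`` in the
        same frame as the points.

    Returns ``(aligned_points_by_dendrite, AlignmentFrame)`` where the frame's
    ``apply`` maps any raw point into the aligned DV/AP space.
    """
    pooled = np.vstack(list(points_by_dendrite.values()))
    sphere = fit_sphere(pooled)
    centred = pooled - sphere.center
    vals, vecs = _eig_descending(np.cov(centred.T))
    R = _rotation_from_eigvecs(vecs)

    half_turns = [np.eye(3)]
    for ax in range(3):
        D = -np.eye(3)
        D[ax, ax] = 1.0
        half_turns.append(D)
    dorsal = np.asarray(anchors["dorsal"], dtype=float) - sphere.center
    anterior = np.asarray(anchors["anterior"], dtype=float) - sphere.center
    chosen = None
    for H in half_turns:
        d, a = H @ R @ dorsal, H @ R @ anterior
        if d[1] > 0 and a[0] > 0:
            chosen = H
            break
    if chosen is None:
        raise ValueError(
            "anchors colinear with origin: cannot disambiguate DV/AP signs"
        )
    frame = AlignmentFrame(chosen @ R, sphere.center, vals, vecs)
    aligned = {k: frame.apply(v) for k, v in points_by_dendrite.items()}
    return aligned, frame


def scale_dendrite(
    dendrite: NeuronTree, mode: str, population_stats: dict | None = None
) -> NeuronTree:
    """Scale an aligned dendrite's coordinates about its root.

    ``mode="population_sd"`` applies the isotropic factor ``1/(mu + 3*sigma)``
    from the type-specific population statistics of the leading eigenvalue
    (``population_stats = {"mu": ..., "sigma": ...}``).  ``mode="unit_variance"``
    scales each axis by ``1/sqrt(var)`` so the cloud has unit variance along
    every axis; topology is untouched.
    """
    ids, pts = dendrite.coords()
    origin = dendrite.pos(dendrite.root)
    rel = pts - origin
    if mode == "population_sd":
        if population_stats is None:
            raise ValueError("population_sd mode needs {'mu', 'sigma'}")
        s = 1.0 / (population_stats["mu"] + 3.0 * population_stats["sigma"])
        scaled = rel * s
    elif mode == "unit_variance":
        var = rel.var(axis=0)
        if np.any(var <= 0):
            raise ValueError("zero variance along an axis; cannot unit-scale")
        scaled = rel / np.sqrt(var)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    out = dendrite.copy()
    for v, p in zip(ids, scaled):
        out.graph.nodes[v]["pos"] = p
    return NeuronTree(out.graph, out.root, validate=False)


def variance_explained(frame: AlignmentFrame) -> np.ndarray:
    """Fraction of variance per principal component, non-increasing, sums to 1."""
    total = frame.eigenvalues.sum()
    if total <= 0:
        raise ValueError("all eigenvalues zero")
    return frame.eigenvalues / total


def pc1_axis_angle(frame: AlignmentFrame, axis=(0.0, 1.0, 0.0)) -> float:
    """Acute angle (degrees, in [0, 90]) between PC1 and a reference axis.

    Eigenvector sign is arbitrary, so the angle is reported for the axis,
    not the direction.
    """
    v = frame.eigenvectors[:, 0]
    a = np.asarray(axis, dtype=float)
    cosang = abs(v @ a) / (np.linalg.norm(v) * np.linalg.norm(a))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def pc1_axis_angle_signed(frame: AlignmentFrame) -> float:
    """Signed in-plane angle (degrees, (-90, 90]) between PC1 and the DV axis.

    Measured in the aligned x-y (AP-DV) plane as an axial quantity: positive
    when PC1 leans toward +AP.  Symmetric dendrite populations centre this
    distribution on zero.
    """
    v = frame.eigenvectors[:2, 0]
    ang = np.degrees(np.arctan2(v[0], v[1]))  # 0 along +DV
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)
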