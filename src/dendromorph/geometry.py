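"""Section and bifurcation geometry: signed planar angles, circular
statistics, radial section angles, bifurcation angular components and the
dihedral planarity measure, plus the random-bifurcation null model.

Angles between 3-D vectors are measured in the plane orthogonal to a normal
``n`` by rejecting each vector from ``n`` and taking the ``atan2`` of signed
sine and cosine, giving a signed angle in (-pi, pi].

A bifurcation is the local geometry within ``delta`` (default 0.1 µm) of a
branch node of out-degree 2: a parent unit vector pointing *up-stream* (from
the branch node back toward the root) and two child unit vectors pointing
down each child branch.  Its angular components are gamma and omega (parent
to either child) and theta (child to child), all unsigned in [0, pi].  With
the up-stream parent convention an exactly planar, outward-opening
bifurcation has gamma + omega + theta = 2*pi.  The dihedral angle beta in
[0, pi] measures flatness: pi for a planar bifurcation whose children open
away from the parent, 0 when they fold back onto it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import NeuronTree

__all__ = [
    "PlanarAngle",
    "CircularSummary",
    "Bifurcation",
    "signed_angle",
    "circular_stats",
    "radial_angle",
    "section_radial_angles",
    "extract_bifurcations",
    "dihedral",
    "null_bifurcations",
]

BIFURCATION_DELTA = 0.1  # µm of cable around the branch node


@dataclass
class PlanarAngle:
    v1: np.ndarray
    v2: np.ndarray
    n_hat: np.ndarray
    theta: float


@dataclass
class CircularSummary:
    mean_angle: float  # nan when the resultant vanishes
    sum_cos: float
    sum_sin: float
    variance_stat: float  # squared resultant length (Sum cos)^2 + (Sum sin)^2
    circular_variance: float  # normalized, 1 - R/n
    n: int


@dataclass
class Bifurcation:
    node: object
    parent_dir: np.ndarray
    child1_dir: np.ndarray
    child2_dir: np.ndarray
    gamma: float
    omega: float
    theta: float
    angle_sum: float
    dihedral_beta: float


def _unit(v):
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero vector")
    return v / norm


def _reject(v, n_hat):
    return v - (v @ n_hat) * n_hat


def signed_angle(v1, v2, n) -> PlanarAngle:
    """Signed angle from v1 to v2 in the plane orthogonal to n, in (-pi, pi]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n_hat = _unit(n)
    r1, r2 = _reject(v1, n_hat), _reject(v2, n_hat)
    if np.linalg.norm(r1) < 1e-12 * max(np.linalg.norm(v1), 1.0) or np.linalg.norm(
        r2
    ) < 1e-12 * max(np.linalg.norm(v2), 1.0):
        raise ValueError("vector parallel to the plane normal: undefined in-plane direction")
    theta = float(np.arctan2(np.cross(r1, r2) @ n_hat, r1 @ r2))
    if theta <= -np.pi:
        theta = np.pi
    return PlanarAngle(v1, v2, n_hat, theta)


def circular_stats(angles) -> CircularSummary:
    """Circular mean and resultant-based dispersion of a set of angles."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    sc, ss = float(np.cos(a).sum()), float(np.sin(a).sum())
    res = np.hypot(sc, ss)
    mean = float(np.arctan2(ss, sc)) if res > 1e-12 * a.size else float("nan")
    return CircularSummary(
        mean_angle=mean,
        sum_cos=sc,
        sum_sin=ss,
        variance_stat=sc**2 + ss**2,
        circular_variance=1.0 - res / a.size,
        n=int(a.size),
    )


def unsigned_angle(v1, v2) -> float:
    """Unsigned 3-D angle in [0, pi] via a clamped dot product."""
    c = _unit(v1) @ _unit(v2)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def radial_angle(source, target, root, plane_normal) -> float:
    """Signed angle between a section and the ray cast from the dendrite root.

    Zero means the section (source -> target) continues straight along the
    root -> source ray.  Sections whose source *is* the root are excluded by
    construction (the ray is undefined there).
    """
    source = np.asarray(source, dtype=float)
    ray = source - np.asarray(root, dtype=float)
    if np.linalg.norm(ray) == 0:
        raise ValueError("section sourced at the root is excluded")
    sec = np.asarray(target, dtype=float) - source
    return signed_angle(ray, sec, plane_normal).theta


def section_radial_angles(reduced, plane_normal=(0.0, 0.0, 1.0)) -> "list":
    """Radial angle and kind for every section not sourced at the root.

    ``plane_normal`` must be oriented consistently across dendrites (e.g. the
    global depth axis) so that signs are comparable.
    """
    root_p = reduced.pos(reduced.root)
    out = []
    for u, v in reduced.edges:
        if u == reduced.root:
            continue
        try:
            th = radial_angle(reduced.pos(u), reduced.pos(v), root_p, plane_normal)
        except ValueError:
            continue
        out.append({"source": u, "target": v, "kind": reduced.section_kind(u, v),
                    "radial_angle": th})
    return out


def dihedral(parent_dir, c1, c2) -> float:
    """Dihedral angle beta in [0, pi] of a bifurcation.

    The children's bisector b is compared with the (up-stream) parent
    direction in the plane with normal (c1 x c2) x b.  Returns nan when the
    bisector is degenerate (children antiparallel).
    """
    u1, u2 = _unit(c1), _unit(c2)
    bs = u1 + u2
    if np.linalg.norm(bs) < 1e-12:
        return float("nan")
    b = bs / np.linalg.norm(bs)
    n = np.cross(np.cross(u1, u2), b)
    if np.linalg.norm(n) < 1e-12:
        # children parallel: everything coplanar with the parent
        return unsigned_angle(b, parent_dir)
    return abs(signed_angle(b, parent_dir, n).theta)


def _walk_point(tree: NeuronTree, node, next_fn, delta: float, truncate: bool):
    """Point ``delta`` µm of cable from ``node`` along a chain given by next_fn.

    When the chain ends before ``delta``: return the last reachable point if
    ``truncate`` (child side, ending at a nearby leaf/branch) else None
    (parent side, meaning the root lies within ``delta`` of cable).
    """
    travelled = 0.0
    cur = node
    while True:
        nxt = next_fn(cur)
        if nxt is None:
            if truncate and travelled > 0:
                return tree.pos(cur)
            return None
        p0, p1 = tree.pos(cur), tree.pos(nxt)
        seg = float(np.linalg.norm(p1 - p0))
        if travelled + seg >= delta and seg > 0:
            frac = (delta - travelled) / seg
            return p0 + frac * (p1 - p0)
        travelled += seg
        cur = nxt


def extract_bifurcations(
    tree: NeuronTree, delta: float = BIFURCATION_DELTA
) -> tuple[list[Bifurcation], int]:
    """Local bifurcation geometry at every out-degree-2 branch node.

    ``tree`` should be the full (0.1 µm resampled) skeleton.  Branch nodes
    closer than ``delta`` of cable to the root are skipped; the skipped count
    is returned alongside.  Trifurcations and higher are not extracted.
    """
    bifs: list[Bifurcation] = []
    skipped = 0
    for node in tree.branch_nodes():
        if tree.out_degree(node) != 2:
            continue
        p_pt = _walk_point(tree, node, tree.parent, delta, truncate=False)
        if p_pt is None:
            skipped += 1
            continue

        def _down(start):
            def nxt(v):
                if v == node:
                    return start
                kids = tree.children(v)
                return kids[0] if len(kids) == 1 else None
            return nxt

        ch = tree.children(node)
        c_pts = [
            _walk_point(tree, node, _down(c), delta, truncate=True) for c in ch
        ]
        if any(c is None for c in c_pts):
            skipped += 1
            continue
        origin = tree.pos(node)
        try:
            pd_ = _unit(p_pt - origin)
            c1 = _unit(c_pts[0] - origin)
            c2 = _unit(c_pts[1] - origin)
        except ValueError:
            skipped += 1
            continue
        gamma = unsigned_angle(pd_, c1)
        omega = unsigned_angle(pd_, c2)
        theta = unsigned_angle(c1, c2)
        bifs.append(
            Bifurcation(
                node=node,
                parent_dir=pd_,
                child1_dir=c1,
                child2_dir=c2,
                gamma=gamma,
                omega=omega,
                theta=theta,
                angle_sum=gamma + omega + theta,
                dihedral_beta=dihedral(pd_, c1, c2),
            )
        )
    return bifs, skipped


def null_bifurcations(
    count: int = 1_000_000,
    z_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
    pc3_fraction: float | None = None,
    return_vectors: bool = False,
):
    """Random-bifurcation null model.

    Draws ``count`` triples of uniform unit vectors, resampling until the
    parent has a negative x component and both children positive x components
    (an outward-opening branch).  To mimic the natural flatness of the
    dendrites' occupied space, z components are multiplied by
    ``pc3_fraction ** (1/3)`` (the cube root of the mean variance explained
    by the third principal component) when given, else by ``z_scale``;
    vectors are then renormalized.

    Returns a dict of arrays: gamma, omega, theta, angle_sum, beta (radians).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pc3_fraction is not None:
        z_scale = float(pc3_fraction) ** (1.0 / 3.0)

    def _draw(n, sign):
        out = np.empty((0, 3))
        while len(out) < n:
            v = rng.normal(size=(int(1.3 * (n - len(out))) + 16, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            v = v[np.sign(v[:, 0]) == sign]
            out = np.vstack([out, v])
        return out[:n]

    p = _draw(count, -1.0)
    c1 = _draw(count, 1.0)
    c2 = _draw(count, 1.0)
    for arr in (p, c1, c2):
        arr[:, 2] *= z_scale
        arr /= np.linalg.norm(arr, axis=1, keepdims=True)

    def _ang(a, b):
        return np.arccos(np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0))

    gamma, omega, theta = _ang(p, c1), _ang(p, c2), _ang(c1, c2)
    # vectorized dihedral
    bsum = c1 + c2
    bnorm = np.linalg.norm(bsum, axis=1, keepdims=True)
    b = bsum / np.where(bnorm > 1e-12, bnorm, 1.0)
    n = np.cross(np.cross(c1, c2), b)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    n_hat = n / np.where(nn > 1e-12, nn, 1.0)
    proj_b = b - np.einsum("ij,ij->i", b, n_hat)[:, None] * n_hat
    proj_p = p - np.einsum("ij,ij->i", p, n_hat)[:, None] * n_hat
    beta = np.abs(
        np.arctan2(
            np.einsum("ij,ij->i", np.cross(proj_b, proj_p), n_hat),
            np.einsum("ij,ij->i", proj_b, proj_p),
        )
    )
    degenerate = (bnorm[:, 0] <= 1e-12) | (nn[:, 0] <= 1e-12)
    beta = np.where(degenerate, _ang(b, p), beta)
    out = {
        "gamma": gamma,
        "omega": omega,
        "theta": theta,
        "angle_sum": gamma + omega + theta,
        "beta": beta,
    }
    if return_vectors:
        out.update(parent=p, child1=c1, child2=c2)
    return out
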