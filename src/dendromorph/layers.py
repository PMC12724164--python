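"""Neuropil-layer surfaces, convex-hull volumes and normalized layer depth.

A layer (Medulla M10 for T4, Lobula L1 for T5) is reconstructed from the
pooled node coordinates of all same-type dendrites: voxelize at 2 µm, dilate
twice to close gaps, keep the largest 26-connected component, run marching
cubes, clean the mesh and smooth it.  Faces are split into an *inner* and an
*outer* surface by the dot product of their outward normal with the ray from
the coordinate origin (the fitted sphere centre): >= 0.3 outer, <= -0.3
inner, in-between tangential faces unclassified.

The normalized depth of a point between the two surfaces is

    d_norm = d_inner / (d_inner + d_outer)        (T4)
    d_norm = 1 - d_inner / (d_inner + d_outer)    (T5)

with the T5 inversion because T5 dendrites innervate their layer from the
opposite side of curvature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull, cKDTree
from skimage import measure

from .trees import NeuronTree

__all__ = [
    "LayerSurface",
    "DepthResult",
    "hull_volume",
    "reconstruct_layer",
    "classify_faces",
    "depth",
    "depth_vs_root_distance",
]

FACE_DOT_THRESHOLD = 0.3


@dataclass
class LayerSurface:
    mesh: trimesh.Trimesh
    voxel_size: float
    inner_faces: np.ndarray | None = None
    outer_faces: np.ndarray | None = None

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))


@dataclass
class DepthResult:
    d_inner: float
    d_outer: float
    d_norm: float
    side: str


def hull_volume(dendrite, reference_volume: float | None = None) -> float:
    """Convex-hull volume of a dendrite's nodes, µm³.

    With ``reference_volume`` the result is the dimensionless fraction of the
    layer-mesh volume (used to compare T4 and T5 across neuropils of
    different size).
    """
    pts = dendrite.coords()[1] if isinstance(dendrite, NeuronTree) else np.asarray(dendrite)
    try:
        vol = ConvexHull(pts).volume
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"coplanar or degenerate node cloud: {exc}") from exc
    if reference_volume is not None:
        return float(vol / reference_volume)
    return float(vol)


def reconstruct_layer(
    points: np.ndarray,
    voxel: float = 2.0,
    dilate: int = 2,
    pad: float = 2.0,
    smooth_iterations: int = 20,
    band: float = 0.01,
) -> LayerSurface:
    """Voxel/marching-cubes reconstruction of a layer surface from points.

    Pipeline: pad the bounding box by ``pad`` µm, occupy ``voxel``-µm voxels,
    ``dilate`` iterations of morphological dilation (full 26-neighbourhood
    structuring element), keep the largest connected component, marching
    cubes, drop unreferenced vertices and degenerate faces, fill holes, fix
    normals outward, then band-pass (Taubin) smooth with pass-band ``band``.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point set")
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 1)
    idx = np.floor((pts - lo) / voxel).astype(int)
    idx = np.clip(idx, 0, shape - 1)
    grid = np.zeros(shape, dtype=bool)
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if not grid.any():
        raise ValueError("empty voxel grid")
    structure = np.ones((3, 3, 3), dtype=bool)
    # headroom so dilation never clips at the array boundary (erosion with a
    # zero border would otherwise eat the layer back asymmetrically)
    grid = np.pad(grid, dilate)
    lo = lo - dilate * voxel
    for _ in range(dilate):
        grid = ndimage.binary_dilation(grid, structure=structure)
    labels, n_comp = ndimage.label(grid, structure=structure)
    if n_comp > 1:
        sizes = ndimage.sum(grid, labels, range(1, n_comp + 1))
        grid = labels == (1 + int(np.argmax(sizes)))
    # matching erosion (closing): gap filling must not thicken the layer,
    # otherwise every reconstructed volume inflates by ~dilate voxels per side
    for _ in range(dilate):
        grid = ndimage.binary_erosion(grid, structure=structure)
    if not grid.any():
        raise ValueError("empty voxel grid after closing")
    padded = np.pad(grid, 1)  # closed isosurface at the boundary
    verts, faces, _, _ = measure.marching_cubes(padded.astype(float), level=0.5)
    verts = (verts - 1) * voxel + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    trimesh.repair.fill_holes(mesh)
    trimesh.repair.fix_normals(mesh)
    if smooth_iterations > 0:
        # Taubin band-pass smoothing: pass-band k = 1/lamb + 1/mu = band
        lamb = 0.5
        mu = 1.0 / (band - 1.0 / lamb)  # negative, |mu| > lamb
        trimesh.smoothing.filter_taubin(
            mesh, lamb=lamb, nu=-mu, iterations=smooth_iterations
        )
    if mesh.volume < 0:
        mesh.invert()
    return LayerSurface(mesh=mesh, voxel_size=voxel)


def classify_faces(
    surface: LayerSurface,
    origin,
    threshold: float = FACE_DOT_THRESHOLD,
) -> LayerSurface:
    """Partition faces into inner/outer by normal-vs-origin-ray dot product.

    ``origin`` is the population sphere-fit centre.  Faces with
    ``dot(normal, unit(centroid - origin)) >= threshold`` are outer,
    ``<= -threshold`` inner; tangential faces stay unclassified and are
    excluded from the depth nearest-neighbour structures.
    """
    mesh = surface.mesh
    rays = mesh.triangles_center - np.asarray(origin, dtype=float)
    rays /= np.linalg.norm(rays, axis=1, keepdims=True)
    dots = np.einsum("ij,ij->i", mesh.face_normals, rays)
    outer = np.where(dots >= threshold)[0]
    inner = np.where(dots <= -threshold)[0]
    if len(outer) == 0 or len(inner) == 0:
        raise ValueError("layer not two-sided from this origin")
    return LayerSurface(
        mesh=mesh,
        voxel_size=surface.voxel_size,
        inner_faces=inner,
        outer_faces=outer,
    )


class _DepthIndex:
    """KD-trees over inner/outer face centroids of a classified surface."""

    def __init__(self, surface: LayerSurface):
        if surface.inner_faces is None or surface.outer_faces is None:
            raise ValueError("surface faces not classified; call classify_faces first")
        centers = surface.mesh.triangles_center
        self.inner = cKDTree(centers[surface.inner_faces])
        self.outer = cKDTree(centers[surface.outer_faces])


def depth(point, surface: LayerSurface, side: str, _index=None) -> DepthResult:
    """Normalized layer depth of a point, with the T5 inversion."""
    if side not in ("T4", "T5"):
        raise ValueError("side must be 'T4' or 'T5'")
    index = _index or _DepthIndex(surface)
    d_inner = float(index.inner.query(point)[0])
    d_outer = float(index.outer.query(point)[0])
    frac = d_inner / (d_inner + d_outer)
    d_norm = frac if side == "T4" else 1.0 - frac
    return DepthResult(d_inner, d_outer, d_norm, side)


def depth_vs_root_distance(
    dendrite: NeuronTree, surface: LayerSurface, side: str
) -> np.ndarray:
    """Per-node (normalized root distance, d_norm) pairs for the tilt analysis.

    x is the Euclidean distance from the dendrite root normalized by the
    per-dendrite maximum; the root (x = 0) and the furthest point (x = 1)
    are excluded, so all retained x lie in the open interval (0, 1).
    """
    ids, pts = dendrite.coords()
    root_p = dendrite.pos(dendrite.root)
    dists = np.linalg.norm(pts - root_p, axis=1)
    dmax = dists.max()
    if dmax <= 0:
        return np.empty((0, 2))
    index = _DepthIndex(surface)
    out = []
    for nid, p, d in zip(ids, pts, dists):
        x = d / dmax
        if x <= 0.0 or x >= 1.0:
            continue
        out.append((x, depth(p, surface, side, _index=index).d_norm))
    return np.array(out) if out else np.empty((0, 2))
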