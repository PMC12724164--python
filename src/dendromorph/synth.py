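"""Seeded generator of synthetic T4/T5-like dendrite populations.

The generator emulates the statistical structure of the real optic-lobe
populations so every analysis stage is testable without connectome access:

* a hexagonal column lattice projected onto a spherical cap (azimuthal
  equidistant projection), elongated along the polar dorsal-ventral axis so
  the population PC1 is DV, PC2 anterior-posterior, PC3 depth;
* four dendrites per column, one per subtype, with subtype headings
  a: +AP, b: -AP, c: +DV, d: -DV (angular jitter configurable) and
  opposite-subtype roots co-located within the column (a-b and c-d pairs sit
  closer than any other relation);
* each dendrite grown as a stochastic tip-branching tree inside an
  elliptical envelope elongated along DV, with the root off-centre opposite
  the heading; inter-branch (internal) section lengths drawn from a
  configurable right-skewed family (gamma by default, minimum-Weibull for
  raw-length emulation) and terminal (external) sections log-normal;
* near-planar bifurcations whose angular components sum to ~2*pi, with a
  configurable out-of-plane noise and a rare trifurcation rate;
* a slight depth tilt: points further from the root sit deeper in the layer.

This is a statistical emulation, not a biophysical growth model: only the
signatures the analysis measures are planted.  Every planted parameter is
recorded in the truth record, and the same config and seed reproduce the
population exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import write_swc
from .trees import NeuronTree

__all__ = [
    "GeneratorConfig",
    "Population",
    "generate_population",
    "write_population",
    "truth_check",
]

SUBTYPE_HEADINGS = {"a": 0.0, "b": np.pi, "c": np.pi / 2, "d": -np.pi / 2}
# heading angle in the tangent plane, measured from +AP (x) toward +DV (y)


@dataclass
class GeneratorConfig:
    """Planted population parameters (defaults are the study conditions)."""

    seed: int = 0
    n_columns: int = 61
    types: tuple = ("T4", "T5")
    sphere_radius: float = 200.0  # µm
    column_pitch: float = 5.0  # µm between adjacent columns
    dv_lattice_stretch: float = 1.5  # DV/AP extent ratio of the cap
    # root micro-placement inside a column (µm)
    pair_offset: float = 0.5  # half-distance between opposite-subtype roots
    cluster_offset: float = 2.0  # distance between the a-b and c-d clusters
    # dendritic envelope semi-axes (µm), DV > AP
    envelope_dv: float = 10.0
    envelope_ap: float = 7.0
    envelope_depth: float = 2.0
    anisotropy_jitter: float = 0.15  # lognormal sd of the per-dendrite
    # elongation factor e: DV axis scales by e, AP by 1/e (plants the
    # PC1-PC2 anticorrelation)
    root_offset_frac: float = 0.4  # root offset opposite the heading
    heading_jitter: float = 0.15  # rad, sd of per-dendrite heading
    heading_bias: float = 0.45  # pull of tip directions toward the heading
    # section-length families
    internal_family: str = "gamma"
    internal_params: dict = field(default_factory=lambda: {"k": 2.5, "theta": 0.52})
    internal_scale_by_type: dict = field(
        default_factory=lambda: {"T4": 1.0, "T5": 0.874}
    )  # plants the longer T4 inter-branch interval
    external_family: str = "lognormal"
    external_params: dict = field(default_factory=lambda: {"mu": 0.0, "sigma": 0.5})
    # branching process
    branch_prob: float = 0.8
    max_branch_depth: int = 7
    trifurcation_rate: float = 0.04
    child_angle_mean: float = np.pi / 2  # mean child-child opening
    child_angle_sd: float = 0.25
    planarity_noise: float = 0.08  # rad, out-of-plane sd at bifurcations
    curvature_jitter: float = 0.04  # µm, perpendicular jitter of midpoints
    points_per_um: float = 2.0  # native sampling density along sections
    # layer depth structure
    layer_thickness: float = 4.0  # µm
    root_depth_frac: float = 0.25  # root position between inner/outer surface
    depth_tilt: float = 0.12  # added depth fraction per µm of radial distance

    def validate(self):
        positive = [
            self.sphere_radius, self.column_pitch, self.envelope_dv,
            self.envelope_ap, self.envelope_depth, self.layer_thickness,
            self.points_per_um,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all scales must be > 0")
        for p in (self.branch_prob, self.trifurcation_rate, self.root_depth_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.envelope_dv <= self.envelope_ap:
            raise ValueError("envelope must be elongated along DV (dv > ap)")


@dataclass
class Population:
    dendrites: dict  # neuron_id -> NeuronTree (global coordinates)
    labels: pd.DataFrame  # neuron_id, type, subtype, column
    anchors: dict  # type -> {dorsal, ventral, anterior, posterior}: 3-vectors
    truth: dict  # every planted parameter
    sphere_centers: dict  # type -> 3-vector


# -- lattice ---------------------------------------------------------------


def _hex_lattice(n_columns: int, pitch: float, stretch: float) -> np.ndarray:
    """2-D column centres: hex lattice cropped to a DV-elongated ellipse."""
    rings = 1
    while 1 + 3 * rings * (rings + 1) < 4 * n_columns:
        rings += 1
    pts = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) > rings:
                continue
            x = pitch * (q + r / 2.0)
            y = pitch * (np.sqrt(3) / 2.0) * r
            pts.append((x, y))
    pts = np.array(pts)
    metric = (pts[:, 0] * stretch) ** 2 + pts[:, 1] ** 2
    order = np.lexsort((pts[:, 1], pts[:, 0], metric))
    return pts[order[:n_columns]]


def _cap_frame(center, R, xy):
    """Map tangent-plane coords to a sphere point + local (AP, DV, radial) basis."""
    rho = np.hypot(xy[0], xy[1])
    apex = np.array([0.0, 0.0, 1.0])
    if rho < 1e-12:
        w = apex
    else:
        bearing = np.array([xy[0], xy[1], 0.0]) / rho
        ang = rho / R
        w = np.cos(ang) * apex + np.sin(ang) * bearing
    y_t = np.array([0.0, 1.0, 0.0]) - w[1] * w
    y_t /= np.linalg.norm(y_t)
    x_t = np.cross(y_t, w)
    surface = center + R * w
    return surface, x_t, y_t, w


# -- section-length sampling ----------------------------------------------


def _draw_length(rng, family: str, params: dict, scale: float = 1.0) -> float:
    if family == "gamma":
        v = rng.gamma(params["k"], params["theta"])
    elif family == "weibull_min":
        v = params["lam"] * rng.weibull(params["c"])
    elif family == "lognormal":
        v = rng.lognormal(params["mu"], params["sigma"])
    elif family == "exponential":
        v = rng.exponential(params["theta"])
    else:
        raise ValueError(f"unknown length family {family!r}")
    return max(v * scale, 1e-3)


# -- single-dendrite growth ------------------------------------------------


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def _grow_dendrite(cfg: GeneratorConfig, rng, type_: str, subtype: str):
    """Grow one dendrite in local (AP, DV, depth) coordinates.

    The branching process runs in an isotropic unit envelope and is mapped
    through the anisotropic (DV-elongated) envelope affinely at the end, so
    the spatial occupancy follows the planted ellipse while every section's
    *final* length is drawn from the configured family (the unit-space length
    is the draw divided by the direction-dependent scale).  Planarity of
    bifurcations survives the affine map.  Returns (graph, root_id) with the
    root at the first branch point.
    """
    e = float(np.exp(rng.normal(0.0, cfg.anisotropy_jitter)))
    ax_dv = cfg.envelope_dv * e
    ax_ap = cfg.envelope_ap / e
    scale = np.array([ax_ap, ax_dv, 1.0])
    heading_angle = SUBTYPE_HEADINGS[subtype] + rng.normal(0.0, cfg.heading_jitter)
    heading_um = np.array([np.cos(heading_angle), np.sin(heading_angle), 0.0])
    heading = heading_um / scale
    heading /= np.linalg.norm(heading)
    # envelope centre sits ahead of the root along the heading (unit space)
    env_center = heading * cfg.root_offset_frac
    env_center[2] = 0.0
    iscale = cfg.internal_scale_by_type.get(type_, 1.0)

    g = nx.DiGraph()
    root = 0
    g.add_node(root, pos=np.zeros(3))
    next_id = 1

    def um_factor(direction):
        """Final-space length of a unit-space unit step along ``direction``."""
        return float(np.linalg.norm(direction * scale))

    def add_section(src, direction, length_um):
        """Polyline section from src along direction; returns end node."""
        nonlocal next_id
        p0 = g.nodes[src]["pos"]
        m = um_factor(direction)
        length = length_um / m  # unit-space length
        n_pts = max(int(np.ceil(length_um * cfg.points_per_um)), 1)
        perp1 = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp1) < 1e-9:
            perp1 = np.cross(direction, [1.0, 0.0, 0.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(direction, perp1)
        prev = src
        for i in range(1, n_pts + 1):
            t = i / n_pts
            p = p0 + direction * (length * t)
            if 0 < i < n_pts and cfg.curvature_jitter > 0:
                bump = np.sin(np.pi * t) * cfg.curvature_jitter / m
                p = p + perp1 * rng.normal(0, bump)
                p = p + perp2 * rng.normal(0, bump)
            g.add_node(next_id, pos=p)
            g.add_edge(prev, next_id)
            prev = next_id
            next_id += 1
        return prev

    def child_dirs(direction, k):
        """k near-planar child directions opening around the parent heading."""
        plane_perp = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(plane_perp) < 1e-9:
            plane_perp = np.cross(direction, [1.0, 0.0, 0.0])
        plane_perp /= np.linalg.norm(plane_perp)
        opening = abs(rng.normal(cfg.child_angle_mean, cfg.child_angle_sd))
        opening = min(opening, 0.9 * np.pi)
        if k == 2:
            angles = (-opening / 2.0, opening / 2.0)
        else:
            angles = (-opening / 2.0, 0.0, opening / 2.0)
        dirs = []
        for a in angles:
            d = np.cos(a) * direction + np.sin(a) * plane_perp
            # out-of-plane noise: tilt about an axis lying in the bifurcation plane
            axis = plane_perp if abs(a) < 1e-9 else direction
            d = _rotate_about(d, axis, rng.normal(0.0, cfg.planarity_noise))
            dirs.append(d / np.linalg.norm(d))
        return dirs

    z_wander = 0.3 * cfg.envelope_depth / cfg.envelope_dv

    def steer(position, direction):
        """Blend momentum, subtype heading, outward radial bias, depth wander."""
        radial = position.copy()
        radial[2] = 0.0
        rn = np.linalg.norm(radial)
        radial = radial / rn if rn > 1e-9 else heading
        d = (
            (1.0 - cfg.heading_bias) * direction
            + cfg.heading_bias * 0.6 * heading
            + cfg.heading_bias * 0.4 * radial
        )
        d[2] = 0.3 * direction[2] + rng.normal(0.0, z_wander)
        n = np.linalg.norm(d)
        return d / n if n > 1e-9 else heading

    def inside(position):
        dx = position[0] - env_center[0]
        dy = position[1] - env_center[1]
        dz = position[2] / cfg.envelope_depth
        return dx * dx + dy * dy + dz * dz <= 1.0

    # root is the first branch point: start with an immediate bifurcation
    first_dirs = child_dirs(heading, 3 if rng.random() < cfg.trifurcation_rate else 2)
    tips = [(root, d, 0) for d in first_dirs]
    while tips:
        src, direction, depth_lvl = tips.pop()
        pos = g.nodes[src]["pos"]
        direction = steer(pos, direction)
        will_branch = (
            depth_lvl < cfg.max_branch_depth
            and rng.random() < cfg.branch_prob
            and inside(pos)
        )
        if will_branch:
            length = _draw_length(rng, cfg.internal_family, cfg.internal_params, iscale)
            end = add_section(src, direction, length)
            if not inside(g.nodes[end]["pos"]):
                continue  # ran out of envelope: the endpoint becomes a leaf
            k = 3 if rng.random() < cfg.trifurcation_rate else 2
            for d in child_dirs(direction, k):
                tips.append((end, d, depth_lvl + 1))
        else:
            length = _draw_length(rng, cfg.external_family, cfg.external_params)
            add_section(src, direction, length)

    # map unit-space coordinates through the anisotropic envelope
    for v in g.nodes:
        g.nodes[v]["pos"] = g.nodes[v]["pos"] * scale
    # depth profile: root at root_depth_frac of the layer, deeper with radius
    for v in g.nodes:
        p = g.nodes[v]["pos"]
        r = np.linalg.norm(p[:2])
        frac = cfg.root_depth_frac + cfg.depth_tilt * r / max(ax_dv, 1.0)
        z = min(frac, 0.95) * cfg.layer_thickness + p[2]
        z = float(np.clip(z, 0.05 * cfg.layer_thickness, 0.95 * cfg.layer_thickness))
        g.nodes[v]["pos"] = np.array([p[0], p[1], z])
    return g, root


# -- population ------------------------------------------------------------


def _root_local_offset(cfg: GeneratorConfig, subtype: str) -> np.ndarray:
    """Root micro-placement in the column: a-b and c-d pairs co-locate."""
    if subtype in ("a", "b"):
        cluster = np.array([0.0, -cfg.cluster_offset / 2.0])
        within = np.array([-cfg.pair_offset if subtype == "a" else cfg.pair_offset, 0.0])
    else:
        cluster = np.array([0.0, cfg.cluster_offset / 2.0])
        within = np.array([0.0, cfg.pair_offset if subtype == "c" else -cfg.pair_offset])
    return cluster + within


def generate_population(cfg: GeneratorConfig) -> Population:
    """Generate the full synthetic population (deterministic under seed)."""
    cfg.validate()
    lattice = _hex_lattice(cfg.n_columns, cfg.column_pitch, cfg.dv_lattice_stretch)
    centers = {
        t: np.array([1000.0 * i, 0.0, 0.0]) for i, t in enumerate(cfg.types)
    }
    dendrites = {}
    rows = []
    anchors = {}
    for t_idx, type_ in enumerate(cfg.types):
        center = centers[type_]
        for col, xy in enumerate(lattice):
            for s_idx, subtype in enumerate("abcd"):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [cfg.seed, t_idx, col, s_idx]
                    )
                )
                root_xy = xy + _root_local_offset(cfg, subtype)
                surface, x_t, y_t, w = _cap_frame(center, cfg.sphere_radius, root_xy)
                g, root = _grow_dendrite(cfg, rng, type_, subtype)
                for v in g.nodes:
                    lx, ly, lz = g.nodes[v]["pos"]
                    g.nodes[v]["pos"] = surface + lx * x_t + ly * y_t + lz * w
                nid = f"{type_}{subtype}_{col:03d}"
                tree = NeuronTree(g, root)
                tree.set_label(root, "dendrite_root")
                dendrites[nid] = tree
                rows.append(
                    {"neuron_id": nid, "type": type_, "subtype": subtype,
                     "column": col}
                )
        marks = {
            "dorsal": (0.0, lattice[:, 1].max() + cfg.column_pitch),
            "ventral": (0.0, lattice[:, 1].min() - cfg.column_pitch),
            "anterior": (lattice[:, 0].max() + cfg.column_pitch, 0.0),
            "posterior": (lattice[:, 0].min() - cfg.column_pitch, 0.0),
        }
        anchors[type_] = {
            k: _cap_frame(center, cfg.sphere_radius, np.array(v))[0]
            for k, v in marks.items()
        }
    truth = {
        "seed": cfg.seed,
        "headings_rad": dict(SUBTYPE_HEADINGS),
        "heading_jitter": cfg.heading_jitter,
        "internal_family": cfg.internal_family,
        "internal_params": dict(cfg.internal_params),
        "internal_scale_by_type": dict(cfg.internal_scale_by_type),
        "external_family": cfg.external_family,
        "external_params": dict(cfg.external_params),
        "branch_prob": cfg.branch_prob,
        "trifurcation_rate": cfg.trifurcation_rate,
        "planarity_noise": cfg.planarity_noise,
        "depth_tilt": cfg.depth_tilt,
        "envelope": {
            "dv": cfg.envelope_dv, "ap": cfg.envelope_ap,
            "depth": cfg.envelope_depth,
        },
        "column_pitch": cfg.column_pitch,
        "pair_offset": cfg.pair_offset,
        "cluster_offset": cfg.cluster_offset,
        "root_depth_frac": cfg.root_depth_frac,
        "layer_thickness": cfg.layer_thickness,
        "sphere_radius": cfg.sphere_radius,
    }
    return Population(
        dendrites=dendrites,
        labels=pd.DataFrame(rows),
        anchors=anchors,
        truth=truth,
        sphere_centers=centers,
    )


def write_population(pop: Population, outdir) -> None:
    """Write SWC files, labels.csv, anchors.csv and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    swc_dir = out / "swc"
    swc_dir.mkdir(exist_ok=True)
    for nid, tree in pop.dendrites.items():
        write_swc(tree, swc_dir / f"{nid}.swc")
    pop.labels.to_csv(out / "labels.csv", index=False)
    rows = []
    for type_, marks in pop.anchors.items():
        for name, p in marks.items():
            rows.append({"type": type_, "landmark": name,
                         "x": p[0], "y": p[1], "z": p[2]})
    pd.DataFrame(rows).to_csv(out / "anchors.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(pop.truth, fh, indent=2, default=float)


def truth_check(recovered: dict, truth: dict, tolerances: dict) -> pd.DataFrame:
    """Planted-vs-recovered comparison table.

    ``recovered`` maps quantity names to measured values, ``tolerances`` to
    absolute tolerances; planted values are looked up in the truth record by
    dotted path (e.g. ``"internal_params.k"``).
    """
    rows = []
    for name, rec in recovered.items():
        node = truth
        for part in name.split("."):
            if not isinstance(node, dict) or part not in node:
                raise KeyError(f"quantity {name!r} missing from truth record")
            node = node[part]
        tol = tolerances.get(name, np.nan)
        ok = bool(abs(rec - node) <= tol) if np.isfinite(tol) else None
        rows.append({"quantity": name, "planted": node, "recovered": rec,
                     "tolerance": tol, "passed": ok})
    return pd.DataFrame(rows)
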