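"""End-to-end orchestration: population in, tidy analysis tables out.

Stage order mirrors the analysis narrative: annotation -> global alignment ->
spatial embedding (shape/volume) -> layer depth -> root neighbours ->
section/bifurcation geometry -> topology -> distribution fits -> statistics.
Every stage is a pure function of (inputs, config, seed); each writes one
tidy CSV so stages can be rerun and diffed independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import (align_dendrite, align_population, fit_sphere,
                    pc1_axis_angle, pc1_axis_angle_signed, scale_dendrite,
                    variance_explained)
from .annotate import annotate_dendrite
from .geometry import extract_bifurcations, section_radial_angles
from .io import read_swc
from .layers import (classify_faces, depth_vs_root_distance, hull_volume,
                     reconstruct_layer)
from .neighbors import RootSet, global_matching, relation_probabilities
from .distfit import group_select
from .stats import anova_type3
from .synth import GeneratorConfig, Population, generate_population
from .topology import (branch_bounds, leaf_depth_profile, section_table,
                       weighted_asymmetry)
from .trees import reduce_tree, resample

log = logging.getLogger("dendromorph")

__all__ = ["run_all", "load_population"]


def load_population(data_dir) -> Population:
    """Load a written population directory (swc/, labels.csv, anchors.csv)."""
    data_dir = Path(data_dir)
    labels_path = data_dir / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing labels file: {labels_path}")
    labels = pd.read_csv(labels_path)
    dendrites = {}
    for nid in labels["neuron_id"]:
        dendrites[nid] = read_swc(data_dir / "swc" / f"{nid}.swc")
    anchors: dict = {}
    anchor_path = data_dir / "anchors.csv"
    if anchor_path.exists():
        for _, row in pd.read_csv(anchor_path).iterrows():
            anchors.setdefault(row["type"], {})[row["landmark"]] = np.array(
                [row["x"], row["y"], row["z"]]
            )
    truth_path = data_dir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return Population(dendrites, labels, anchors, truth, sphere_centers={})


def run_all(
    out_dir,
    population: Population | None = None,
    data_dir=None,
    synth_config: GeneratorConfig | None = None,
    seed: int = 0,
    bootstrap_reps: int = 200,
    resample_step: float = 0.1,
) -> dict:
    """Run every stage and write one tidy CSV per analysis.

    Exactly one of ``population``, ``data_dir`` or ``synth_config`` supplies
    the input.  Returns a dict of the output DataFrames keyed as the files
    are named.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if population is None:
        if synth_config is not None:
            population = generate_population(synth_config)
        elif data_dir is not None:
            population = load_population(data_dir)
        else:
            raise ValueError("provide population, data_dir or synth_config")
    labels = population.labels.set_index("neuron_id")
    results: dict = {}

    # -- stage: annotation (idempotent on pre-isolated dendrites) ---------
    log.info("annotating %d dendrites", len(population.dendrites))
    dendrites = {}
    for nid, tree in population.dendrites.items():
        try:
            dendrites[nid] = (
                tree if tree.label(tree.root) == "dendrite_root"
                else annotate_dendrite(tree)
            )
        except ValueError as exc:
            raise RuntimeError(f"annotation failed for neuron {nid}: {exc}")

    # -- stage: global alignment per type ---------------------------------
    aligned_points = {}
    frames = {}
    for type_ in sorted(labels["type"].unique()):
        ids = [n for n in dendrites if labels.loc[n, "type"] == type_]
        pts = {n: dendrites[n].coords()[1] for n in ids}
        anchors = population.anchors.get(type_)
        if anchors is None:
            raise RuntimeError(f"no anchor landmarks for type {type_}")
        aligned, frame = align_population(pts, anchors)
        aligned_points.update(aligned)
        frames[type_] = frame
        # move the dendrites themselves into the aligned frame
        for n in ids:
            tree = dendrites[n]
            ids_n, _ = tree.coords()
            for v, p in zip(ids_n, aligned[n]):
                tree.graph.nodes[v]["pos"] = p

    # -- stage: shape (per-dendrite alignment, variance explained) --------
    shape_rows = []
    local = {}
    for nid, tree in dendrites.items():
        try:
            aligned, frame = align_dendrite(tree)
        except ValueError:
            continue
        local[nid] = (aligned, frame)
        ve = variance_explained(frame)
        shape_rows.append(
            {
                "neuron_id": nid,
                "type": labels.loc[nid, "type"],
                "subtype": labels.loc[nid, "subtype"],
                "pc1_dv_angle_deg": pc1_axis_angle(frame),
                "pc1_dv_angle_signed_deg": pc1_axis_angle_signed(frame),
                "lambda1": frame.eigenvalues[0],
                "var_pc1": ve[0],
                "var_pc2": ve[1],
                "var_pc3": ve[2],
            }
        )
    results["fig2_shape"] = pd.DataFrame(shape_rows)

    # -- stage: layer surfaces, volume and depth ---------------------------
    volume_rows, depth_rows = [], []
    surfaces = {}
    for type_ in sorted(labels["type"].unique()):
        ids = [n for n in dendrites if labels.loc[n, "type"] == type_]
        pooled = np.vstack([dendrites[n].coords()[1] for n in ids])
        surf = reconstruct_layer(pooled)
        origin = fit_sphere(pooled).center
        surf = classify_faces(surf, origin)
        surfaces[type_] = surf
        for n in ids:
            tree = dendrites[n]
            try:
                vol = hull_volume(tree)
            except ValueError:
                continue
            volume_rows.append(
                {
                    "neuron_id": n,
                    "type": type_,
                    "subtype": labels.loc[n, "subtype"],
                    "hull_volume_um3": vol,
                    "hull_volume_scaled": vol / surf.volume,
                }
            )
            for x, d_norm in depth_vs_root_distance(tree, surf, type_):
                depth_rows.append(
                    {"neuron_id": n, "type": type_,
                     "subtype": labels.loc[n, "subtype"],
                     "root_distance_norm": x, "d_norm": d_norm}
                )
    results["fig2_volume"] = pd.DataFrame(volume_rows)
    results["fig3_depth"] = pd.DataFrame(depth_rows)

    # -- stage: root nearest neighbours ------------------------------------
    roots = RootSet(
        ids=list(dendrites),
        positions=np.array([dendrites[n].pos(dendrites[n].root) for n in dendrites]),
        types=[labels.loc[n, "type"] for n in dendrites],
        subtypes=[labels.loc[n, "subtype"] for n in dendrites],
    )
    nn_rows = []
    for type_ in sorted(set(roots.types)):
        pairs = global_matching(roots, type_)
        rel, _ = relation_probabilities(pairs)
        pairs["type"] = type_
        nn_rows.append(pairs)
    results["fig4_neighbors"] = pd.concat(nn_rows, ignore_index=True)

    # -- stage: section + bifurcation geometry -----------------------------
    geo_rows, bif_rows = [], []
    for nid, tree in dendrites.items():
        red = reduce_tree(tree)
        for rec in section_radial_angles(red):
            geo_rows.append({"neuron_id": nid,
                             "type": labels.loc[nid, "type"],
                             "subtype": labels.loc[nid, "subtype"],
                             **rec})
        fine = resample(tree, resample_step)
        bifs, skipped = extract_bifurcations(fine)
        for b in bifs:
            bif_rows.append(
                {"neuron_id": nid, "type": labels.loc[nid, "type"],
                 "subtype": labels.loc[nid, "subtype"],
                 "gamma": b.gamma, "omega": b.omega, "theta": b.theta,
                 "angle_sum": b.angle_sum, "beta": b.dihedral_beta}
            )
    results["fig5_geometry"] = pd.DataFrame(geo_rows)
    results["fig5_bifurcations"] = pd.DataFrame(bif_rows)

    # -- stage: topology ----------------------------------------------------
    topo_rows, section_rows = [], []
    reduced = {}
    for nid, tree in dendrites.items():
        red = reduce_tree(tree)
        reduced[nid] = red
        bb = branch_bounds(red)
        asym = weighted_asymmetry(red)
        secs = section_table(tree, red)
        secs.insert(0, "neuron_id", nid)
        secs.insert(1, "type", labels.loc[nid, "type"])
        secs.insert(2, "subtype", labels.loc[nid, "subtype"])
        section_rows.append(secs)
        topo_rows.append(
            {
                "neuron_id": nid,
                "type": labels.loc[nid, "type"],
                "subtype": labels.loc[nid, "subtype"],
                "n": bb["n"], "L": bb["L"], "I": bb["I"],
                "total_cable": red.total_cable(),
                "n_sections": red.graph.number_of_edges(),
                "asymmetry_median": float(np.median(asym.values))
                if len(asym.values) else np.nan,
                "leaf_depth_max": max(leaf_depth_profile(red)),
            }
        )
    results["fig6_topology"] = pd.DataFrame(topo_rows)
    sections = pd.concat(section_rows, ignore_index=True)

    # -- stage: distribution fits (raw + variance-scaled lengths) ----------
    scaled_rows = []
    for nid, tree in dendrites.items():
        if nid not in local:
            continue
        aligned, _ = local[nid]
        try:
            scaled = scale_dendrite(aligned, "unit_variance")
        except ValueError:
            continue
        red = reduce_tree(scaled)
        tab = section_table(scaled, red)[["kind", "length"]]
        tab.insert(0, "neuron_id", nid)
        tab.insert(1, "type", labels.loc[nid, "type"])
        tab.insert(2, "subtype", labels.loc[nid, "subtype"])
        scaled_rows.append(tab)
    raw_tab = sections[["neuron_id", "type", "subtype", "kind", "length"]].copy()
    raw_tab["scaling"] = "raw"
    scl_tab = pd.concat(scaled_rows, ignore_index=True)
    scl_tab["scaling"] = "variance_scaled"
    all_lengths = pd.concat([raw_tab, scl_tab], ignore_index=True)
    results["fig7_sections"] = all_lengths
    results["fig7_distfits"] = group_select(
        all_lengths, grouping=("type", "kind", "scaling")
    )

    # -- stage: effect statistics ------------------------------------------
    stats_rows = []
    for name, frame, response in [
        ("pc1_dv_angle", results["fig2_shape"], "pc1_dv_angle_deg"),
        ("hull_volume_scaled", results["fig2_volume"], "hull_volume_scaled"),
    ]:
        if frame.empty:
            continue
        for rep in anova_type3(frame, response, reps=bootstrap_reps, seed=seed):
            stats_rows.append(
                {"analysis": name, "term": rep.term, "eta_p2": rep.eta_p2,
                 "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                 "meaningful": rep.meaningful}
            )
    results["stats_effects"] = pd.DataFrame(stats_rows)

    # -- write --------------------------------------------------------------
    for name, frame in results.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "version": __version__,
        "seed": seed,
        "n_dendrites": len(dendrites),
        "stages": sorted(results),
        "elapsed_s": round(time.time() - t0, 2),
        "config_hash": hashlib.sha256(
            json.dumps(population.truth, sort_keys=True, default=float).encode()
        ).hexdigest()[:16],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results
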