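"""Graph-theoretic morphometrics of reduced dendrite trees.

With all pass-through nodes contracted, a tree with n nodes and L leaves has
I = n - L internal (root/branch) nodes, bounded by 1 <= I <= (n - 1)/2: the
lower bound is a star, the upper a full binary tree.

Weighted partition asymmetry at a branch node v with k >= 2 children
averages, over all child pairs (p, q), the leaf-count imbalance of the two
child subtrees weighted by their share of the whole-tree cable:

    A_v = 1/C(k,2) * sum_{p<q} |L_p - L_q| / (L_p + L_q - 1)
                               * (W_p + W_q) / W(T)

A_v lies in [0, 1]; 0 is fully symmetric branching.  A subtree rooted at a
leaf counts one leaf and zero cable.

Section records carry, per reduced edge: kind (internal/external), integer
tree depth (distal-node convention), cable length, straight-line chord, and
within-section curvature (mean unsigned angle between the raw edges and the
section chord, plus the circular variance of those angles).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import circular_stats, unsigned_angle
from .trees import NeuronTree, ReducedTree

__all__ = [
    "AsymmetryProfile",
    "branch_bounds",
    "weighted_asymmetry",
    "leaf_depth_profile",
    "section_table",
    "cable_vs_sections",
]


@dataclass
class AsymmetryProfile:
    nodes: list
    values: np.ndarray  # A_v per branch node, same order as nodes
    total_cable: float


def branch_bounds(tree: ReducedTree) -> dict:
    """Counts (n, L, I) and the structural bounds 1 <= I <= (n-1)/2."""
    n = tree.n_nodes
    L = len(tree.leaves())
    I = n - L
    upper = (n - 1) / 2
    if not 1 <= I <= upper:
        raise AssertionError(f"branch-count bound violated: I={I}, n={n}")
    return {"n": n, "L": L, "I": I, "lower": 1, "upper": upper}


def _subtree_stats(tree: NeuronTree):
    """Post-order (cable, leaf count) per subtree."""
    g = tree.graph
    cable, leaves = {}, {}
    for v in reversed(list(nx.topological_sort(g))):
        kids = list(g.successors(v))
        if not kids:
            cable[v], leaves[v] = 0.0, 1
        else:
            cable[v] = sum(cable[c] + g.edges[v, c]["weight"] for c in kids)
            leaves[v] = sum(leaves[c] for c in kids)
    return cable, leaves


def weighted_asymmetry(tree: ReducedTree, local_norm: bool = False) -> AsymmetryProfile:
    """A_v for every branch node.

    ``local_norm=True`` normalizes each node's cable weighting by the cable
    of the subtree at v instead of the whole tree.
    """
    W = tree.total_cable()
    if W <= 0:
        raise ValueError("tree has zero total cable")
    cable, leaves = _subtree_stats(tree)
    nodes, values = [], []
    for v in tree.branch_nodes():
        kids = tree.children(v)
        norm = cable[v] if local_norm else W
        if norm <= 0:
            continue
        terms = []
        for p, q in combinations(kids, 2):
            # child-subtree stats: leaves include the child node itself,
            # cable excludes the connecting edge v -> child
            lp, lq = leaves[p], leaves[q]
            wp, wq = cable[p], cable[q]
            terms.append(abs(lp - lq) / (lp + lq - 1) * (wp + wq) / norm)
        nodes.append(v)
        values.append(float(np.mean(terms)))
    return AsymmetryProfile(nodes, np.array(values), W)


def leaf_depth_profile(tree: ReducedTree) -> dict:
    """Histogram of unweighted leaf depths h(leaf); counts sum to L."""
    depths = tree.depths()
    hist: dict = {}
    for v in tree.leaves():
        h = depths[v]
        hist[h] = hist.get(h, 0) + 1
    return hist


def section_table(raw: NeuronTree, reduced: ReducedTree) -> pd.DataFrame:
    """Per-section geometry built from the contraction map.

    Columns: source, target, kind, depth, length, chord, mean_edge_deviation,
    edge_angular_variance, valid.  Curvature compares each raw edge vector
    with the section's straight chord (unsigned 3-D angles).
    """
    depths = reduced.depths()
    rows = []
    for (u, v), chain in reduced.contraction.items():
        nodes = chain["nodes"]
        pts = np.array([raw.pos(n) for n in nodes])
        chord_vec = pts[-1] - pts[0]
        chord = float(np.linalg.norm(chord_vec))
        length = chain["length"]
        valid = chord > 0
        mean_dev = np.nan
        ang_var = np.nan
        if valid:
            edge_vecs = np.diff(pts, axis=0)
            angs = [
                unsigned_angle(e, chord_vec)
                for e in edge_vecs
                if np.linalg.norm(e) > 0
            ]
            if angs:
                mean_dev = float(np.mean(angs))
                ang_var = circular_stats(angs).circular_variance
        rows.append(
            {
                "source": u,
                "target": v,
                "kind": reduced.section_kind(u, v),
                "depth": depths[v],
                "length": length,
                "chord": chord,
                "mean_edge_deviation": mean_dev,
                "edge_angular_variance": ang_var,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)


def cable_vs_sections(reduced_dendrites: dict) -> pd.DataFrame:
    """Per-dendrite (section count, total cable) table for the ANCOVA slope."""
    if len(reduced_dendrites) < 2:
        raise ValueError("need at least 2 dendrites")
    rows = [
        {
            "dendrite": did,
            "n_sections": red.graph.number_of_edges(),
            "total_cable": red.total_cable(),
        }
        for did, red in reduced_dendrites.items()
    ]
    return pd.DataFrame(rows)
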