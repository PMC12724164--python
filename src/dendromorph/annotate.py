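"""Semi-automated dendrite annotation via the subtree score Φ.

For a neuron rooted at the soma, every branch node v is scored with

    Φ(v) = 1 - W(T_v)/W(T) + L_v/L

where ``W(T_v)`` is the cable of the subtree at v, ``W(T)`` the whole-neuron
cable, ``L_v`` the subtree's leaf count and ``L`` the neuron's.  The argmax
picks the node whose subtree keeps as many terminal tips as possible for as
little cable as possible — for T-shaped neurons (soma, long neurite, dense
dendritic tuft) this is the dendrite root.  A manual ``override`` channel
replaces the paper-scale GUI review step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .trees import NeuronTree, subtree

__all__ = ["SubtreeScore", "score_branch_nodes", "annotate_dendrite"]


@dataclass
class SubtreeScore:
    node: object
    phi: float
    cable_fraction: float
    leaf_fraction: float


def score_branch_nodes(tree: NeuronTree) -> list[SubtreeScore]:
    """Φ score for every branch node, sorted descending.

    Ties break by (higher leaf fraction, smaller node id) for
    reproducibility.  The root is a candidate only when it branches.
    """
    g = tree.graph
    W = tree.total_cable()
    L = len(tree.leaves())
    if W <= 0:
        raise ValueError("tree has zero total cable")

    # single post-order pass: subtree cable and leaf count per node
    sub_cable: dict = {}
    sub_leaves: dict = {}
    for v in reversed(list(nx.topological_sort(g))):
        kids = list(g.successors(v))
        if not kids:
            sub_cable[v], sub_leaves[v] = 0.0, 1
        else:
            sub_cable[v] = sum(
                sub_cable[c] + g.edges[v, c]["weight"] for c in kids
            )
            sub_leaves[v] = sum(sub_leaves[c] for c in kids)

    scores = []
    for v in g:
        if g.out_degree(v) >= 2:
            cf = sub_cable[v] / W
            lf = sub_leaves[v] / L
            scores.append(SubtreeScore(v, 1.0 - cf + lf, cf, lf))
    if not scores:
        warnings.warn("tree has no branch nodes; nothing to score")
    scores.sort(key=lambda s: (-s.phi, -s.leaf_fraction, s.node))
    return scores


def annotate_dendrite(tree: NeuronTree, override=None) -> NeuronTree:
    """Isolate the dendritic subtree at the Φ-argmax (or ``override``) node.

    The returned tree is rooted at the chosen node, the node carries the
    label ``"dendrite_root"``, and the Φ table is attached as
    ``.phi_table`` for review of low-margin cases.

    A tree whose root is already labelled ``"dendrite_root"`` is returned
    unchanged (annotation is idempotent): for an isolated dendrite
    Φ(root) = 1 exactly, while a leaf-dense proper subtree can score higher,
    so re-running the argmax would strip cable from an already-accepted
    dendrite.
    """
    if override is None and tree.label(tree.root) == "dendrite_root":
        dend = tree.copy()
        dend.phi_table = score_branch_nodes(tree)
        return dend
    scores = score_branch_nodes(tree)
    if override is not None:
        if override not in tree.graph:
            raise ValueError(f"override node {override} not in tree")
        if tree.graph.out_degree(override) < 2:
            warnings.warn(
                f"override node {override} is not a branch node; honoured anyway"
            )
        chosen = override
    else:
        if not scores:
            raise ValueError("no branch nodes and no override given")
        chosen = scores[0].node
    dend = subtree(tree, chosen)
    dend.set_label(chosen, "dendrite_root")
    dend.phi_table = scores
    return dend
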