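"""Rooted tree-graph model of a neuron skeleton.

A skeleton is a directed tree ``T = (V, E, r)`` embedded in 3-D: nodes carry
coordinates in µm, every edge is oriented away from the root ``r`` and carries
its Euclidean length ``w(e)``.  The total cable ``W(T)`` is the sum of edge
weights.  Branch nodes have out-degree >= 2, leaves have out-degree 0, and the
*reduced* tree contracts every maximal run of pass-through nodes
(in-degree = out-degree = 1) into a single edge — a *section* — whose weight
is the summed cable of the contracted run.  Sections ending at a leaf are
*external*, all others *internal*.

Node depth ``h(v)`` is the unweighted step count of the unique root-to-v path;
the cable (weighted) root distance is exposed separately.  An edge inherits
the depth of its distal (target) node.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "NeuronTree",
    "ReducedTree",
    "PathResult",
    "reroot",
    "reduce_tree",
    "subtree",
    "resample",
    "degree_profile",
]

_REL_TOL = 1e-9


class SkeletonError(ValueError):
    """Structural problem in a skeleton (multiple roots, cycles, orphans...)."""


@dataclass
class PathResult:
    """Unique undirected path between two nodes of a rooted tree."""

    node_sequence: list
    edge_sequence: list
    steps: int
    cable: float


class NeuronTree:
    """Directed rooted tree in 3-D with Euclidean edge weights.

    Parameters
    ----------
    graph
        ``networkx.DiGraph`` whose nodes carry a ``pos`` attribute
        (length-3 array, µm) and optionally ``label``.  Edge weights are
        (re)computed from the node positions.
    root
        Node id with in-degree 0.
    """

    def __init__(self, graph: nx.DiGraph, root, validate: bool = True):
        self.graph = graph
        self.root = root
        for u, v in graph.edges:
            graph.edges[u, v]["weight"] = float(
                np.linalg.norm(self.pos(v) - self.pos(u))
            )
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_parents(cls, ids, parents, coords, labels=None) -> "NeuronTree":
        """Build from parallel arrays (parent -1 or None marks the root)."""
        g = nx.DiGraph()
        coords = np.asarray(coords, dtype=float)
        root = None
        for i, nid in enumerate(ids):
            g.add_node(nid, pos=coords[i])
            if labels is not None and labels[i] is not None:
                g.nodes[nid]["label"] = labels[i]
        for nid, par in zip(ids, parents):
            if par is None or par == -1:
                if root is not None:
                    raise SkeletonError("multiple roots")
                root = nid
            else:
                if par not in g:
                    raise SkeletonError(f"orphan parent id {par} for node {nid}")
                g.add_edge(par, nid)
        if root is None:
            raise SkeletonError("no root (parent -1) found")
        return cls(g, root)

    def _validate(self):
        g = self.graph
        if self.root not in g:
            raise SkeletonError(f"root {self.root} not in node set")
        roots = [v for v in g if g.in_degree(v) == 0]
        if roots != [self.root] and set(roots) != {self.root}:
            raise SkeletonError(f"expected single root {self.root}, found {roots}")
        for v in g:
            if v != self.root and g.in_degree(v) != 1:
                raise SkeletonError(f"node {v} has in-degree {g.in_degree(v)}")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise SkeletonError("edge count != n - 1 (cycle or disconnection)")
        if g.number_of_nodes() > 1 and not nx.is_weakly_connected(g):
            raise SkeletonError("graph is not connected")

    # -- basic accessors ---------------------------------------------------

    def pos(self, v) -> np.ndarray:
        return np.asarray(self.graph.nodes[v]["pos"], dtype=float)

    def label(self, v):
        return self.graph.nodes[v].get("label")

    def set_label(self, v, label):
        self.graph.nodes[v]["label"] = label

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return list(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def coords(self):
        """(ids, (n, 3) array) of all node coordinates."""
        ids = list(self.graph.nodes)
        return ids, np.array([self.pos(v) for v in ids])

    def edge_weight(self, u, v) -> float:
        return self.graph.edges[u, v]["weight"]

    def total_cable(self) -> float:
        """W(T) = sum of edge weights, µm."""
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def out_degree(self, v) -> int:
        return self.graph.out_degree(v)

    def parent(self, v):
        preds = list(self.graph.predecessors(v))
        return preds[0] if preds else None

    def children(self, v) -> list:
        return list(self.graph.successors(v))

    def leaves(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def branch_nodes(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) >= 2]

    # -- paths and depth ---------------------------------------------------

    def path(self, u, v) -> PathResult:
        """The unique undirected path from u to v with step and cable length."""
        und = self.graph.to_undirected(as_view=True)
        seq = nx.shortest_path(und, u, v)
        edges = list(zip(seq[:-1], seq[1:]))
        cable = 0.0
        for a, b in edges:
            w = (
                self.graph.edges[a, b]["weight"]
                if self.graph.has_edge(a, b)
                else self.graph.edges[b, a]["weight"]
            )
            cable += w
        return PathResult(seq, edges, len(edges), cable)

    def depth(self, v) -> int:
        """h(v): unweighted step distance from the root."""
        return self.depths()[v]

    def depths(self) -> dict:
        if not hasattr(self, "_depths"):
            self._depths = nx.single_source_shortest_path_length(
                self.graph, self.root
            )
        return self._depths

    def root_cable_distance(self, v) -> float:
        """d_w(r, v): cable length of the root-to-v path."""
        return self.path(self.root, v).cable

    # -- misc --------------------------------------------------------------

    def copy(self) -> "NeuronTree":
        return NeuronTree(self.graph.copy(), self.root, validate=False)

    def __repr__(self):
        return (
            f"{type(self).__name__}(n={self.n_nodes}, "
            f"leaves={len(self.leaves())}, W={self.total_cable():.3f} µm)"
        )


class ReducedTree(NeuronTree):
    """Tree with all pass-through nodes contracted; edges are *sections*.

    ``contraction[(u, v)]`` is the ordered list of original node ids along the
    contracted path u -> ... -> v (endpoints included), for curvature analysis.
    """

    def __init__(self, graph, root, contraction, validate=True):
        self.contraction = contraction
        super().__init__(graph, root, validate=validate)
        # contracted weights override Euclidean chord lengths
        for (u, v), chain in contraction.items():
            if graph.has_edge(u, v):
                graph.edges[u, v]["weight"] = chain["length"]

    def section_kind(self, u, v) -> str:
        """'external' if the section ends at a leaf, else 'internal'."""
        return "external" if self.graph.out_degree(v) == 0 else "internal"

    def section_nodes(self, u, v) -> list:
        """Original node ids contracted into section (u, v), endpoints included."""
        return self.contraction[(u, v)]["nodes"]


# -- operations ------------------------------------------------------------


def reroot(tree: NeuronTree, new_root) -> NeuronTree:
    """Re-orient all edges away from ``new_root``; W(T) is unchanged."""
    if new_root not in tree.graph:
        raise SkeletonError(f"unknown node id {new_root}")
    g = nx.DiGraph()
    for v, d in tree.graph.nodes(data=True):
        g.add_node(v, **d)
    und = tree.graph.to_undirected(as_view=True)
    for u, v in nx.bfs_edges(und, new_root):
        g.add_edge(u, v)
    return NeuronTree(g, new_root)


def reduce_tree(tree: NeuronTree) -> ReducedTree:
    """Contract every maximal run of pass-through nodes into one section."""
    g = tree.graph
    keep = {
        v
        for v in g
        if v == tree.root or g.out_degree(v) != 1 or g.in_degree(v) != 1
    }
    rg = nx.DiGraph()
    for v in keep:
        rg.add_node(v, **g.nodes[v])
    contraction = {}
    for u in keep:
        for child in g.successors(u):
            chain = [u, child]
            while chain[-1] not in keep:
                chain.append(next(iter(g.successors(chain[-1]))))
            length = sum(
                g.edges[a, b]["weight"] for a, b in zip(chain[:-1], chain[1:])
            )
            rg.add_edge(u, chain[-1])
            contraction[(u, chain[-1])] = {"nodes": chain, "length": length}
    if not rg.nodes:
        rg.add_node(tree.root, **g.nodes[tree.root])
    return ReducedTree(rg, tree.root, contraction)


def subtree(tree: NeuronTree, v) -> NeuronTree:
    """T_v: node v, all its descendants, and the connecting edges, rooted at v."""
    if v not in tree.graph:
        raise SkeletonError(f"unknown node id {v}")
    nodes = {v} | nx.descendants(tree.graph, v)
    return NeuronTree(tree.graph.subgraph(nodes).copy(), v, validate=False)


def resample(tree: NeuronTree, step: float) -> NeuronTree:
    """Re-space pass-through nodes to ~``step`` µm along each section.

    Branch and leaf coordinates are preserved exactly; interior points are
    linearly interpolated on the original polyline, so total cable changes
    only by corner-cutting when ``step`` exceeds the native spacing.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    red = reduce_tree(tree)
    g = nx.DiGraph()
    for v in red.graph:
        g.add_node(v, **red.graph.nodes[v])
    next_id = max(tree.graph.nodes) + 1 if tree.n_nodes else 0
    for (u, v), chain in red.contraction.items():
        pts = np.array([tree.pos(n) for n in chain["nodes"]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        n_steps = max(int(round(total / step)), 1)
        targets = np.linspace(0.0, total, n_steps + 1)[1:-1]
        prev = u
        for t in targets:
            i = int(np.searchsorted(cum, t, side="right") - 1)
            i = min(i, len(seg) - 1)
            frac = (t - cum[i]) / seg[i] if seg[i] > 0 else 0.0
            p = pts[i] + frac * (pts[i + 1] - pts[i])
            g.add_node(next_id, pos=p)
            g.add_edge(prev, next_id)
            prev = next_id
            next_id += 1
        g.add_edge(prev, v)
    if g.number_of_nodes() == 0:
        g.add_node(tree.root, **tree.graph.nodes[tree.root])
    return NeuronTree(g, tree.root)


def degree_profile(tree: ReducedTree) -> dict:
    """Histogram of node out-degree; a reduced tree has no mass at deg+ = 1."""
    hist: dict = {}
    for v in tree.graph:
        d = tree.graph.out_degree(v)
        hist[d] = hist.get(d, 0) + 1
    return hist
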