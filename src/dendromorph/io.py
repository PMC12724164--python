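"""SWC skeleton I/O.

SWC is the plain-text interchange format for neuron skeletons: one node per
line with seven whitespace-separated columns

    id  type  x  y  z  radius  parent

where ``parent == -1`` marks the root and ``#`` starts a comment.  Coordinates
are kept in file units (µm by convention here); pass ``nm_to_um=True`` for
skeletons exported in nanometres.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .trees import NeuronTree, SkeletonError

__all__ = ["read_swc", "write_swc"]

# SWC structure-type codes we write; reading accepts any integer code.
_SOMA, _UNDEFINED = 1, 0


def read_swc(path, nm_to_um: bool = False, merge_zero_edges: bool = True) -> NeuronTree:
    """Parse an SWC file into a :class:`NeuronTree`.

    Duplicate-coordinate (zero-length) edges are merged with a warning by
    default, since they break downstream angle computations.

    Raises
    ------
    SkeletonError
        On multiple roots, duplicate ids, orphan parents or cycles; the
        message names the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SkeletonError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            nid, stype = int(parts[0]), int(parts[1])
            x, y, z, radius = map(float, parts[2:6])
            parent = int(parts[6])
            rows.append((lineno, nid, stype, x, y, z, radius, parent))

    scale = 1e-3 if nm_to_um else 1.0
    g = nx.DiGraph()
    root = None
    seen = {}
    for lineno, nid, stype, x, y, z, radius, parent in rows:
        if nid in seen:
            raise SkeletonError(f"line {lineno}: duplicate id {nid} (first at line {seen[nid]})")
        seen[nid] = lineno
        g.add_node(nid, pos=np.array([x, y, z]) * scale, radius=radius * scale,
                   swc_type=stype)
    for lineno, nid, stype, x, y, z, radius, parent in rows:
        if parent == -1:
            if root is not None:
                raise SkeletonError(f"line {lineno}: multiple roots (id {nid})")
            root = nid
        else:
            if parent not in g:
                raise SkeletonError(f"line {lineno}: orphan parent {parent}")
            g.add_edge(parent, nid)
    if root is None:
        raise SkeletonError("no root row (parent -1) in file")
    try:
        cycles = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycles = None
    if cycles:
        raise SkeletonError(f"cycle detected involving edge {cycles[0][:2]}")

    if merge_zero_edges:
        dup = [
            (u, v)
            for u, v in g.edges
            if np.allclose(g.nodes[u]["pos"], g.nodes[v]["pos"])
        ]
        for u, v in dup:
            warnings.warn(f"merging zero-length edge {u}->{v} (duplicate coordinates)")
            for w in list(g.successors(v)):
                g.add_edge(u, w)
            g.remove_node(v)
            if v == root:
                root = u
    return NeuronTree(g, root)


def write_swc(tree: NeuronTree, path) -> None:
    """Write a :class:`NeuronTree` as SWC, root first, in topological order."""
    order = list(nx.bfs_tree(tree.graph, tree.root))
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for v in order:
            p = tree.pos(v)
            parent = tree.parent(v)
            stype = tree.graph.nodes[v].get(
                "swc_type", _SOMA if v == tree.root else _UNDEFINED
            )
            radius = tree.graph.nodes[v].get("radius", 0.1)
            fh.write(
                f"{v} {stype} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                f"{radius:.17g} {parent if parent is not None else -1}\n"
            )
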