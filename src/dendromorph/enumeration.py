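"""Exhaustive enumeration of small reduced tree topologies.

A reduced dendrite tree has no pass-through nodes: every internal node,
including the root (the first branch point), has out-degree >= 2.  For small
node counts all distinct rooted topologies can be enumerated exactly, which
gives a brute-force oracle for the structural bounds, the partition-asymmetry
range and the subtree-score argmax.

Topologies are nested tuples: a leaf is ``()`` and an internal node is the
sorted tuple of its child topologies.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations_with_replacement

import networkx as nx
import numpy as np

from .trees import NeuronTree

__all__ = ["enumerate_reduced_topologies", "topology_to_tree", "count_nodes"]

LEAF = ()


def count_nodes(shape) -> int:
    return 1 + sum(count_nodes(c) for c in shape)


@lru_cache(maxsize=None)
def _trees_of_size(n: int) -> tuple:
    """All canonical topologies with exactly n nodes (internal out-deg >= 2)."""
    if n == 1:
        return (LEAF,)
    if n == 2:
        return ()  # an internal node must have >= 2 children
    out = set()
    # root has k >= 2 children whose sizes sum to n - 1
    for k in range(2, n):
        for sizes in _partitions(n - 1, k):
            pools = [_trees_of_size(s) for s in sizes]
            if any(len(p) == 0 for p in pools):
                continue
            out.update(_combine(pools, sizes))
    return tuple(sorted(out))


def _partitions(total: int, k: int, minimum: int = 1):
    """Non-increasing k-part partitions of ``total``."""
    if k == 1:
        if total >= minimum:
            yield (total,)
        return
    for first in range(minimum, total - (k - 1) * minimum + 1):
        for rest in _partitions(total - first, k - 1, first):
            yield (first,) + tuple(rest)


def _combine(pools, sizes):
    """Multisets of child topologies, one from each pool, canonically sorted.

    Children of equal size draw unordered combinations (with replacement)
    to avoid generating the same multiset twice.
    """
    groups = []
    i = 0
    while i < len(sizes):
        j = i
        while j < len(sizes) and sizes[j] == sizes[i]:
            j += 1
        groups.append((pools[i], j - i))
        i = j
    def rec(gi):
        if gi == len(groups):
            yield ()
            return
        pool, count = groups[gi]
        for combo in combinations_with_replacement(pool, count):
            for rest in rec(gi + 1):
                yield combo + rest
    for multiset in rec(0):
        yield tuple(sorted(multiset))


def enumerate_reduced_topologies(max_n: int, min_n: int = 3):
    """All reduced topologies with min_n <= n <= max_n nodes, smallest first."""
    for n in range(min_n, max_n + 1):
        yield from _trees_of_size(n)


def topology_to_tree(shape, rng=None) -> NeuronTree:
    """Embed a topology in 3-D with unit-length edges.

    Each child is placed one µm from its parent along a random direction, so
    every edge has weight exactly 1 (up to floating point) and node positions
    are almost surely distinct.
    """
    rng = rng or np.random.default_rng(0)
    g = nx.DiGraph()
    g.add_node(0, pos=np.zeros(3))
    counter = [0]

    def build(parent, sub):
        for child in sub:
            counter[0] += 1
            cid = counter[0]
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            g.add_node(cid, pos=g.nodes[parent]["pos"] + d)
            g.add_edge(parent, cid)
            build(cid, child)

    build(0, shape)
    return NeuronTree(g, 0)
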