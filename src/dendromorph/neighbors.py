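"""Dendrite-root nearest-neighbour structure.

Each optic-lobe column hosts four dendrites of a type, one per subtype
(a, b, c, d).  Two complementary views of the root-position geometry:

* subtype-specific nearest neighbours (KD-tree per type-subtype cell,
  excluding self), and
* a global subtype-agnostic pairing of all same-type roots — the
  maximum-cardinality matching of minimum total Euclidean distance — whose
  pairs are classified as *opposite* (a-b, c-d), *same* (equal subtypes) or
  *orthogonal* (everything else).  Under uniformly shuffled labels the
  chance levels are 0.25 / 0.25 / 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RootSet",
    "classify_pair",
    "subtype_nn",
    "global_matching",
    "relation_probabilities",
]

SUBTYPES = ("a", "b", "c", "d")
_OPPOSITE = {frozenset("ab"), frozenset("cd")}


@dataclass
class RootSet:
    """Dendrite root positions with type and subtype labels."""

    ids: list
    positions: np.ndarray  # (n, 3)
    types: list  # "T4" | "T5"
    subtypes: list  # "a" | "b" | "c" | "d"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        bad = set(self.subtypes) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtypes {sorted(bad)}")

    def mask(self, type_=None, subtype=None) -> np.ndarray:
        m = np.ones(len(self.ids), dtype=bool)
        if type_ is not None:
            m &= np.array([t == type_ for t in self.types])
        if subtype is not None:
            m &= np.array([s == subtype for s in self.subtypes])
        return m


def classify_pair(subtype_i: str, subtype_j: str) -> str:
    """'opposite' (a-b / c-d), 'same' (equal) or 'orthogonal' (remaining)."""
    if subtype_i == subtype_j:
        return "same"
    if frozenset((subtype_i, subtype_j)) in _OPPOSITE:
        return "opposite"
    return "orthogonal"


def subtype_nn(
    roots: RootSet, type_: str, query_subtype: str, target_subtype: str
) -> pd.DataFrame:
    """Distance from each query-subtype root to its nearest target-subtype root.

    Self matches are excluded when query and target subtypes coincide.
    """
    qm = roots.mask(type_, query_subtype)
    tm = roots.mask(type_, target_subtype)
    if tm.sum() < (2 if query_subtype == target_subtype else 1):
        raise ValueError(
            f"not enough {type_}{target_subtype} roots to query against"
        )
    tree = cKDTree(roots.positions[tm])
    k = 2 if query_subtype == target_subtype else 1
    d, _ = tree.query(roots.positions[qm], k=k)
    dist = d[:, -1] if k == 2 else np.atleast_1d(d)
    ids = [i for i, m in zip(roots.ids, qm) if m]
    return pd.DataFrame({"id": ids, "distance": dist})


def _exact_matching(pts: np.ndarray):
    """Blossom minimum-weight maximum-cardinality matching (O(n^3))."""
    n = len(pts)
    dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=dmat[i, j])
    return [tuple(sorted(p)) for p in nx.min_weight_matching(g)], dmat


def _greedy_2opt_matching(pts: np.ndarray, k: int = 12, passes: int = 8):
    """Near-optimal geometric matching for large n.

    Greedy shortest-candidate-edge matching on a k-NN graph (leftovers
    matched among themselves), refined by 2-opt pair rewiring restricted to
    spatially close pairs until no improving swap is found.  Total cost is
    never worse than plain greedy.
    """
    n = len(pts)
    tree = cKDTree(pts)
    kq = min(k + 1, n)
    dists, nbrs = tree.query(pts, k=kq)
    cand = []
    for i in range(n):
        for d, j in zip(dists[i, 1:], nbrs[i, 1:]):
            if i < j:
                cand.append((d, i, int(j)))
    cand.sort()
    mate = np.full(n, -1)
    for d, i, j in cand:
        if mate[i] < 0 and mate[j] < 0:
            mate[i], mate[j] = j, i
    free = [i for i in range(n) if mate[i] < 0]
    while len(free) > 1:  # rare leftovers: greedy on the remaining set
        i = free.pop()
        j = min(free, key=lambda j: np.linalg.norm(pts[i] - pts[j]))
        free.remove(j)
        mate[i], mate[j] = j, i

    def dist(i, j):
        return float(np.linalg.norm(pts[i] - pts[j]))

    pairs = [
        list(p)
        for p in sorted(
            {tuple(sorted((i, int(mate[i])))) for i in range(n) if mate[i] >= 0}
        )
    ]
    for _ in range(passes):
        mids = np.array([(pts[i] + pts[j]) / 2 for i, j in pairs])
        ptree = cKDTree(mids)
        neighbour_pairs = ptree.query(mids, k=min(16, len(pairs)))[1]
        improved = False
        for pi, row in enumerate(neighbour_pairs):
            for qi in np.atleast_1d(row):
                qi = int(qi)
                if qi == pi:
                    continue
                a, b = pairs[pi]
                c, d = pairs[qi]
                cur = dist(a, b) + dist(c, d)
                alt1 = dist(a, c) + dist(b, d)
                alt2 = dist(a, d) + dist(b, c)
                best = min(cur, alt1, alt2)
                if best < cur - 1e-12:
                    if alt1 <= alt2:
                        pairs[pi], pairs[qi] = [a, c], [b, d]
                    else:
                        pairs[pi], pairs[qi] = [a, d], [b, c]
                    improved = True
        if not improved:
            break
    return [tuple(sorted(p)) for p in pairs], None


def global_matching(roots: RootSet, within_type: str, exact_max: int = 200) -> pd.DataFrame:
    """Minimum-total-distance maximum-cardinality pairing of same-type roots.

    For up to ``exact_max`` roots the matching is solved exactly with the
    blossom algorithm on the complete geometric graph; beyond that a greedy
    k-nearest-neighbour matching refined by local 2-opt rewiring is used
    (the objective is unchanged, only the solver).  For odd n one root stays
    unmatched.  Returns a deterministic table
    (pair_id, id1, id2, subtypes, distance, relation).
    """
    m = roots.mask(within_type)
    idx = np.where(m)[0]
    if len(idx) < 2:
        raise ValueError(f"need at least 2 {within_type} roots")
    pts = roots.positions[idx]
    if len(idx) <= exact_max:
        pairs, _ = _exact_matching(pts)
    else:
        pairs, _ = _greedy_2opt_matching(pts)
    rows = []
    for i, j in pairs:
        gi, gj = idx[i], idx[j]
        rows.append(
            {
                "id1": roots.ids[gi],
                "id2": roots.ids[gj],
                "subtype1": roots.subtypes[gi],
                "subtype2": roots.subtypes[gj],
                "distance": float(np.linalg.norm(pts[i] - pts[j])),
                "relation": classify_pair(roots.subtypes[gi], roots.subtypes[gj]),
            }
        )
    rows.sort(key=lambda r: (str(r["id1"]), str(r["id2"])))
    out = pd.DataFrame(rows)
    out.insert(0, "pair_id", range(len(out)))
    return out


def relation_probabilities(pairs: pd.DataFrame):
    """Relation probabilities and the 4x4 subtype-by-subtype partner table.

    Returns ``(relation_probs, subtype_table)``: a Series over
    opposite/same/orthogonal summing to 1, and a row-stochastic DataFrame of
    partner-subtype probabilities per query subtype (each pair counted from
    both ends).
    """
    rel = pairs["relation"].value_counts(normalize=True)
    rel = rel.reindex(["opposite", "same", "orthogonal"], fill_value=0.0)
    counts = pd.DataFrame(0.0, index=list(SUBTYPES), columns=list(SUBTYPES))
    for _, row in pairs.iterrows():
        counts.loc[row["subtype1"], row["subtype2"]] += 1
        counts.loc[row["subtype2"], row["subtype1"]] += 1
    table = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    return rel, table
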