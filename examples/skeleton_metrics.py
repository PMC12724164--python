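"""Tree-graph basics: build a skeleton, reduce it, read off topology metrics.

A neuron skeleton is a rooted directed tree in 3-D.  Contracting every
pass-through node gives the reduced tree whose edges are *sections*; on that
tree we count leaves and branch nodes, check the structural bounds, and score
branching symmetry at every branch node.
"""

import networkx as nx
import numpy as np

from dendromorph import (NeuronTree, branch_bounds, degree_profile,
                         leaf_depth_profile, reduce_tree, weighted_asymmetry)

# a small hand-made dendrite rooted at its first branch point:
# two unequal lobes, one reached through a pass-through corridor
g = nx.DiGraph()
coords = {
    2: (2, 0, 0),                                       # dendrite root
    3: (3, 1, 0), 4: (4, 2, 0), 5: (4, 1, 0),          # upper lobe (2 leaves)
    6: (3, -1, 0), 8: (3.5, -1, 0), 7: (4, -1, 0),     # lower corridor + leaf
}
for v, p in coords.items():
    g.add_node(v, pos=np.array(p, dtype=float))
g.add_edges_from([(2, 3), (3, 4), (3, 5), (2, 6), (6, 8), (8, 7)])

tree = NeuronTree(g, root=2)
red = reduce_tree(tree)
print(f"raw skeleton : {tree}")
print(f"reduced      : {red}")
print(f"out-degree profile  : {degree_profile(red)}")
print(f"leaf depth histogram: {leaf_depth_profile(red)}")

bb = branch_bounds(red)
print(f"n={bb['n']} nodes, L={bb['L']} leaves, I={bb['I']} internal "
      f"(bounds {bb['lower']} <= I <= {bb['upper']})")

prof = weighted_asymmetry(red)
for v, a in zip(prof.nodes, prof.values):
    print(f"branch node {v}: partition asymmetry A_v = {a:.3f}")
print("A_v = 0 means the child subtrees balance leaves exactly; values near 1"
      "\nmean one child carries almost all terminal tips, weighted by cable.")
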