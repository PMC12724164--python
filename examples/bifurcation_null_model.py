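"""Bifurcation geometry against the random null model.

A bifurcation has three angular components: gamma and omega (up-stream parent
direction to each child) and theta (between the children).  Exactly planar,
outward-opening bifurcations satisfy gamma + omega + theta = 2*pi and have
dihedral angle beta = pi; the null model draws random outward-opening unit
vectors to show how much planarity to expect by chance.
"""

import numpy as np

from dendromorph import null_bifurcations

sample = null_bifurcations(count=100_000, z_scale=1.0, seed=7)
deg = np.degrees

print(f"{len(sample['angle_sum'])} random outward-opening bifurcations")
print(f"max single component : {deg(max(sample[k].max() for k in ('gamma','omega','theta'))):.2f} deg (bound 180)")
print(f"max angle sum        : {deg(sample['angle_sum'].max()):.2f} deg (bound 360)")
print(f"median angle sum     : {deg(np.median(sample['angle_sum'])):.1f} deg")
print(f"mass within 5 deg of 360: {np.mean(sample['angle_sum'] > np.radians(355)):.3f}")
print(f"median dihedral beta : {deg(np.median(sample['beta'])):.1f} deg (pi = planar, opening away)")

# flattening the z axis (as a thin neuropil layer does) pushes both toward planarity
flat = null_bifurcations(count=100_000, pc3_fraction=0.02, seed=7)
print("\nwith z flattened to the typical depth variance fraction (2%):")
print(f"mass within 5 deg of 360: {np.mean(flat['angle_sum'] > np.radians(355)):.3f}")
print(f"median dihedral beta : {deg(np.median(flat['beta'])):.1f} deg")
print("\nreal dendrites concentrate harder at 360/180 than either null —"
      "\nbifurcations are flatter than their flattened environment forces.")
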