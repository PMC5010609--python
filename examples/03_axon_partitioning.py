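"""Partitioned optimization of a large axonal cloud.

Clouds beyond ~200 points are split into sub-regions (k-means clusters or
soma-distance shells), solved independently, merged, and polished at the
junctions.  Both partitioning methods are tried and the shorter global
tree wins.
"""

import numpy as np

from neurowire import GAConfig, choose_axon_method, constraints_from_tree, prim_mst, random_cloud
from neurowire.morphology import real_wiring_length

# stand-in axon: a 300-point cloud constrained to its own MST topology
pts = random_cloud(300, seed=5)
edges, mst_len = prim_mst(pts)
root = int(np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
cloud = constraints_from_tree(pts, edges, root, label="example_axon")

result = choose_axon_method(
    cloud, GAConfig(seed=1), repeats=3, group_sizes=(100, 150)
)
real = real_wiring_length(cloud)
print(f"axonal cloud: n={cloud.n}")
print(f"real (MST) wiring : {real:9.1f} um")
print(f"found wiring      : {result.best_length:9.1f} um")
print(f"winning method    : {result.method_chosen}")
print(f"gap over optimum  : {100 * (result.best_length - mst_len) / mst_len:6.2f}%")
# The gap is the price of divide-and-conquer: sub-regions are optimized
# separately, so the merged tree is close to, but not exactly, the optimum.
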