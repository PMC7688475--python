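"""Metro-map 2-D layout of a fitted principal tree.

Embeds the tree with Kamada-Kawai stress minimization, scatters observations
around their projected edge positions, and encodes a variable's trend as
per-edge widths.
"""

import numpy as np

from medtraj.graph import grow_tree, prune_tree
from medtraj.layout import edge_trend, layout_graph, place_points
from medtraj.synthetic import bifurcating_tree_spec, generate_branching_dataset

spec = bifurcating_tree_spec(3, points_per_branch=100, noise=0.05, dim=3)
ds, truth = generate_branching_dataset(spec, seed=5)
X = ds.values.to_numpy(float)
tree, _ = grow_tree(X, n_nodes=18, seed=5)
tree = prune_tree(tree)

gl = layout_graph(tree, seed=5)
pl = place_points(X, tree, gl, seed=5)
print(f"2-D layout: {tree.n_nodes} nodes, scattering = {pl.scattering:.3f} "
      "(median point displacement = 25% of median edge length)")

# width-encode a binary marker present only on arm 1
marker = (truth["branch"] == 1).astype(float).to_numpy()
widths = edge_trend(tree, X, marker)
print("normalized edge widths for an arm-1 marker "
      f"(max on the marked arm): min={widths.min():.2f}, max={widths.max():.2f}")
print("first three point placements (x, y, edge, side):")
print(pl.table[["x", "y", "edge", "side"]].head(3).round(3).to_string())
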