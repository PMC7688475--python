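"""Quantify a mixed-type table and impute its missing cells.

Builds a small branching dataset, degrades two coordinates to an ordinal and
a binary variable, knocks out 3% of cells, then runs the quantification
(latent-Gaussian level scores) and the complete-row SVD imputer.
"""

import numpy as np

from medtraj.impute import svd_complete_impute
from medtraj.quantify import quantify_dataset
from medtraj.synthetic import (
    bifurcating_tree_spec,
    degrade_to_mixed,
    generate_branching_dataset,
    inject_missing,
)

spec = bifurcating_tree_spec(3, points_per_branch=100, noise=0.05, dim=4)
ds, _ = generate_branching_dataset(spec, seed=0)
X = ds.values.to_numpy(float)
mixed = degrade_to_mixed(
    X,
    {0: {"kind": "ordinal", "bins": list(np.quantile(X[:, 0], [0.25, 0.5, 0.75]))},
     1: {"kind": "binary", "bins": [float(np.median(X[:, 1]))]}},
)
mixed = inject_missing(mixed, "uniform", fraction=0.03, seed=1)

qm = quantify_dataset(mixed)
print(f"table: {mixed.n_rows} observations x {mixed.n_cols} variables, "
      f"{mixed.missing_mask.to_numpy().sum()} missing cells")
print("ordinal level scores for x0 (normal quantiles of cumulative midpoints):")
print("  levels:", qm.maps["x0"].levels, " scores:", np.round(qm.maps["x0"].scores, 3))

result = svd_complete_impute(qm, round_discrete=True)
print(f"imputed {len(result.imputed_cells)} cells with a rank-{result.k} model; "
      "discrete entries snapped to admissible level scores")
# The scores above are the numeric values the ordinal levels receive under a
# standard-normal latent model; the imputer fills holes from the principal
# hyperplane of the complete rows.
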