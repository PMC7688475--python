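# medtraj

Branching clinical trajectories and pseudo-time from mixed-type tabular data,
via elastic principal trees.

## The problem

Large observational clinical datasets are usually *synchronic*: each patient
contributes one snapshot (a hospital stay, an admission record) rather than a
longitudinal series. Yet if the snapshot is large enough, it samples the whole
landscape of disease states, and the stereotyped routes a disease follows —
including its bifurcations and terminal states — appear as one-dimensional
ridges along which the observations condense. `medtraj` models this geometry
explicitly: it fits a **principal tree** to the data cloud, reads the
root-to-leaf paths as **clinical trajectories** (ordered sequences of disease
states), and assigns each patient a **pseudo-time** — the geodesic distance
from a chosen root to the patient's projection on the tree — quantifying how
far the disease has progressed along its scenario. The package is aimed at
biostatisticians and clinical data scientists working with epidemiological
tables of mixed type (binary, ordinal, categorical, continuous) with missing
values.

## The model

An elastic principal tree is a set of nodes `V` with embedding
`phi : V -> R^m` joined by edges `E`, minimizing

    U = MSD + U_E + U_R

    MSD  = (1/|X|) * sum_i min( ||X_i - phi(V_P(i))||^2 , R0^2 )
    U_E  = sum_{edges} [ lambda + alpha * (max(2, deg(u), deg(v)) - 2) ] * ||phi(u) - phi(v)||^2
    U_R  = mu * sum_{stars} || phi(center) - mean(phi(neighbors)) ||^2

where `P(i)` assigns each point to its nearest node, `lambda` penalizes edge
stretching, `mu` pulls branch stars toward harmonic configurations, `alpha`
taxes higher-order branchings and `R0` is an optional trimming radius.
At fixed topology the problem is quadratic, so node positions are found
exactly by solving a linear system; the topology itself is searched by a
topological grammar ("add a node to a node", "bisect an edge"), accepting at
each step the lowest-energy candidate.

Around this core the package provides the full analysis chain:

| stage | module |
| --- | --- |
| typed tables, missingness filtering | `medtraj.datasets` |
| latent-Gaussian ordinal scores, dummy coding, optimal scaling, z-scores, PCA | `medtraj.quantify` |
| SVD imputers (complete-row and iterative low-rank) | `medtraj.impute` |
| elastic tree learning, pruning, leaf extension, projection | `medtraj.graph` |
| segments, trajectories, pseudo-time Pt(x) | `medtraj.tree` |
| chi-square / ANOVA segment tests, kernel & logistic pseudo-time regressions | `medtraj.association` |
| pseudo-time survival: Nelson-Aalen, cause-specific hazards, Kaplan-Meier, Cox | `medtraj.survival` |
| metro-map 2-D layouts | `medtraj.layout` |
| seeded branching-data generator with ground truth | `medtraj.synthetic` |
| end-to-end pipeline + `medtraj` CLI | `medtraj.pipeline`, `medtraj.cli` |

Ordinal variables are scored under a latent-Gaussian model
(`x_i = Phi^-1(cum_{<i} + p_i/2)`), optionally refined by optimal scaling
(maximizing the summed squared pairwise correlations subject to monotone
level maps). Pseudo-time follows
`Pt(x) = d(root, E(0)) +/- eps` in edge units, where `{E, eps}` is the
projection of `x` on the tree. Survival analysis substitutes pseudo-time for
physical time, separately per trajectory.

## Worked example

`examples/02_fit_principal_tree.py` generates a noisy 3-armed branching cloud
(100 points per arm, noise 5% of arm length), fits a 20-node tree, prunes and
extends it:

```
energy trace over grammar steps (non-increasing): [0.1774, 0.1272, 0.0897, 0.0771] ... 0.0236
recovered topology: 3 leaves, 1 branching node(s) (truth: 3 arms from one bifurcation point)
explained variance: 97.7% (fraction of total variance captured by projection onto the tree)
```

The energy trace shows the grammar search monotonically improving the fit;
the recovered topology matches the generator's ground truth; the explained
variance plays the role the cumulative variance of retained components plays
in PCA. Continuing with `examples/03_pseudotime_and_associations.py`:

```
3 non-branching segments; observations per segment: [92, 89, 119]
3 trajectories from root node 17
  arm 0: Spearman(pseudo-time, true arc length) = 0.981
  arm 1: Spearman(pseudo-time, true arc length) = 0.979
  arm 2: Spearman(pseudo-time, true arc length) = 0.979
8 variable-trajectory pairs with R^2 > 0.3 (coordinates tracking progression along an arm)
```

Pseudo-time reproduces the true arc-length ordering along every arm
(Spearman ≈ 0.98), and the association screen finds exactly the coordinates
that vary along each trajectory. The other examples cover quantification and
imputation (`01`), pseudo-time survival with per-trajectory Cox regression
(`04`) and the metro-map layout (`05`). The same chain runs from the shell:

```bash
medtraj simulate --arms 3 --out fixture/
medtraj run --table fixture/table.csv --meta fixture/meta.json --out run/ --seed 0
```

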