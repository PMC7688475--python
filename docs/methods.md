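# Methods

This note records the models implemented in `medtraj`, the numerical choices
behind them, and what the synthetic test bed does and does not establish.

## Data model and quantification

The input is an observation × variable table whose columns are declared
binary, ordinal, categorical or continuous, with a role (feature, outcome,
annotation). Missing entries (tokens `""`, `NA`, `NaN`, `?`, configurable)
are tracked in an explicit mask; row and column identifiers survive every
stage so results map back to source records.

**Missingness filtering.** Columns with missing fraction strictly above
`delta_column` are dropped first, then rows strictly above `delta_row`
(recomputed on the surviving columns). This greedy two-pass rule is the
simple substitute for the (hard) largest-admissible-submatrix problem. It is
*not* idempotent in full generality — dropping rows can push a kept column
back above its threshold — and the tests assert exactly what it guarantees:
row thresholds on the output, column thresholds at evaluation time. Defaults
follow common practice for hospital tables (30% columns, 20% rows), exposed
as parameters.

**Ordinal scores.** An ordinal variable with ordered levels and observed
proportions `p_i` is scored under a latent standard-normal model:
`x_i = Phi^-1(sum_{j<i} p_j + p_i/2)`. Binary variables are 2-level
ordinals; categorical variables are one-hot encoded (a missing source entry
is missing in every derived column). The quantile argument is clipped to
`[1e-12, 1 - 1e-12]` so zero-count boundary levels stay finite; strict
monotonicity of scores is guaranteed for strictly positive counts.

**Optimal scaling.** With several ordinal variables, level scores can be
refined jointly by maximizing `J = sum_{i<j} corr(col_i, col_j)^2` over
monotone rescorings. The objective alone does not fix an algorithm; the
implementation cycles over ordinal columns, takes as target the first
principal direction of the other standardized columns, maps per-level target
means through isotonic regression (both monotone directions tried; the
non-decreasing level map is kept, negating when needed since `corr^2` is
sign-blind), and **accepts a candidate only if `J` does not decrease**. The
trace is therefore monotone by construction; iteration stops when the sweep
gain falls below `tol` (default 1e-6, max 100 sweeps). Constant columns are
excluded with a warning.

The pipeline order is fixed: univariate quantification → imputation →
optimal scaling → z-scores (population 1/N convention, matching the
proportion convention of the quantile scores) → PCA.

**Intrinsic dimension.** The scree heuristic counts covariance eigenvalues
above `lambda_0 / C` with `C = 10` (the tolerated condition number after
reduction); it sets the default PCA dimension and the default imputation
rank.

## SVD imputation

`svd_complete_impute` computes the top-k principal components of the
complete-row submatrix (centered on complete-row means) and maps each
incomplete row to the nearest point of that affine hyperplane measured over
its *observed* coordinates only (a small least-squares per row); missing
coordinates are read off the projection. It requires at least `k + 1`
complete rows.

`svd_full_impute` is hard-impute: missing cells start at observed-cell
column means, and the filled matrix is repeatedly replaced on its missing
cells by its own best affine rank-k approximation (column mean + SVD of the
recentered matrix) until the largest change over missing cells drops below
`tol` (1e-6, max 200 iterations). Recentring on the *current* filled matrix
each iteration is essential: it makes the mean+SVD step the optimal affine
rank-k fit, so noiseless affine rank-k matrices are completed exactly and
the observed-cell objective is non-increasing (both tested).

Optional discrete rounding snaps imputed ordinal/binary entries to the
nearest admissible level score and restores mutual exclusivity inside each
dummy block by an argmax rule. Observed cells are never modified by either
imputer.

## Elastic principal tree

Energy, with `P(i)` the nearest-node assignment:

    U   = MSD + U_E + U_R
    MSD = (1/|X|) sum_i min(||X_i - phi(V_P(i))||^2, R0^2)
    U_E = sum_edges [lambda + alpha (max(2, deg u, deg v) - 2)] ||phi(u) - phi(v)||^2
    U_R = mu sum_{deg >= 2} ||phi(center) - mean(phi(neighbors))||^2

Defaults `lambda = 0.05`, `mu = 0.1`, `alpha = 0.01`, `R0 = inf`,
50 nodes. At fixed topology and partition the energy is quadratic in the
node coordinates, so positions are obtained exactly from one `K x K` linear
solve per data dimension; alternating partition/solve ("splitting"
iterations) makes `U` non-increasing. Nodes with empty clusters are kept —
the elastic terms keep the system non-singular for any connected graph with
`lambda > 0`.

**Structure search.** The two-node seed sits at `mean ± s * pc1` with `s`
half the standard deviation along the first principal direction
(deterministic). Each growth step enumerates every graph reachable by one
grammar operation — "add a node to a node" (new leaf at the parent plus the
mean offset of its assigned points, seeded jitter if the cluster is empty)
and "bisect an edge" (midpoint) — refits each candidate cheaply
(`tol = 1e-4`, 20 iterations), and accepts the minimum-energy candidate
(ties to the lowest index). The final graph is polished at `tol = 1e-6`.
Candidate refits are warm-started from the parent graph, which is why cheap
inner loops suffice.

**Post-processing.** Pruning removes leaves directly attached to a branching
node (one-edge stubs), one at a time, lowest index first, re-evaluating
degrees — so a star of single edges collapses to its center path (with a
warning when all branching structure disappears). Leaf extension moves each
terminal node outward along its edge direction to the ray projection of the
farthest assigned point, so extreme observations project onto edge interiors
rather than piling up on leaf nodes.

**A note on branching order.** At these parameters the energy genuinely
prefers two adjacent degree-3 branchings over one degree-4 star in roughly
half of noisy replicates, even for perfectly symmetric stars — verified by
fitting the ideal degree-4 structure directly and comparing energies
(`alpha` taxes higher-order stars by design). The method should therefore be
read as recovering *bifurcating* structure; the synthetic 4-armed fixture is
accordingly built from two bifurcations (a degree-4 star remains available
via an explicit `TreeSpec`).

## Segments, trajectories, pseudo-time

Non-branching segments are maximal paths whose interior nodes have degree 2,
found by depth-first walks that record visited *edges* (so pure cycles
become single cycle segments and isolated nodes singleton segments); the
segments partition the edge set exactly. Observations are labeled by the
segment of their nearest node; at a branching node the segment containing
the second-nearest candidate node wins. On trees with ≥ 30 nodes this agrees
with nearest-edge assignment for ≥ 95% of points (tested).

Root selection is advisory: per node, a 2×2 chi-square of node membership
against a target class; the most significant *positively enriched* node is
suggested, and the absence of any significant node is flagged rather than
guessed. All downstream operations take an explicit root.

Pseudo-time uses hop (edge-count) geodesics: with projection `{E, eps}` and
`d0, d1` the hop distances from the root to the edge's endpoints,
`Pt = d0 + eps` if `d0 < d1`, else `d0 - eps`. Edge units make trajectories
comparable across arms of different embedded lengths; a Euclidean-length
variant was considered and left out to keep one convention throughout.
An observation belongs to every trajectory (root-to-leaf path) whose edge
set contains its projection edge, with a single shared `Pt` — the formal
expression of prognostic uncertainty before a bifurcation.

## Association statistics

Categorical/binary variables vs segments: independence chi-square on the
segments × levels table with per-cell deviation `(E - O)/E` (positive values
mean the observed count falls *short* of the independence expectation).
Numeric/ordinal variables: one-way ANOVA on one-hot segment indicators with
the largest segment as reference; effects are linear-model coefficients with
their p-values. Along one trajectory, continuous/ordinal variables are
regressed on pseudo-time by Nadaraya-Watson with a Gaussian kernel
(default bandwidth 0.25 edge units, exposed), `R^2 = 1 - SSres/SStot`;
binary variables by logistic regression with `R^2` the squared correlation
of fitted probability with outcome (a deliberate pseudo-R² choice) and a
ridge fallback on separation. Screening applies Benjamini-Hochberg across
variables per analysis at level 0.05 and keeps pairs above `R^2 > 0.3` /
effect thresholds; both are parameters. Both segment tests hold their
nominal 5% size within Monte-Carlo error over 1,000 null replicates
(tested).

## Pseudo-time survival

Each observation on a trajectory enters the risk set with its pseudo-time as
time-on-study; terminal outcomes are events, everything else is censored at
its pseudo-time. Estimators accept one trajectory's `EventTable` at a time —
pseudo-times from different trajectories are not commensurable and are never
pooled. The Nelson-Aalen estimator `H(t) = sum_{t_i <= t} d_i / n_i` is
implemented directly (variance `sum d_i / n_i^2`, log-transformed
intervals) and cross-checked against lifelines; cause-specific curves treat
one cause as the event and the rest as censoring, so their increments
partition the all-cause increments. Kaplan-Meier and Cox regression delegate
to lifelines (the field-standard implementation); ties are therefore handled
by Efron's approximation — immaterial for continuous pseudo-times.
Covariates are standardized by default, exact collinearity is rejected up
front via a rank check, and non-convergence falls back to a flagged
ridge-penalized fit.

## Layout

The tree is embedded in 2-D by Kamada-Kawai stress minimization with
data-space edge lengths as target distances, started from a deterministic
circular layout (components tiled if disconnected). Observations sit at
their projection abscissa on the embedded edge, displaced perpendicularly by
`scattering × residual` on a seeded random side; the default scattering
makes the median displacement 25% of the median embedded edge length.
Edge-trend widths are per-edge means of a variable over the points projected
onto the edge, min-max normalized; empty edges interpolate their incident
nodes' means. Per-node class-proportion tables are emitted for pie-chart
style summaries; rendering is left to the caller.

## Synthetic test bed

The generator samples points uniformly along the arms of an embedded tree
plus isotropic Gaussian noise, recording each point's true branch and
arc-length pseudo-time before degradation. Arm directions at a node are
chosen by a best-of-100 max-min-angle rule so the declared branching is
geometrically realized (a rejection sampler can silently produce
near-collinear "arms"). Defaults, fixed once: unit arms, noise 5% of arm
length, 100 points per arm, embedding dimension 3. Degradation bins chosen
columns into ordinal/binary levels (order preserved); missingness is
injected uniformly or concentrated in chosen columns.

What this emulates — and what it does not: points condensed along noisy
1-D ridges with known branch labels, ordinal coarsening, and both uniform
and column-concentrated missingness. It does not emulate heavy-tailed or
site-batched noise, informative missingness, mixed measurement scales with
real covariance structure, or label noise in outcomes. Passing tests
therefore establish correctness of the machinery and recoverability under
the stated geometric model, not clinical validity on any particular
dataset.

Problem sizes in the test suite and acceptance script (chosen as the
package's own study conditions): topology/pseudo-time recovery uses 2-, 3-
and 4-armed bifurcating trees, 20 replicates each, 200-400 points, 20-25
nodes; energy monotonicity uses 20 runs of 150 points and 10 nodes;
estimator calibration uses n = 500 with 20-50 replicates and 1,000 null
replicates for the test sizes. The Nelson-Aalen exponential-limit check
evaluates the *median* sup-error over 20 draws because the sampling noise
of a single draw (s.d. of H(2) ≈ 0.11 at n = 500) is of the same order as
the bound being checked.

## Known limitations

- Tree topologies only; loops (converging trajectories) are out of scope.
- The grammar search is greedy: it finds low-energy structures, not
  certified global optima; degree-4 stars are usually represented as two
  close bifurcations (see above).
- Optimal scaling guarantees monotone improvement, not a global maximum of
  the correlation objective.
- Root choice is semantically external: enrichment can suggest a root but
  the interpretation (least-severe state) is the analyst's.
- Pseudo-time is an ordering surrogate, not physical time; its relation to
  chronology may differ per trajectory.
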