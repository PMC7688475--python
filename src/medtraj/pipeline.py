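"""End-to-end pipeline orchestration with a serializable run configuration.

``run_pipeline`` executes the full chain — missingness filtering, univariate
quantification, SVD imputation, optimal scaling, z-scoring, PCA reduction,
elastic-tree growth with pruning and leaf extension, segment partitioning,
root selection, trajectory extraction and pseudo-time, association screening,
per-trajectory pseudo-time survival, and 2-D layout — writing every
intermediate artifact plus a timed log into a run directory.  Runs are fully
deterministic given the seed, and the resolved configuration is persisted
next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, impute, layout as layout_mod, survival as survival_mod
from .datasets import MixedDataset, filter_missing, read_dataset
from .graph import ElasticParams, explained_variance, extend_leaves, grow_tree, prune_tree
from .quantify import (
    estimate_intrinsic_dimension_pca,
    optimal_scaling,
    quantify_dataset,
    reduce_dimension,
    zscore,
)
from .tree import (
    compute_pseudotime,
    decompose_segments,
    extract_trajectories,
    partition_by_segments,
    select_root,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

IMPUTERS = ("svd_complete", "svd_full")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serialized next to outputs)."""

    table_path: str
    meta_path: str
    output_dir: str
    delta_column: float = 0.3
    delta_row: float = 0.2
    imputer: str = "svd_complete"
    impute_k: int | None = None
    round_discrete: bool = True
    apply_optimal_scaling: bool = True
    n_components: int | str = "auto"  # "auto" = PCA intrinsic-dimension rule
    elastic: dict = field(default_factory=lambda: {"lam": 0.05, "mu": 0.1, "alpha": 0.01})
    n_nodes: int = 50
    prune: bool = True
    extend: bool = True
    root: int | None = None  # explicit node id; None = enrichment-based on target class
    root_target_class: str | None = None
    event_column: str | None = None  # binary outcome column for survival
    run_associations: bool = True
    run_survival: bool = True
    run_layout: bool = True
    scattering: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imputer not in IMPUTERS:
            raise ValueError(f"unknown imputer {self.imputer!r}; choose from {IMPUTERS}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load JSON or YAML config; keyword overrides win over file values."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def run_pipeline(config: RunConfig, dataset: MixedDataset | None = None) -> Path:
    """Run the full analysis; returns the run directory of artifacts.

    A ready :class:`MixedDataset` may be passed instead of reading from
    ``config.table_path``.  Any stage failure aborts with the stage name
    while keeping the artifacts written so far.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "resolved_config.json")
    log_lines: list[str] = []
    t_start = time.perf_counter()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.perf_counter() - t_start:8.2f}s] {msg}")
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")

    def stage(name):
        class _Stage:
            def __enter__(self):
                log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED: {exc}")
                    raise PipelineError(name, exc) from exc
                log(f"stage {name}: done")
                return False

        return _Stage()

    log(f"seed={config.seed}")

    with stage("read"):
        ds = dataset if dataset is not None else read_dataset(config.table_path, config.meta_path)

    with stage("filter"):
        ds, report = filter_missing(ds, config.delta_column, config.delta_row)
        report.to_json(outdir / "filter_report.json")
        ds.to_csv(outdir / "filtered.csv")

    with stage("quantify"):
        qm = quantify_dataset(ds)
        qm.data.to_csv(outdir / "quantified.csv")

    with stage("impute"):
        if config.imputer == "svd_complete":
            result = impute.svd_complete_impute(qm, k=config.impute_k,
                                                round_discrete=config.round_discrete)
        else:
            result = impute.svd_full_impute(qm, k=config.impute_k,
                                            round_discrete=config.round_discrete)
        qm = result.matrix
        qm.data.to_csv(outdir / "imputed.csv")
        log(f"imputer={config.imputer} k={result.k} cells={len(result.imputed_cells)}")

    if config.apply_optimal_scaling:
        with stage("optimal_scaling"):
            qm, trace = optimal_scaling(qm)
            log(f"objective {trace[0]:.4f} -> {trace[-1]:.4f} in {len(trace) - 1} sweeps")

    with stage("zscore"):
        qm = zscore(qm)
        qm.data.to_csv(outdir / "scaled.csv")

    with stage("reduce"):
        if config.n_components == "auto":
            n_comp = max(2, estimate_intrinsic_dimension_pca(qm))
        else:
            n_comp = int(config.n_components)
        scores, _, evr = reduce_dimension(qm, n_comp)
        pd.DataFrame(scores, index=qm.data.index,
                     columns=[f"pc{i + 1}" for i in range(n_comp)]).to_csv(outdir / "reduced.csv")
        log(f"n_components={n_comp} explained={evr.sum():.3f}")

    with stage("tree"):
        params = ElasticParams(**config.elastic)
        G, fit = grow_tree(scores, n_nodes=config.n_nodes, params=params, seed=config.seed)
        if config.prune:
            G = prune_tree(G)
        if config.extend:
            G = extend_leaves(G, scores)
        G.to_json(outdir / "graph.json")
        log(f"nodes={G.n_nodes} leaves={len(G.leaves)} "
            f"explained_variance={explained_variance(G, scores):.3f}")

    with stage("segments"):
        segments = decompose_segments(G)
        seg_labels = partition_by_segments(scores, G, segments)
        pd.DataFrame({"row_id": ds.row_ids, "segment": seg_labels}).to_csv(
            outdir / "partition.csv", index=False
        )
        (outdir / "segments.json").write_text(json.dumps(
            [{"id": s.id, "nodes": list(s.node_path), "kind": s.kind} for s in segments], indent=2
        ))

    with stage("root"):
        if config.root is not None:
            root = int(config.root)
        elif config.root_target_class is not None and config.event_column is not None:
            labels = ds.values[config.event_column].to_numpy()
            sel = select_root(G, scores, labels, config.root_target_class)
            if not sel.significant:
                raise ValueError("no significantly enriched root node; supply one explicitly")
            root = int(sel.node)
        else:
            # default: the leaf farthest from the data mean along the tree
            root = int(G.leaves[0]) if G.leaves else 0
        log(f"root={root}")

    with stage("pseudotime"):
        trajectories = extract_trajectories(G, root, segments)
        pt = compute_pseudotime(scores, G, root, segments, trajectories, index=ds.row_ids)
        table = pt.table.copy()
        for tr in trajectories:
            table[f"traj_{tr.id}"] = pt.trajectory_members[tr.id]
        table.to_csv(outdir / "pseudotime.csv", index_label="row_id")

    if config.run_associations:
        with stage("associations"):
            kinds = {c: qm.kinds.get(c, "continuous") for c in qm.columns}
            res = association.screen_associations(qm.data, kinds, seg_labels, pt)
            for key, frame in res.items():
                frame.to_csv(outdir / f"association_{key}.csv", index=False)

    if config.run_survival and config.event_column is not None:
        with stage("survival"):
            events_all = (
                pd.to_numeric(ds.values[config.event_column], errors="coerce")
                .fillna(0)
                .to_numpy()
            )
            events_all = (events_all > 0).astype(int)
            rows = []
            for tr in trajectories:
                et = survival_mod.events_for_trajectory(pt, tr.id, events_all)
                if et.events.sum() == 0:
                    continue
                curve = survival_mod.nelson_aalen(et)
                for t_, h, v in zip(curve.times, curve.cumulative_hazard, curve.variance):
                    rows.append((tr.id, t_, h, v))
            pd.DataFrame(rows, columns=["trajectory", "pt", "cum_hazard", "variance"]).to_csv(
                outdir / "survival_hazards.csv", index=False
            )

    if config.run_layout:
        with stage("layout"):
            gl = layout_mod.layout_graph(G, seed=config.seed)
            pl = layout_mod.place_points(scores, G, gl, scattering=config.scattering,
                                         seed=config.seed)
            (outdir / "layout.json").write_text(json.dumps({
                "nodes": gl.coordinates.tolist(),
                "edges": [list(e) for e in G.edges],
                "scattering": pl.scattering,
                "seed": config.seed,
            }, indent=2))
            pl.table.to_csv(outdir / "layout_points.csv", index=False)

    log("pipeline complete")
    return outdir
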