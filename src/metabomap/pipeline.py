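"""End-to-end orchestration: generate/read -> exclude -> index -> scale ->
SOM -> Ward -> profile, with deterministic text artifacts and a manifest.

Every artifact is a pure function of (input, config, seed); the manifest
records a SHA-256 content hash per file so reruns can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy

from metabomap import clustering, indexes, preprocess, profiling, som
from metabomap import synthetic_cohort as sc

log = logging.getLogger("metabomap")


@dataclass
class RunConfig:
    """Validated hyperparameters of one pipeline run."""

    input_path: str | None = None      # cohort CSV; None -> generate
    n_subjects: int = 1000             # generator size when no input
    separation: float = 3.0            # generator archetype separation
    use_default_archetypes: bool = False
    grid_rows: int = 3
    grid_cols: int = 9
    iterations: int = 500
    lr_start: float = 0.05
    lr_end: float = 0.01
    n_restarts: int = 100
    k_range: tuple = clustering.DEFAULT_K_RANGE
    cut_levels: tuple = clustering.DEFAULT_CUT_LEVELS
    n_bootstrap: int = 0
    bootstrap_restarts: int = 10
    by_gender: bool = False
    missing_rate: float = 0.0
    medicated_rate: float = 0.0
    seed: int = 0
    out_dir: str = "runs/latest"

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.iterations < 0 or self.n_restarts < 1:
            raise ValueError("iterations >= 0 and n_restarts >= 1 required")
        if not (0 < self.lr_end <= self.lr_start):
            raise ValueError("need 0 < lr_end <= lr_start")
        n_units = self.grid_rows * self.grid_cols
        if any(not 1 <= k <= n_units for k in self.cut_levels):
            raise ValueError(f"cut levels must lie in [1, {n_units}]")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "cut_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunArtifacts:
    out_dir: Path
    exclusion_report: preprocess.ExclusionReport
    panel: pd.DataFrame
    model: som.SOMModel
    tree: clustering.ClusterTree
    optimal_k: int
    partitions: dict
    stability: clustering.StabilityReport | None
    profiles: dict
    manifest: dict = field(default_factory=dict)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Nested-parenthesis tree text with Ward heights as branch lengths."""
    root = hierarchy.to_tree(Z)

    def _fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return _fmt(root, root.dist) + ";"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, encoding="utf-8", **kwargs)


def run(config: RunConfig) -> RunArtifacts:
    """Execute the full pipeline and write all artifacts under
    ``config.out_dir``. Deterministic given config + seed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input ---------------------------------------------------------
    if config.input_path is not None:
        cohort = sc.read_cohort(config.input_path)
    else:
        archetypes = (
            sc.default_archetypes() if config.use_default_archetypes
            else sc.separated_pair(config.separation)
        )
        gen = sc.GeneratorConfig(
            n_subjects=config.n_subjects,
            archetypes=tuple(archetypes),
            missing_rate=config.missing_rate,
            medicated_rate=config.medicated_rate,
            seed=config.seed,
        )
        cohort = sc.generate_cohort(gen)
        sc.write_cohort(cohort, out / "cohort.csv")

    # --- exclusions + indexes -----------------------------------------
    retained, report = preprocess.apply_exclusions(cohort)
    log.info(
        "exclusions: input=%d medicated=%d missing=%d retained=%d",
        report.n_input, report.n_medicated, report.n_missing, report.n_retained,
    )
    panel = indexes.compute_panel(retained)
    indexes.write_panel(panel, out / "index_panel.csv", out / "units_manifest.tsv")

    # --- SOM -----------------------------------------------------------
    layers = preprocess.scale_features(retained)
    grid = som.build_grid(config.grid_rows, config.grid_cols)
    model = som.restart_best(
        layers, grid,
        n_restarts=config.n_restarts,
        seed=config.seed,
        iterations=config.iterations,
        lr_start=config.lr_start,
        lr_end=config.lr_end,
    )
    log.info("som: quantization_error=%.6f restarts=%d",
             model.quantization_error, config.n_restarts)
    bmu, bmu_dist = som.map_subjects(model, layers)

    # --- clustering ----------------------------------------------------
    tree = clustering.ward_tree(model)
    optimal_k = clustering.choose_k(tree, model, config.k_range)
    log.info("clustering: optimal_k=%d silhouette=%.4f",
             optimal_k, tree.silhouette_by_k[optimal_k])
    cuts = sorted(set(config.cut_levels) | {optimal_k})
    partitions = clustering.cut_partitions(tree, cuts, bmu)

    stability = None
    if config.n_bootstrap > 0:
        stability = clustering.bootstrap_stability(
            retained, grid, k=optimal_k,
            n_resamples=config.n_bootstrap,
            seed=config.seed,
            pipeline_config={
                "n_restarts": config.bootstrap_restarts,
                "iterations": config.iterations,
                "lr_start": config.lr_start,
                "lr_end": config.lr_end,
            },
            reference_labels=partitions[optimal_k]["subject_to_cluster"],
        )
        log.info("stability: mean_jaccard=%.3f skipped=%d",
                 stability.overall, stability.n_skipped)

    # --- profiling -----------------------------------------------------
    profile_table = retained[
        ["id", "sex"] + list(sc.CLUSTERING_VARIABLES) + ["hba1c", "tg", "hdl"]
    ].join(panel.drop(columns=["id", "bmi"]))  # bmi already a clustering var
    numeric_vars = [
        c for c in profile_table.columns
        if c not in ("id", "sex") and pd.api.types.is_numeric_dtype(profile_table[c])
    ]
    percentiles = profiling.population_percentiles(profile_table, numeric_vars)
    strata = ["all"] + (["male", "female"] if config.by_gender else [])
    profiles = {}
    for k in cuts:
        assignment = partitions[k]["subject_to_cluster"]
        for stratum in strata:
            prof = profiling.profile_clusters(
                assignment, profile_table, percentiles,
                stratum=stratum, sex=retained["sex"].to_numpy(),
                allow_empty=(stratum != "all"),
            )
            profiles[(k, stratum)] = prof
    footprints = {
        key: profiling.footprint(prof) for key, prof in profiles.items()
    }
    compositions = {
        k: profiling.dysglycemia_composition(
            partitions[k]["subject_to_cluster"],
            panel["glycemia_class"].to_numpy(),
        )
        for k in cuts
    }

    # --- artifacts -----------------------------------------------------
    _write_csv(
        pd.DataFrame({
            "variable": list(percentiles.index),
            **{c: percentiles[c].to_numpy() for c in percentiles.columns},
        }),
        out / "population_percentiles.csv", index=False,
    )
    assignments = pd.DataFrame({"id": retained["id"], "bmu": bmu,
                                "bmu_distance": bmu_dist})
    for k in cuts:
        assignments[f"cluster_k{k}"] = partitions[k]["subject_to_cluster"]
    _write_csv(assignments, out / "assignments.csv", index=False)

    codebook_df = pd.DataFrame(
        model.codebooks,
        columns=[f"{name}_{t}" for name in preprocess.LAYER_NAMES
                 for t in ("a", "b", "c")],
    )
    codebook_df.insert(0, "unit", np.arange(grid.n_units))
    _write_csv(codebook_df, out / "codebooks.csv", index=False)

    (out / "dendrogram.nwk").write_text(
        linkage_to_newick(tree.linkage, [f"U{i}" for i in range(grid.n_units)])
        + "\n", encoding="utf-8",
    )
    _write_csv(
        pd.DataFrame(
            {"k": list(tree.silhouette_by_k),
             "mean_silhouette": list(tree.silhouette_by_k.values())}
        ),
        out / "silhouette_by_k.csv", index=False,
    )
    for (k, stratum), prof in profiles.items():
        base = out / f"profile_k{k}_{stratum}"
        _write_csv(prof.medians, Path(f"{base}_medians.csv"))
        _write_csv(prof.bins, Path(f"{base}_bins.csv"))
        _write_csv(footprints[(k, stratum)].radial, Path(f"{base}_footprint.csv"))
    for k, comp in compositions.items():
        _write_csv(comp, out / f"dysglycemia_k{k}.csv")

    summary = {
        "exclusions": dataclasses.asdict(report),
        "quantization_error": model.quantization_error,
        "optimal_k": optimal_k,
        "silhouette_by_k": {int(k): v for k, v in tree.silhouette_by_k.items()},
        "cluster_sizes": {
            int(k): {int(c): int(s)
                     for c, s in partitions[k]["cluster_sizes"].items()}
            for k in cuts
        },
        "stability": None if stability is None else {
            "overall_mean_jaccard": stability.overall,
            "per_cluster": [float(x) for x in stability.per_cluster],
            "n_resamples": stability.n_resamples,
            "n_skipped": stability.n_skipped,
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n", encoding="utf-8"
    )
    resolved = dataclasses.asdict(config)
    resolved["k_range"] = list(config.k_range)
    resolved["cut_levels"] = list(config.cut_levels)
    (out / "config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True), encoding="utf-8"
    )

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )

    return RunArtifacts(
        out_dir=out,
        exclusion_report=report,
        panel=panel,
        model=model,
        tree=tree,
        optimal_k=optimal_k,
        partitions=partitions,
        stability=stability,
        profiles=profiles,
        manifest=manifest,
    )
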