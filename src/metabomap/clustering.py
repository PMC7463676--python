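"""Ward clustering of SOM units, cut-level partitions, silhouette-based
selection of K, and bootstrap clusterwise Jaccard stability.

Units are clustered on their codebook vectors in the layer-normalized
feature space (plain Euclidean there equals the SOM training metric).
Subjects inherit the cluster of their best-matching unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from metabomap import preprocess, som
from metabomap.som import SOMGrid, SOMModel

DEFAULT_K_RANGE = tuple(range(2, 11))
DEFAULT_CUT_LEVELS = (2, 11, 27)


@dataclass
class ClusterTree:
    """Ward merge sequence over the SOM units."""

    linkage: np.ndarray              # scipy linkage matrix, (n_units-1, 4)
    n_leaves: int
    silhouette_by_k: dict = field(default_factory=dict)
    optimal_k: int | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Unit -> cluster labels (0-based, renumbered by first leaf)."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"K={k} outside [1, {self.n_leaves}]")
        raw = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return _canonical_labels(raw)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 0..K-1 in order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def ward_tree(model: SOMModel) -> ClusterTree:
    """Agglomerative Ward (D2 criterion on Euclidean distances) over the
    unit codebooks; deterministic given the codebooks."""
    X = model.normalized_codebooks()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite codebooks")
    Z = hierarchy.linkage(X, method="ward")
    return ClusterTree(linkage=Z, n_leaves=X.shape[0])


def unit_silhouette(model: SOMModel, labels: np.ndarray) -> float:
    """Mean silhouette width of a unit partition (Euclidean on codebooks)."""
    return float(
        silhouette_score(model.normalized_codebooks(), labels, metric="euclidean")
    )


def choose_k(tree: ClusterTree, model: SOMModel,
             k_range=DEFAULT_K_RANGE) -> int:
    """Argmax of mean silhouette width over ``k_range``; ties -> smallest K.

    K values where the cut degenerates to fewer than two clusters are
    recorded as NaN and never selected.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    if min(k_range) < 2 or max(k_range) > tree.n_leaves - 1:
        raise ValueError(f"k_range must lie within [2, {tree.n_leaves - 1}]")
    best_k, best_s = None, -np.inf
    for k in sorted(k_range):
        labels = tree.cut(k)
        if len(np.unique(labels)) < 2:
            tree.silhouette_by_k[k] = float("nan")
            continue
        s = unit_silhouette(model, labels)
        tree.silhouette_by_k[k] = s
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no K in range produced a valid partition")
    tree.optimal_k = best_k
    return best_k


def cut_partitions(tree: ClusterTree, ks, assignment: np.ndarray) -> dict:
    """Subject partitions at each cut level.

    ``assignment`` maps subject -> BMU; subjects inherit their unit's
    cluster. Returns {k: {"unit_to_cluster", "subject_to_cluster",
    "cluster_sizes"}}.
    """
    out = {}
    for k in ks:
        units = tree.cut(k)
        subjects = units[np.asarray(assignment)]
        sizes = pd.Series(subjects).value_counts().sort_index()
        out[k] = {
            "unit_to_cluster": units,
            "subject_to_cluster": subjects,
            "cluster_sizes": sizes.to_dict(),
        }
    return out


@dataclass
class StabilityReport:
    n_resamples: int
    k: int
    per_cluster: np.ndarray        # (k,) mean Jaccard per original cluster
    overall: float                 # unweighted mean across clusters
    per_resample: np.ndarray       # (n_resamples, k), NaN where skipped
    n_skipped: int


DEFAULT_BOOTSTRAP_CONFIG = {
    "n_restarts": 10,
    "iterations": 500,
    "lr_start": 0.05,
    "lr_end": 0.01,
    "sigma_start": None,
    "layer_weights": None,
}


def _cluster_subjects(cohort: pd.DataFrame, grid: SOMGrid, k: int,
                      config: dict, seed) -> np.ndarray:
    """scaling -> SOM (restart_best) -> Ward -> cut at k, returning
    subject labels for the rows of ``cohort``."""
    layers = preprocess.scale_features(cohort)
    model = som.restart_best(
        layers, grid,
        n_restarts=config["n_restarts"],
        seed=seed,
        iterations=config["iterations"],
        lr_start=config["lr_start"],
        lr_end=config["lr_end"],
        sigma_start=config["sigma_start"],
        layer_weights=config["layer_weights"],
    )
    tree = ward_tree(model)
    bmu, _ = som.map_subjects(model, layers)
    return tree.cut(k)[bmu]


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return float("nan")
    return len(a & b) / len(a | b)


def bootstrap_stability(
    cohort: pd.DataFrame,
    grid: SOMGrid,
    k: int,
    n_resamples: int = 100,
    seed=0,
    pipeline_config: dict | None = None,
    reference_labels: np.ndarray | None = None,
    indices: np.ndarray | None = None,
) -> StabilityReport:
    """Clusterwise Jaccard stability over bootstrap resamples.

    Each resample draws subjects with replacement, reruns the full
    scaling -> SOM -> Ward -> cut-at-k procedure (with the reduced restart
    count of ``pipeline_config``), and matches every original cluster to
    its maximum-Jaccard resample cluster over the subjects present in the
    resample. Deterministic given ``seed``.

    ``indices`` (n_resamples, n) overrides the drawn resample indices — a
    testing hook to force particular resamples.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    config = {**DEFAULT_BOOTSTRAP_CONFIG, **(pipeline_config or {})}
    n = len(cohort)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ref_seed, *resample_seeds = ss.spawn(n_resamples + 1)

    if reference_labels is None:
        reference_labels = _cluster_subjects(cohort, grid, k, config, ref_seed)
    reference_labels = np.asarray(reference_labels)
    orig_sets = [set(np.flatnonzero(reference_labels == c)) for c in range(k)]

    per_resample = np.full((n_resamples, k), np.nan)
    n_skipped = 0
    for r, child in enumerate(resample_seeds):
        idx_seed, som_seed = child.spawn(2)
        if indices is not None:
            idx = np.asarray(indices[r])
        else:
            idx = np.random.default_rng(idx_seed).integers(0, n, size=n)
        resample = cohort.iloc[idx].reset_index(drop=True)
        try:
            labels = _cluster_subjects(resample, grid, k, config, som_seed)
        except ValueError:
            n_skipped += 1
            continue
        if len(np.unique(labels)) < k:
            n_skipped += 1
            continue
        # map back to original subject positions (first occurrence wins;
        # duplicated rows have identical features, hence identical labels)
        present = {}
        for pos_in_resample, orig_pos in enumerate(idx):
            if orig_pos not in present:
                present[orig_pos] = labels[pos_in_resample]
        in_resample = set(present)
        resample_sets: dict = {}
        for orig_pos, lab in present.items():
            resample_sets.setdefault(lab, set()).add(orig_pos)
        for c in range(k):
            restricted = orig_sets[c] & in_resample
            if not restricted:
                continue
            per_resample[r, c] = max(
                _jaccard(restricted, b) for b in resample_sets.values()
            )

    with np.errstate(invalid="ignore"):
        per_cluster = np.nanmean(per_resample, axis=0)
    overall = float(np.nanmean(per_cluster))
    return StabilityReport(
        n_resamples=n_resamples,
        k=k,
        per_cluster=per_cluster,
        overall=overall,
        per_resample=per_resample,
        n_skipped=n_skipped,
    )
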