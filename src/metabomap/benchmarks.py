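"""Planted-recovery benchmarks: run the full pipeline on synthetic
two-archetype cohorts and measure how well the planted structure is
recovered. Used by the acceptance checks; everything is recomputed from
scratch at call time.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from metabomap import clustering, preprocess, som
from metabomap import synthetic_cohort as sc


def make_two_archetype_cohort(n_subjects: int = 1000,
                              separation: float = 3.0, seed=0):
    """Clean (no missingness/medication) two-archetype cohort with the
    planted pooled-SD separation on the insulin axis."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    cfg = sc.GeneratorConfig(
        n_subjects=n_subjects,
        archetypes=tuple(sc.separated_pair(separation)),
        seed=int(ss.generate_state(1)[0]),
    )
    return sc.generate_cohort(cfg)


def planted_recovery(
    seed,
    n_subjects: int = 1000,
    separation: float = 3.0,
    n_restarts: int = 20,
    iterations: int = 500,
    k_range=clustering.DEFAULT_K_RANGE,
) -> dict:
    """One full pipeline pass: generate -> exclude -> scale -> SOM
    (restart_best) -> Ward -> silhouette choice of K -> ARI of the K=2
    partition against the planted labels."""
    gen_ss, som_ss = np.random.SeedSequence(seed).spawn(2)
    cohort = make_two_archetype_cohort(n_subjects, separation, gen_ss)
    retained, _ = preprocess.apply_exclusions(cohort)
    layers = preprocess.scale_features(retained)
    grid = som.build_grid(3, 9)
    model = som.restart_best(
        layers, grid, n_restarts=n_restarts, seed=som_ss,
        iterations=iterations,
    )
    tree = clustering.ward_tree(model)
    optimal_k = clustering.choose_k(tree, model, k_range)
    bmu, _ = som.map_subjects(model, layers)
    labels_k2 = tree.cut(2)[bmu]
    truth = (retained["true_archetype"] == retained["true_archetype"].iloc[0])
    ari = float(adjusted_rand_score(truth.astype(int), labels_k2))
    return {
        "optimal_k": optimal_k,
        "ari_k2": ari,
        "silhouette_by_k": dict(tree.silhouette_by_k),
        "quantization_error": model.quantization_error,
        "n_subjects": len(retained),
    }


def stability_floor(
    seed,
    n_subjects: int = 1000,
    separation: float = 3.0,
    n_resamples: int = 100,
    bootstrap_restarts: int = 10,
    iterations: int = 500,
    reference_restarts: int = 20,
) -> clustering.StabilityReport:
    """Bootstrap clusterwise Jaccard stability of the K=2 partition on the
    standard two-archetype cohort."""
    gen_ss, ref_ss, boot_ss = np.random.SeedSequence(seed).spawn(3)
    cohort = make_two_archetype_cohort(n_subjects, separation, gen_ss)
    retained, _ = preprocess.apply_exclusions(cohort)
    grid = som.build_grid(3, 9)

    # reference partition from the main (higher-restart) analysis
    layers = preprocess.scale_features(retained)
    model = som.restart_best(
        layers, grid, n_restarts=reference_restarts, seed=ref_ss,
        iterations=iterations,
    )
    tree = clustering.ward_tree(model)
    bmu, _ = som.map_subjects(model, layers)
    reference = tree.cut(2)[bmu]

    return clustering.bootstrap_stability(
        retained, grid, k=2,
        n_resamples=n_resamples,
        seed=boot_ss,
        pipeline_config={
            "n_restarts": bootstrap_restarts,
            "iterations": iterations,
        },
        reference_labels=reference,
    )
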