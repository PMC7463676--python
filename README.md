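# metabomap

Metabolic phenotype stratification from OGTT cohort tables: derived
insulin-resistance / secretion / clearance indexes, a from-scratch
multilayer self-organizing map on a toroidal hexagonal grid, Ward
hierarchical clustering with silhouette model selection and bootstrap
Jaccard stability, and percentile-band cluster profiling (the cluster
"footprint").

Because no public cohort exists for this analysis, the package ships a
first-class synthetic cohort generator with planted metabolic archetypes
(normometabolic, insulin-resistant hyperinsulinemic, insulin-deficient
high-clearance, hyperinsulinemic low-clearance) so that every pipeline
stage is testable end to end, including planted-structure recovery.

## Layout

| module | role |
| --- | --- |
| `metabomap.synthetic_cohort` | archetype mixture generator; log-normal OGTT trajectories with within-subject correlation, missingness, medication flags |
| `metabomap.indexes` | AUCs, HOMA (pluggable backend), Matsuda, IGI/DI, tissue-specific IR, insulin clearance, fatty-liver scores, CKD-EPI eGFR, WHO glycemia classes |
| `metabomap.preprocess` | medication/missingness exclusions; five 3-variable feature layers; gender-wise min-max for BMI/waist, z-scores elsewhere |
| `metabomap.som` | 27-unit toroidal hexagonal SOM, five codebook layers, sequential training with linear annealing, restarts, quantization error |
| `metabomap.clustering` | Ward tree over SOM units, cut-level partitions, silhouette choice of K, bootstrap clusterwise Jaccard stability |
| `metabomap.profiling` | population percentiles, cluster-median band assignment, dysglycemia composition, radar footprint, gender comparisons |
| `metabomap.pipeline` | end-to-end orchestration with deterministic text artifacts and a hash manifest |
| `metabomap.benchmarks` | planted-recovery and stability benchmarks used by the acceptance checks |

## CLI

```sh
# generate a synthetic cohort (two archetypes, 3 pooled-SD separation)
metabomap simulate --n 1000 --seed 7 --separation 3.0 --out cohort.csv

# derived metabolic index panel (after exclusions)
metabomap indexes cohort.csv --out panel.csv --units-out units.tsv

# full analysis: exclusions -> indexes -> SOM -> Ward -> profiling
metabomap cluster cohort.csv --seed 7 --restarts 100 --bootstrap 100 \
    --cuts 2,11,27 --by-gender --out runs/demo

# end to end from a YAML config (generator defaults if no input given)
metabomap run --config config.yaml --seed 7 --out runs/demo
```

`--full` switches to the reference-scale 1000 SOM restarts. Every run
writes the resolved config, per-stage tables (assignments, codebooks,
silhouette-by-K, profiles, footprint coordinates, dysglycemia composition),
the unit dendrogram as newick text, and a `manifest.json` with SHA-256
hashes; identical config + seed reproduces every artifact byte for byte.

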