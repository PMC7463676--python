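import numpy as np
import pytest

from metabomap import preprocess, som
from metabomap import synthetic_cohort as sc


@pytest.fixture(scope="session")
def grid():
    return som.build_grid(3, 9)


@pytest.fixture(scope="session")
def two_archetype_cohort():
    """n=600 strongly separated two-archetype cohort (clean: no missing,
    no medication) reused across SOM/clustering tests."""
    cfg = sc.GeneratorConfig(
        n_subjects=600, archetypes=tuple(sc.separated_pair(3.0)), seed=20240901
    )
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def two_archetype_layers(two_archetype_cohort):
    retained, _ = preprocess.apply_exclusions(two_archetype_cohort)
    return preprocess.scale_features(retained)


@pytest.fixture(scope="session")
def trained_model(two_archetype_layers, grid):
    """A short-but-real training run shared by downstream tests."""
    return som.train_som(two_archetype_layers, grid, iterations=60, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = sc.GeneratorConfig(
        n_subjects=800, archetypes=tuple(sc.default_archetypes()),
        missing_rate=0.05, medicated_rate=0.06, seed=99,
    )
    return sc.generate_cohort(cfg)
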