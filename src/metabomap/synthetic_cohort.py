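"""Synthetic OGTT cohort generator with planted metabolic archetypes.

Emits cohort tables with the structure the downstream analysis expects:
per-subject anthropometry, glucose / insulin / C-peptide / FFA at the
0, 30 and 120 min OGTT time points, HbA1c, lipids, creatinine, optional
fat-mass % and blood pressure, a medication flag, and the (generator-only)
planted archetype label.

Concentration marginals are log-normal — parameterised so the archetype's
stated central value is the *median* of the marginal — with an AR(1)-like
correlation linking the three time points of each analyte on the log scale.
Anthropometrics and age are truncated normal. The planted label
``true_archetype`` is written by the generator and never read back by the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

#: analytes measured at the three OGTT time points
OGTT_ANALYTES = ("glucose", "insulin", "cpeptide", "ffa")
OGTT_TIMES = (0, 30, 120)

#: variables whose marginals are log-normal
_LOGNORMAL_SCALARS = ("hba1c", "tg", "hdl", "creatinine")
#: variables drawn from truncated normals, with plausibility bounds
_TRUNCNORM_BOUNDS = {
    "age": (18.0, 95.0),
    "bmi": (15.0, 55.0),
    "waist": (55.0, 160.0),
    "fat_mass_pct": (5.0, 60.0),
    "sbp": (80.0, 230.0),
    "dbp": (40.0, 140.0),
}

_HEIGHT_BY_SEX = {"male": (1.72, 0.07), "female": (1.61, 0.065)}
_HEIGHT_BOUNDS = (1.2, 2.2)

#: the 15 variables that inform the clustering algorithm
CLUSTERING_VARIABLES = tuple(
    f"{a}_{t}" for a in OGTT_ANALYTES for t in OGTT_TIMES
) + ("age", "bmi", "waist")

#: fixed output column order of a cohort table
COHORT_COLUMNS = (
    ["id", "sex", "age", "weight", "height", "bmi", "waist"]
    + [f"{a}_{t}" for a in OGTT_ANALYTES for t in OGTT_TIMES]
    + ["hba1c", "tg", "hdl", "creatinine", "fat_mass_pct", "sbp", "dbp",
       "on_medication", "true_archetype"]
)

_ALL_MEAN_KEYS = tuple(
    [f"{a}_{t}" for a in OGTT_ANALYTES for t in OGTT_TIMES]
    + ["age", "bmi", "waist"]
    + list(_LOGNORMAL_SCALARS)
    + ["fat_mass_pct", "sbp", "dbp"]
)


@dataclass(frozen=True)
class Archetype:
    """One metabolic phenotype of the mixture.

    ``means`` holds the central value (median) of every generated variable;
    ``cvs`` the coefficient of variation; ``ogtt_rho`` the AR(1) correlation
    between adjacent OGTT time points on the log scale.
    """

    name: str
    prevalence: float
    means: dict = field(default_factory=dict)
    cvs: dict = field(default_factory=dict)
    ogtt_rho: float = 0.6

    def within_subject_corr(self) -> np.ndarray:
        """3x3 AR(1) correlation matrix across the OGTT time points."""
        r = self.ogtt_rho
        return np.array([[1.0, r, r * r], [r, 1.0, r], [r * r, r, 1.0]])

    def validate(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")
        missing = [k for k in _ALL_MEAN_KEYS if k not in self.means]
        if missing:
            raise ValueError(f"archetype {self.name!r} lacks means for {missing}")
        for key, value in self.means.items():
            if value <= 0:
                raise ValueError(f"non-positive mean {key}={value} in {self.name!r}")
        for key in _ALL_MEAN_KEYS:
            if self.cvs.get(key, 0.0) < 0:
                raise ValueError(f"negative CV for {key} in {self.name!r}")
        eigvals = np.linalg.eigvalsh(self.within_subject_corr())
        if eigvals.min() < -1e-12:
            raise ValueError(
                f"within-subject correlation of {self.name!r} is not PSD"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int
    archetypes: tuple
    female_fraction: float = 0.6
    missing_rate: float = 0.0
    medicated_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if not self.archetypes:
            raise ValueError("at least one archetype required")
        for a in self.archetypes:
            a.validate()
        total = sum(a.prevalence for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype prevalences sum to {total}, not 1")
        for name in ("female_fraction", "missing_rate", "medicated_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


_DEFAULT_CVS = {
    **{f"glucose_{t}": 0.12 for t in OGTT_TIMES},
    **{f"insulin_{t}": 0.40 for t in OGTT_TIMES},
    **{f"cpeptide_{t}": 0.32 for t in OGTT_TIMES},
    **{f"ffa_{t}": 0.35 for t in OGTT_TIMES},
    "age": 0.17, "bmi": 0.12, "waist": 0.10,
    "hba1c": 0.06, "tg": 0.45, "hdl": 0.22, "creatinine": 0.18,
    "fat_mass_pct": 0.20, "sbp": 0.12, "dbp": 0.10,
}

# central values of the reference (normometabolic) phenotype: population
# medians of a middle-aged European screening cohort
_NORMO_MEANS = {
    "glucose_0": 5.46, "glucose_30": 9.16, "glucose_120": 6.58,
    "insulin_0": 43.1, "insulin_30": 318.0, "insulin_120": 238.0,
    "cpeptide_0": 0.68, "cpeptide_30": 2.09, "cpeptide_120": 2.59,
    "ffa_0": 0.48, "ffa_30": 0.33, "ffa_120": 0.12,
    "age": 62.0, "bmi": 27.0, "waist": 96.0,
    "hba1c": 5.5, "tg": 100.0, "hdl": 55.0, "creatinine": 0.80,
    "fat_mass_pct": 30.0, "sbp": 124.0, "dbp": 76.0,
}


def default_archetypes() -> list[Archetype]:
    """Four named archetypes spanning the canonical dysmetabolism axes.

    The normometabolic archetype sits at the reference cohort medians; the
    other three displace insulin action, secretion and clearance in the
    directions that dominate metabolic heterogeneity.
    """
    normo = Archetype("normometabolic", 0.55, dict(_NORMO_MEANS), dict(_DEFAULT_CVS))

    ir = Archetype(
        "insulin_resistant_hyperinsulinemic", 0.25,
        {**_NORMO_MEANS,
         "glucose_0": 6.2, "glucose_30": 10.6, "glucose_120": 8.6,
         "insulin_0": 130.0, "insulin_30": 920.0, "insulin_120": 760.0,
         "cpeptide_0": 1.15, "cpeptide_30": 3.3, "cpeptide_120": 4.4,
         "ffa_0": 0.56, "ffa_30": 0.42, "ffa_120": 0.20,
         "bmi": 32.0, "waist": 107.0, "hba1c": 5.9,
         "tg": 175.0, "hdl": 43.0, "fat_mass_pct": 38.0,
         "sbp": 134.0, "dbp": 82.0},
        dict(_DEFAULT_CVS),
    )

    deficient = Archetype(
        "insulin_deficient_high_clearance", 0.12,
        {**_NORMO_MEANS,
         "glucose_0": 6.3, "glucose_30": 11.2, "glucose_120": 9.2,
         "insulin_0": 27.0, "insulin_30": 140.0, "insulin_120": 120.0,
         "cpeptide_0": 0.58, "cpeptide_30": 1.45, "cpeptide_120": 1.80,
         "ffa_0": 0.52, "ffa_30": 0.38, "ffa_120": 0.16,
         "bmi": 24.5, "waist": 90.0, "hba1c": 5.8},
        dict(_DEFAULT_CVS),
    )

    low_clearance = Archetype(
        "hyperinsulinemic_low_clearance", 0.08,
        {**_NORMO_MEANS,
         "glucose_0": 5.8, "glucose_30": 10.0, "glucose_120": 7.6,
         "insulin_0": 110.0, "insulin_30": 720.0, "insulin_120": 560.0,
         "cpeptide_0": 0.72, "cpeptide_30": 2.1, "cpeptide_120": 2.5,
         "bmi": 30.0, "waist": 103.0, "tg": 150.0,
         "fat_mass_pct": 36.0},
        dict(_DEFAULT_CVS),
    )

    return [normo, ir, deficient, low_clearance]


def pooled_sd_separation(a: Archetype, b: Archetype, variable: str) -> float:
    """|mean difference| / pooled SD of ``variable`` between two archetypes.

    SDs follow the log-normal moments implied by each archetype's central
    value m and CV c: median m, sd = m * sqrt(1 + c^2) * c (sd of a
    log-normal with median m and CV c).
    """

    def _sd(arch: Archetype) -> float:
        m, c = arch.means[variable], arch.cvs.get(variable, _DEFAULT_CVS[variable])
        return m * math.sqrt(1.0 + c * c) * c

    pooled = math.sqrt((_sd(a) ** 2 + _sd(b) ** 2) / 2.0)
    return abs(a.means[variable] - b.means[variable]) / pooled


def separated_pair(separation: float = 3.0) -> list[Archetype]:
    """Two archetypes — normometabolic vs insulin-resistant — with the
    insulin means (and the co-moving glucose/C-peptide/anthropometry)
    separated by ``separation`` pooled SDs.

    Used as the planted-recovery benchmark: the downstream pipeline should
    recover K=2 and match the planted labels.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    base = default_archetypes()[0]
    normo = replace(base, prevalence=0.5)

    shifted_vars = [f"insulin_{t}" for t in OGTT_TIMES]
    shifted_vars += [f"cpeptide_{t}" for t in OGTT_TIMES]
    shifted_vars += [f"glucose_{t}" for t in OGTT_TIMES]
    shifted_vars += ["bmi", "waist", "tg", "fat_mass_pct"]

    means = dict(normo.means)
    for var in shifted_vars:
        m = means[var]
        c = normo.cvs[var]
        sd0 = m * math.sqrt(1.0 + c * c) * c
        m2 = m
        for _ in range(50):  # fixed-point: separation in pooled-SD units
            sd2 = m2 * math.sqrt(1.0 + c * c) * c
            m2 = m + separation * math.sqrt((sd0 * sd0 + sd2 * sd2) / 2.0)
        means[var] = m2
    ir = Archetype("insulin_resistant", 0.5, means, dict(normo.cvs))
    return [normo, ir]


def _lognormal_params(median: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with given median and CV."""
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.log(median), sigma


def _draw_ogtt_block(
    rng: np.random.Generator, arch: Archetype, n: int, analyte: str
) -> np.ndarray:
    """(n, 3) correlated log-normal draws of one analyte across time points."""
    corr = arch.within_subject_corr()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ chol.T
    out = np.empty((n, 3))
    for j, t in enumerate(OGTT_TIMES):
        mu, sigma = _lognormal_params(
            arch.means[f"{analyte}_{t}"], arch.cvs[f"{analyte}_{t}"]
        )
        out[:, j] = np.exp(mu + sigma * z[:, j])
    return out


def _draw_truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lo: float, hi: float,
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort table. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    prevalences = np.array([a.prevalence for a in config.archetypes])
    arch_idx = rng.choice(len(config.archetypes), size=n, p=prevalences)
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")

    data = {col: np.full(n, np.nan) for col in COHORT_COLUMNS[2:-2]}
    for i, arch in enumerate(config.archetypes):
        mask = arch_idx == i
        m = int(mask.sum())
        if m == 0:
            continue
        for analyte in OGTT_ANALYTES:
            block = _draw_ogtt_block(rng, arch, m, analyte)
            for j, t in enumerate(OGTT_TIMES):
                data[f"{analyte}_{t}"][mask] = block[:, j]
        for var in _LOGNORMAL_SCALARS:
            mu, sigma = _lognormal_params(arch.means[var], arch.cvs[var])
            data[var][mask] = rng.lognormal(mu, sigma, size=m)
        for var, (lo, hi) in _TRUNCNORM_BOUNDS.items():
            mean = arch.means[var]
            sd = max(mean * arch.cvs[var], 1e-9)
            data[var][mask] = _draw_truncnorm(rng, m, mean, sd, lo, hi)

    height = np.empty(n)
    for s, (mean, sd) in _HEIGHT_BY_SEX.items():
        mask = sex == s
        height[mask] = _draw_truncnorm(
            rng, int(mask.sum()), mean, sd, *_HEIGHT_BOUNDS
        )
    data["height"] = height
    data["weight"] = data["bmi"] * height**2

    on_medication = rng.random(n) < config.medicated_rate

    # inject missingness: one OGTT clustering variable per selected subject
    missing_subjects = np.flatnonzero(rng.random(n) < config.missing_rate)
    ogtt_cols = [f"{a}_{t}" for a in OGTT_ANALYTES for t in OGTT_TIMES]
    which = rng.integers(0, len(ogtt_cols), size=missing_subjects.size)
    for subj, col_i in zip(missing_subjects, which):
        data[ogtt_cols[col_i]][subj] = np.nan

    table = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            **{k: data[k] for k in COHORT_COLUMNS[2:-2]},
            "on_medication": on_medication,
            "true_archetype": [config.archetypes[i].name for i in arch_idx],
        }
    )
    return table[list(COHORT_COLUMNS)]


def write_cohort(table: pd.DataFrame, path) -> None:
    """UTF-8 CSV, empty cell = missing, fixed column order."""
    table[list(COHORT_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS[:-1] if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    return table
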