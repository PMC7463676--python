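"""Percentile-band cluster profiling and the radar-plot footprint.

Each cluster's per-variable median is placed against the overall
population's 10th/25th/75th/90th percentiles, giving an ordinal band:

    0: < p10   1: [p10, p25)   2: [p25, p75]   3: (p75, p90]   4: > p90

Boundary ties resolve toward the middle band (the 25th-75th interval holds
the accepted normal range). The footprint maps bands to radial coordinates
in [0, 1], reversing variables where *low* is the adverse direction, and
groups variables into milieu / mechanisms / pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PERCENTILES = (10.0, 25.0, 75.0, 90.0)
BIN_LABELS = ("<p10", "p10-p25", "p25-p75", "p75-p90", ">p90")

#: variables where a LOW value is the adverse direction; their footprint
#: radius is reversed so larger radius always means more adverse.
DEFAULT_ADVERSE_LOW = frozenset({
    "matsuda", "isi_ffa", "di", "igi", "delta_cpep_glu_030",
    "ratio_cpep_glu_030", "ratio_ins_glu_030", "homa_b",
    "ic_fast", "ic_120", "egfr", "hdl",
})

#: default milieu / mechanisms / pathology grouping of profiled variables
DEFAULT_GROUPING = {
    "milieu": (
        "glucose_0", "glucose_30", "glucose_120", "auc_glucose", "hba1c",
        "insulin_0", "insulin_30", "insulin_120", "auc_insulin",
        "cpeptide_0", "cpeptide_30", "cpeptide_120", "auc_cpeptide",
        "ffa_0", "ffa_30", "ffa_120", "auc_ffa",
        "age", "bmi", "waist", "tg", "hdl",
    ),
    "mechanisms": (
        "homa_b", "homa_ir", "ratio_cpep_glu_030", "ratio_ins_glu_030",
        "igi", "delta_cpep_glu_030", "di", "matsuda",
        "liver_ir", "hepatic_ir", "adipo_ir", "isi_ffa",
        "ic_fast", "ic_delta_030", "ic_120",
    ),
    "pathology": ("nafld_fls", "fli", "egfr", "mets_idf"),
}


def population_percentiles(table: pd.DataFrame, variables=None,
                           min_n: int = 10) -> pd.DataFrame:
    """p10/p25/p75/p90 per variable over all subjects, missing skipped;
    linear interpolation between order statistics."""
    if variables is None:
        variables = [
            c for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c]) and c != "id"
        ]
    rows = {}
    for var in variables:
        values = table[var].to_numpy(float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"variable {var!r} is entirely missing")
        if values.size < min_n:
            raise ValueError(
                f"variable {var!r} has {values.size} values; need >= {min_n}"
            )
        rows[var] = np.percentile(values, PERCENTILES, method="linear")
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{int(p)}" for p in PERCENTILES]
    )
    out.index.name = "variable"
    return out


def assign_bin(median: float, p10: float, p25: float, p75: float,
               p90: float) -> int:
    """Ordinal band of a cluster median; ties resolve toward the middle."""
    if np.isnan(median):
        return -1
    if p25 <= median <= p75:
        return 2
    if median < p10:
        return 0
    if median < p25:
        return 1
    if median <= p90:
        return 3
    return 4


@dataclass
class ProfileMatrix:
    """Cluster-by-variable percentile-band table for one cut level."""

    medians: pd.DataFrame        # variables x clusters, raw cluster medians
    bins: pd.DataFrame           # variables x clusters, ordinal band 0..4
    percentiles: pd.DataFrame    # variables x (p10, p25, p75, p90)
    stratum: str = "all"
    cluster_sizes: dict = field(default_factory=dict)


def profile_clusters(
    assignment: np.ndarray,
    table: pd.DataFrame,
    percentiles: pd.DataFrame,
    stratum: str = "all",
    sex: np.ndarray | None = None,
    allow_empty: bool = False,
) -> ProfileMatrix:
    """Profile each cluster against the population percentile bands.

    ``assignment``: subject -> cluster labels aligned with ``table`` rows.
    ``stratum``: 'all', 'male' or 'female' (requires ``sex``).
    ``allow_empty``: clusters with no subjects in the stratum get NaN
    medians and bin -1 instead of raising (fine cuts within one gender).
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(table):
        raise ValueError("assignment does not cover the table")
    mask = np.ones(len(table), dtype=bool)
    if stratum != "all":
        if sex is None:
            raise ValueError("sex vector required for gender strata")
        mask = np.asarray(sex) == stratum
    variables = list(percentiles.index)
    clusters = sorted(np.unique(assignment))
    medians = pd.DataFrame(index=variables, columns=clusters, dtype=float)
    bins = pd.DataFrame(index=variables, columns=clusters, dtype=int)
    sizes = {}
    for c in clusters:
        sel = (assignment == c) & mask
        if not sel.any():
            if not allow_empty:
                raise ValueError(f"empty cluster {c} in stratum {stratum!r}")
            sizes[c] = 0
            medians[c] = np.nan
            bins[c] = -1
            continue
        sizes[c] = int(sel.sum())
        sub = table.loc[sel]
        for var in variables:
            med = float(np.nanmedian(sub[var].to_numpy(float))) \
                if sub[var].notna().any() else float("nan")
            medians.loc[var, c] = med
            bins.loc[var, c] = assign_bin(med, *percentiles.loc[var])
    return ProfileMatrix(
        medians=medians, bins=bins, percentiles=percentiles,
        stratum=stratum, cluster_sizes=sizes,
    )


def dysglycemia_composition(assignment: np.ndarray,
                            glycemia_class: np.ndarray) -> pd.DataFrame:
    """Counts and fractions of each dysglycemia class per cluster."""
    from metabomap.indexes import GLYCEMIA_CLASSES

    df = pd.DataFrame({
        "cluster": np.asarray(assignment),
        "class": np.asarray(glycemia_class, dtype=object),
    })
    counts = (
        df.groupby(["cluster", "class"], observed=True).size().unstack(fill_value=0)
    )
    for cls in GLYCEMIA_CLASSES:
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[list(GLYCEMIA_CLASSES)]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.columns = [f"frac_{c}" for c in fractions.columns]
    return pd.concat([counts, fractions], axis=1)


@dataclass
class Footprint:
    """Radial footprint coordinates per cluster, grouped by function."""

    radial: pd.DataFrame     # variables x clusters, in [0, 1]
    groups: dict             # variable -> group name


def footprint(profile: ProfileMatrix, grouping: dict | None = None,
              adverse_low=DEFAULT_ADVERSE_LOW) -> Footprint:
    """Map ordinal bands to radii {0, .25, .5, .75, 1}; adverse-low
    variables are reversed so a larger radius is always more adverse."""
    grouping = grouping or DEFAULT_GROUPING
    var_group = {}
    for group, variables in grouping.items():
        for var in variables:
            var_group[var] = group
    ungrouped = [v for v in profile.bins.index if v not in var_group]
    if ungrouped:
        raise ValueError(f"ungrouped profiling variables: {ungrouped}")

    radial = profile.bins.astype(float) / 4.0
    for var in profile.bins.index:
        if var in adverse_low:
            radial.loc[var] = 1.0 - radial.loc[var]
    radial = radial.clip(0.0, 1.0)
    return Footprint(radial=radial, groups=var_group)


def gender_compare(cohort: pd.DataFrame, panel: pd.DataFrame | None = None,
                   categorical=("glycemia_class", "on_medication")) -> pd.DataFrame:
    """Per-variable two-sided Mann-Whitney (continuous) or chi-square
    (categorical) comparison between genders; unadjusted p-values."""
    sex = cohort["sex"].to_numpy()
    if len(np.unique(sex)) < 2:
        raise ValueError("both genders required")
    table = cohort if panel is None else cohort.join(
        panel.drop(columns=["id"], errors="ignore")
    )
    rows = []
    for col in table.columns:
        if col in ("id", "sex", "true_archetype"):
            continue
        values = table[col]
        if col in categorical or not pd.api.types.is_numeric_dtype(values):
            contingency = pd.crosstab(sex, values.astype(str))
            if contingency.shape[1] < 2:
                continue
            stat, p, _, _ = stats.chi2_contingency(contingency)
            kind = "chi-square"
        else:
            male = values[sex == "male"].dropna()
            female = values[sex == "female"].dropna()
            if len(male) == 0 or len(female) == 0:
                continue
            stat, p = stats.mannwhitneyu(male, female, alternative="two-sided")
            kind = "mann-whitney"
        rows.append({"variable": col, "test": kind, "statistic": float(stat),
                     "p_value": float(p)})
    return pd.DataFrame(rows).set_index("variable")
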