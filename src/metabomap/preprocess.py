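"""Cohort exclusions and clustering-feature construction.

Exclusion order mirrors the analysis protocol: medicated subjects first,
then subjects missing any of the 15 clustering variables; subjects carrying
both flags are counted once, under medication. Outliers are retained.

The clustering features form five 3-variable layers: one per OGTT analyte
(glucose, C-peptide, insulin, FFA at 0/30/120 min) plus an anthropometric
layer (age, BMI, waist). BMI and waist are min-max scaled within gender;
every other variable is z-standardized over the fit data. Scaling
parameters are stored so resamples can be transformed or refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metabomap.synthetic_cohort import CLUSTERING_VARIABLES, OGTT_TIMES

LAYER_NAMES = ("glucose", "cpeptide", "insulin", "ffa", "anthropometric")

LAYER_VARIABLES = {
    "glucose": tuple(f"glucose_{t}" for t in OGTT_TIMES),
    "cpeptide": tuple(f"cpeptide_{t}" for t in OGTT_TIMES),
    "insulin": tuple(f"insulin_{t}" for t in OGTT_TIMES),
    "ffa": tuple(f"ffa_{t}" for t in OGTT_TIMES),
    "anthropometric": ("age", "bmi", "waist"),
}

#: variables min-max scaled within gender instead of z-standardized
GENDER_MINMAX_VARIABLES = ("bmi", "waist")


@dataclass
class ExclusionReport:
    n_input: int
    n_medicated: int
    n_missing: int
    n_retained: int


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop medicated subjects, then subjects with missing clustering data."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    medicated = cohort["on_medication"].astype(bool).to_numpy()
    missing_any = cohort[list(CLUSTERING_VARIABLES)].isna().any(axis=1).to_numpy()
    n_med = int(medicated.sum())
    n_missing = int((missing_any & ~medicated).sum())
    keep = ~medicated & ~missing_any
    retained = cohort.loc[keep].reset_index(drop=True)
    report = ExclusionReport(
        n_input=len(cohort),
        n_medicated=n_med,
        n_missing=n_missing,
        n_retained=len(retained),
    )
    return retained, report


@dataclass
class ScalingParams:
    """Per-variable transforms fitted on the post-exclusion cohort."""

    zscore: dict = field(default_factory=dict)       # var -> (mean, std)
    minmax: dict = field(default_factory=dict)       # (sex, var) -> (min, max)

    def transform_column(self, var: str, values: np.ndarray,
                         sex: np.ndarray | None = None) -> np.ndarray:
        if var in GENDER_MINMAX_VARIABLES:
            out = np.empty_like(values, dtype=float)
            for s in ("male", "female"):
                lo, hi = self.minmax[(s, var)]
                mask = sex == s
                out[mask] = (values[mask] - lo) / (hi - lo)
            return out
        mean, std = self.zscore[var]
        return (values - mean) / std

    def inverse_transform_column(self, var: str, values: np.ndarray,
                                 sex: np.ndarray | None = None) -> np.ndarray:
        if var in GENDER_MINMAX_VARIABLES:
            out = np.empty_like(values, dtype=float)
            for s in ("male", "female"):
                lo, hi = self.minmax[(s, var)]
                mask = sex == s
                out[mask] = values[mask] * (hi - lo) + lo
            return out
        mean, std = self.zscore[var]
        return values * std + mean


@dataclass
class FeatureLayers:
    """Five named (n, 3) feature blocks plus ids and scaling metadata."""

    ids: np.ndarray
    sex: np.ndarray
    layers: dict                      # name -> (n, 3) float array
    params: ScalingParams

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    def stacked(self) -> np.ndarray:
        """(n, 15) concatenation in LAYER_NAMES order."""
        return np.hstack([self.layers[name] for name in LAYER_NAMES])


def fit_scaling(cohort: pd.DataFrame) -> ScalingParams:
    params = ScalingParams()
    sex = cohort["sex"].to_numpy()
    for var in CLUSTERING_VARIABLES:
        values = cohort[var].to_numpy(float)
        if var in GENDER_MINMAX_VARIABLES:
            for s in ("male", "female"):
                group = values[sex == s]
                if group.size == 0:
                    raise ValueError(f"no {s} subjects for gender-wise scaling")
                lo, hi = float(group.min()), float(group.max())
                if hi - lo <= 0:
                    raise ValueError(
                        f"zero range for {var} in {s} group; cannot min-max scale"
                    )
                params.minmax[(s, var)] = (lo, hi)
        else:
            mean, std = float(values.mean()), float(values.std(ddof=0))
            if std <= 0:
                raise ValueError(f"constant clustering variable {var}")
            params.zscore[var] = (mean, std)
    return params


def scale_features(cohort: pd.DataFrame,
                   params: ScalingParams | None = None) -> FeatureLayers:
    """Build the five clustering layers; fit scaling unless params given."""
    if cohort[list(CLUSTERING_VARIABLES)].isna().any().any():
        raise ValueError("missing clustering variables; run apply_exclusions first")
    if params is None:
        params = fit_scaling(cohort)
    sex = cohort["sex"].to_numpy()
    layers = {}
    for name in LAYER_NAMES:
        cols = []
        for var in LAYER_VARIABLES[name]:
            cols.append(
                params.transform_column(var, cohort[var].to_numpy(float), sex)
            )
        layers[name] = np.column_stack(cols)
    return FeatureLayers(
        ids=cohort["id"].to_numpy(), sex=sex, layers=layers, params=params
    )
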