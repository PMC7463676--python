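"""OGTT-derived metabolic and functional indexes.

All functions accept scalars or numpy arrays and propagate NaN for missing
inputs; values that are mathematically undefined for a subject (zero glucose
excursion, fasting glucose at or below the beta-cell model floor, a
non-positive argument to a logarithm) come back as NaN rather than raising.

Expected input units follow the cohort table convention:
glucose mmol/L, insulin pmol/L, C-peptide nmol/L, FFA mmol/L, TG and HDL-c
mg/dL, creatinine mg/dL, waist cm, HbA1c %.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

# ---- unit conversion layer -------------------------------------------------

GLUCOSE_MMOL_TO_MGDL = 18.016
INSULIN_PMOL_PER_MIU = 6.0  # pmol/L per mIU/L (uIU/mL)
CPEPTIDE_NMOL_TO_PMOL = 1000.0

#: scale constants making the FFA-based sensitivity index O(1); the source
#: formula is scale-sensitive and printed without units, so these are
#: configurable module constants.
ISI_FFA_INSULIN_AUC_SCALE = 1e-4   # applied to insulin AUC in pmol/L*min
ISI_FFA_FFA_AUC_SCALE = 1.0 / 30.0  # applied to FFA AUC in mmol/L*min


def insulin_to_miu(insulin_pmol):
    """pmol/L -> mIU/L (uIU/mL)."""
    return np.asarray(insulin_pmol, dtype=float) / INSULIN_PMOL_PER_MIU


def glucose_to_mgdl(glucose_mmol):
    return np.asarray(glucose_mmol, dtype=float) * GLUCOSE_MMOL_TO_MGDL


# ---- elementary operations -------------------------------------------------

def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under irregularly sampled concentrations.

    ``times`` must be strictly increasing with >= 2 points and no value may
    be missing — this is a per-subject primitive, not a panel column.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points")
    if t.shape != v.shape:
        raise ValueError("times and values must align")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(np.isnan(t)) or np.any(np.isnan(v)):
        raise ValueError("missing value in AUC input")
    return float(np.trapezoid(v, t))


class BetaCellIndexes(NamedTuple):
    ratio_cpep_glu_030: float
    ratio_ins_glu_030: float
    igi: float
    delta_cpep_glu_030: float
    di: float


def beta_cell_indexes(g0, g30, i0, i30, c0, c30) -> BetaCellIndexes:
    """Absorptive-phase secretion indexes.

    Sum ratios use (x0+x30)/(g0+g30); difference quotients (IGI and the
    C-peptide delta ratio) are undefined (NaN) when g30 == g0.
    """
    g0, g30, i0, i30, c0, c30 = map(
        lambda x: np.asarray(x, dtype=float), (g0, g30, i0, i30, c0, c30)
    )
    ratio_cpep = (c0 + c30) / (g0 + g30)
    ratio_ins = (i0 + i30) / (g0 + g30)
    dg = g30 - g0
    with np.errstate(divide="ignore", invalid="ignore"):
        igi = np.where(dg != 0, (i30 - i0) / dg, np.nan)
        delta_cpep = np.where(dg != 0, (c30 - c0) / dg, np.nan)
        di = igi / i0
    return BetaCellIndexes(ratio_cpep, ratio_ins, igi, delta_cpep, di)


#: default homeostatic-model backend: the classic closed form. The original
#: iterative computer model is closed-source, so the beta-cell index applies
#: the closed form to C-peptide converted onto the insulin mIU/L scale. A
#: user-supplied backend (g0, i0, c0) -> (homa_b, homa_ir) is passed through
#: unchanged, e.g. to inject precomputed calculator outputs.
def _homa_closed_form(g0, i0, c0):
    g0 = np.asarray(g0, dtype=float)
    i_miu = insulin_to_miu(i0)
    c_miu_equiv = np.asarray(c0, dtype=float) * CPEPTIDE_NMOL_TO_PMOL / INSULIN_PMOL_PER_MIU
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_b = np.where(g0 > 3.5, 20.0 * c_miu_equiv / (g0 - 3.5), np.nan)
    homa_ir = g0 * i_miu / 22.5
    return homa_b, homa_ir


def homa_indexes(g0, i0, c0, backend: Callable | None = None):
    """(homa_b, homa_ir) via the pluggable homeostatic-model backend."""
    backend = backend or _homa_closed_form
    return backend(g0, i0, c0)


def matsuda(g, i) -> float:
    """Composite whole-body insulin sensitivity over the three time points.

    ``g``: glucose mmol/L at (0, 30, 120); ``i``: insulin pmol/L likewise.
    10000 / sqrt(G0 * I0 * Gmean * Imean) with glucose in mg/dL and insulin
    in uU/mL, means over the available three points.
    """
    g = glucose_to_mgdl(g)
    i = insulin_to_miu(i)
    if g.shape[-1] != 3 or i.shape[-1] != 3:
        raise ValueError("matsuda requires the three OGTT time points")
    prod = g[..., 0] * i[..., 0] * g.mean(axis=-1) * i.mean(axis=-1)
    with np.errstate(invalid="ignore"):
        out = np.where(prod > 0, 10000.0 / np.sqrt(np.abs(prod)), np.nan)
    return out


class TissueIR(NamedTuple):
    liver_ir: float
    hepatic_ir: float
    adipo_ir: float
    isi_ffa: float


def _log10_pos(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, np.log10(np.abs(x) + (x <= 0)), np.nan)


def tissue_ir(
    auc_insulin_0_120, auc_glucose_030, auc_insulin_030,
    fat_mass_pct, hdl, bmi, ffa0, i0, auc_insulin, auc_ffa,
) -> TissueIR:
    """Tissue-specific insulin-resistance composites.

    liver_ir: -0.091 + 0.400*log10(AUC insulin 0-120) + 0.346*log10(fat-mass %)
              - 0.408*log10(HDL-c) + 0.435*log10(BMI)
    hepatic_ir: AUC(0-30) insulin x AUC(0-30) glucose, native units
    adipo_ir: fasting FFA x fasting insulin
    isi_ffa: 2 / (scaled insulin AUC x scaled FFA AUC + 1)
    """
    liver_ir = (
        -0.091
        + 0.400 * _log10_pos(auc_insulin_0_120)
        + 0.346 * _log10_pos(fat_mass_pct)
        - 0.408 * _log10_pos(hdl)
        + 0.435 * _log10_pos(bmi)
    )
    hepatic_ir = np.asarray(auc_insulin_030, dtype=float) * np.asarray(
        auc_glucose_030, dtype=float
    )
    adipo_ir = np.asarray(ffa0, dtype=float) * np.asarray(i0, dtype=float)
    scaled = (
        np.asarray(auc_insulin, dtype=float) * ISI_FFA_INSULIN_AUC_SCALE
        * np.asarray(auc_ffa, dtype=float) * ISI_FFA_FFA_AUC_SCALE
    )
    isi_ffa = 2.0 / (scaled + 1.0)
    return TissueIR(liver_ir, hepatic_ir, adipo_ir, isi_ffa)


class InsulinClearance(NamedTuple):
    ic_fast: float
    ic_delta_030: float
    ic_120: float


def insulin_clearance(c0, c30, c120, i0, i30, i120) -> InsulinClearance:
    """C-peptide / insulin clearance ratios at fast, 0-30 slope, and 30-120.

    Single-interval AUC ratios collapse to sum ratios; the 0-30 min
    suppression is the slope (ic30 - ic_fast) / 30 per minute.
    """
    c0, c30, c120, i0, i30, i120 = map(
        lambda x: np.asarray(x, dtype=float), (c0, c30, c120, i0, i30, i120)
    )
    ic_fast = c0 / i0
    ic30 = (c0 + c30) / (i0 + i30)
    ic_120 = (c30 + c120) / (i30 + i120)
    ic_delta_030 = (ic30 - ic_fast) / 30.0
    return InsulinClearance(ic_fast, ic_delta_030, ic_120)


class FattyLiverScores(NamedTuple):
    nafld_fls: float
    fli: float


def fatty_liver_scores(mets, t2d, i0, tg, bmi, waist) -> FattyLiverScores:
    """Fatty-liver surrogate scores.

    nafld_fls = -2.889 + 1.179*[met.syndrome] + 0.454*(2 if diabetes else 0)
                + 0.145 * fasting insulin (mIU/L)
    fli = 100 * logistic(0.953*ln(TG) + 0.139*BMI + 0.053*waist - 15.745)
    """
    mets = np.asarray(mets, dtype=float)
    t2d = np.asarray(t2d, dtype=float)
    i_miu = insulin_to_miu(i0)
    nafld_fls = -2.889 + 1.179 * mets + 0.454 * (2.0 * t2d) + 0.145 * i_miu

    tg = np.asarray(tg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_tg = np.where(tg > 0, np.log(np.abs(tg) + (tg <= 0)), np.nan)
    lin = 0.953 * ln_tg + 0.139 * np.asarray(bmi, dtype=float) \
        + 0.053 * np.asarray(waist, dtype=float) - 15.745
    fli = 100.0 * expit(lin)
    return FattyLiverScores(nafld_fls, fli)


def egfr_ckd_epi(creatinine, age, sex):
    """CKD-EPI 2009 creatinine equation, race coefficient omitted.

    ``sex``: 'male'/'female' (scalar or array). Units mL/min/1.73 m2.
    """
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(sex) == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    base = np.where(female, 141.0 * 1.018, 141.0)
    with np.errstate(invalid="ignore"):
        ratio = np.where(scr > 0, scr, np.nan) / kappa
        egfr = (
            base
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993**age
        )
    return np.where((scr > 0) & (age > 0), egfr, np.nan)


GLYCEMIA_CLASSES = ("NG", "IFG", "IGT", "IFG+IGT", "DM")


def classify_glycemia(g0, g120=np.nan):
    """WHO 1999 fasting / 2-h glucose bands (mmol/L).

    DM if g0 >= 7.0 or g120 >= 11.1; IFG if 6.1 <= g0 < 7.0;
    IGT if 7.8 <= g120 < 11.1; 'IFG+IGT' when both; else NG.
    Missing g120 leaves IGT undeterminable (treated as absent).
    """
    g0 = np.asarray(g0, dtype=float)
    g120 = np.asarray(g120, dtype=float)
    g120b = np.broadcast_to(g120, g0.shape) if g0.shape else g120
    if np.any(np.isnan(g0)):
        raise ValueError("fasting glucose is required for classification")
    dm = (g0 >= 7.0) | (g120b >= 11.1)
    ifg = (g0 >= 6.1) & (g0 < 7.0)
    igt = (g120b >= 7.8) & (g120b < 11.1)
    out = np.full(np.shape(g0), "NG", dtype=object)
    out[np.asarray(ifg & ~igt)] = "IFG"
    out[np.asarray(igt & ~ifg)] = "IGT"
    out[np.asarray(ifg & igt)] = "IFG+IGT"
    out[np.asarray(dm)] = "DM"
    return out if out.shape else out.item()


def bmi(weight, height):
    """kg / m^2."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    return weight / height**2


def metabolic_syndrome_idf(sex, waist, tg, hdl, g0, sbp=np.nan, dbp=np.nan):
    """IDF metabolic-syndrome flag.

    Central obesity (waist >= 94 cm male / 80 cm female) plus any two of:
    TG >= 150 mg/dL; HDL-c < 40 (male) / 50 (female) mg/dL;
    BP >= 130/85 mmHg (missing BP counts as absent); fasting glucose
    >= 5.6 mmol/L.
    """
    female = np.asarray(sex) == "female"
    waist = np.asarray(waist, dtype=float)
    central = np.where(female, waist >= 80.0, waist >= 94.0)
    tg_c = np.asarray(tg, dtype=float) >= 150.0
    hdl_c = np.asarray(hdl, dtype=float) < np.where(female, 50.0, 40.0)
    with np.errstate(invalid="ignore"):
        bp_c = (np.asarray(sbp, dtype=float) >= 130.0) | (
            np.asarray(dbp, dtype=float) >= 85.0
        )
    bp_c = np.where(np.isnan(np.asarray(sbp, dtype=float))
                    & np.isnan(np.asarray(dbp, dtype=float)), False, bp_c)
    glu_c = np.asarray(g0, dtype=float) >= 5.6
    n_extra = (
        tg_c.astype(int) + hdl_c.astype(int)
        + np.asarray(bp_c).astype(int) + glu_c.astype(int)
    )
    return central & (n_extra >= 2)


# ---- panel assembly --------------------------------------------------------

PANEL_COLUMNS = (
    "bmi", "auc_glucose", "auc_insulin", "auc_cpeptide", "auc_ffa",
    "homa_b", "homa_ir",
    "ratio_cpep_glu_030", "ratio_ins_glu_030", "igi", "delta_cpep_glu_030",
    "di", "matsuda",
    "liver_ir", "hepatic_ir", "adipo_ir", "isi_ffa",
    "ic_fast", "ic_delta_030", "ic_120",
    "mets_idf", "nafld_fls", "fli", "egfr", "glycemia_class",
)

UNITS = {
    "bmi": "kg/m^2",
    "auc_glucose": "mmol/L*min", "auc_insulin": "pmol/L*min",
    "auc_cpeptide": "nmol/L*min", "auc_ffa": "mmol/L*min",
    "homa_b": "%", "homa_ir": "dimensionless",
    "ratio_cpep_glu_030": "nmol per mmol", "ratio_ins_glu_030": "pmol per mmol",
    "igi": "pmol/L per mmol/L", "delta_cpep_glu_030": "nmol/L per mmol/L",
    "di": "1/mmol", "matsuda": "dimensionless",
    "liver_ir": "dimensionless", "hepatic_ir": "(pmol/L*min)*(mmol/L*min)",
    "adipo_ir": "mmol/L * pmol/L", "isi_ffa": "dimensionless",
    "ic_fast": "nmol/pmol", "ic_delta_030": "nmol/pmol per min",
    "ic_120": "nmol/pmol",
    "mets_idf": "boolean", "nafld_fls": "dimensionless", "fli": "0-100",
    "egfr": "mL/min/1.73m^2", "glycemia_class": "category",
}


def _auc_columns(df: pd.DataFrame, analyte: str) -> np.ndarray:
    """Vectorized 3-point trapezoid with NaN propagation per subject."""
    v0 = df[f"{analyte}_0"].to_numpy(float)
    v30 = df[f"{analyte}_30"].to_numpy(float)
    v120 = df[f"{analyte}_120"].to_numpy(float)
    return 30.0 * (v0 + v30) / 2.0 + 90.0 * (v30 + v120) / 2.0


def compute_panel(cohort: pd.DataFrame, homa_backend: Callable | None = None) -> pd.DataFrame:
    """One derived-index row per subject; missing inputs flag the dependent
    indexes missing without touching the others. Idempotent and pure."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.reset_index(drop=True)
    g0 = df["glucose_0"].to_numpy(float)
    g30 = df["glucose_30"].to_numpy(float)
    g120 = df["glucose_120"].to_numpy(float)
    i0 = df["insulin_0"].to_numpy(float)
    i30 = df["insulin_30"].to_numpy(float)
    i120 = df["insulin_120"].to_numpy(float)
    c0 = df["cpeptide_0"].to_numpy(float)
    c30 = df["cpeptide_30"].to_numpy(float)
    c120 = df["cpeptide_120"].to_numpy(float)
    f0 = df["ffa_0"].to_numpy(float)

    panel = pd.DataFrame(index=df.index)
    panel["id"] = df["id"]
    panel["bmi"] = bmi(df["weight"].to_numpy(float), df["height"].to_numpy(float))
    for analyte in ("glucose", "insulin", "cpeptide", "ffa"):
        panel[f"auc_{analyte}"] = _auc_columns(df, analyte)

    hb, hir = homa_indexes(g0, i0, c0, backend=homa_backend)
    panel["homa_b"], panel["homa_ir"] = hb, hir

    beta = beta_cell_indexes(g0, g30, i0, i30, c0, c30)
    panel["ratio_cpep_glu_030"] = beta.ratio_cpep_glu_030
    panel["ratio_ins_glu_030"] = beta.ratio_ins_glu_030
    panel["igi"] = beta.igi
    panel["delta_cpep_glu_030"] = beta.delta_cpep_glu_030
    panel["di"] = beta.di

    panel["matsuda"] = matsuda(
        np.column_stack([g0, g30, g120]), np.column_stack([i0, i30, i120])
    )

    auc_ins_030 = 30.0 * (i0 + i30) / 2.0
    auc_glu_030 = 30.0 * (g0 + g30) / 2.0
    tir = tissue_ir(
        panel["auc_insulin"], auc_glu_030, auc_ins_030,
        df["fat_mass_pct"].to_numpy(float), df["hdl"].to_numpy(float),
        panel["bmi"], f0, i0,
        panel["auc_insulin"], panel["auc_ffa"],
    )
    panel["liver_ir"] = tir.liver_ir
    panel["hepatic_ir"] = tir.hepatic_ir
    panel["adipo_ir"] = tir.adipo_ir
    panel["isi_ffa"] = tir.isi_ffa

    ic = insulin_clearance(c0, c30, c120, i0, i30, i120)
    panel["ic_fast"] = ic.ic_fast
    panel["ic_delta_030"] = ic.ic_delta_030
    panel["ic_120"] = ic.ic_120

    glyc = np.full(len(df), "", dtype=object)
    valid_g0 = ~np.isnan(g0)
    glyc[valid_g0] = classify_glycemia(g0[valid_g0], g120[valid_g0])
    glyc[~valid_g0] = np.nan
    panel["glycemia_class"] = glyc

    t2d = np.where(valid_g0, glyc == "DM", np.nan)
    sbp = df["sbp"].to_numpy(float) if "sbp" in df else np.full(len(df), np.nan)
    dbp = df["dbp"].to_numpy(float) if "dbp" in df else np.full(len(df), np.nan)
    mets = metabolic_syndrome_idf(
        df["sex"].to_numpy(), df["waist"].to_numpy(float),
        df["tg"].to_numpy(float), df["hdl"].to_numpy(float), g0, sbp, dbp,
    ).astype(float)
    mets_inputs_missing = (
        np.isnan(df["waist"].to_numpy(float))
        | np.isnan(df["tg"].to_numpy(float))
        | np.isnan(df["hdl"].to_numpy(float))
        | np.isnan(g0)
    )
    mets[mets_inputs_missing] = np.nan
    panel["mets_idf"] = mets
    fls = fatty_liver_scores(
        mets, t2d.astype(float), i0,
        df["tg"].to_numpy(float), panel["bmi"].to_numpy(float),
        df["waist"].to_numpy(float),
    )
    panel["nafld_fls"] = fls.nafld_fls
    panel["fli"] = fls.fli
    panel["egfr"] = egfr_ckd_epi(
        df["creatinine"].to_numpy(float), df["age"].to_numpy(float),
        df["sex"].to_numpy(),
    )
    return panel


def write_panel(panel: pd.DataFrame, path, units_path=None) -> None:
    panel.to_csv(path, index=False, encoding="utf-8")
    if units_path is not None:
        with open(units_path, "w", encoding="utf-8") as fh:
            for col in panel.columns:
                fh.write(f"{col}\t{UNITS.get(col, '-')}\n")
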