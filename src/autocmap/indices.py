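"""Composite cardiometabolic indices and hair-toxicity scoring.

Implements the subject-level scores used in the cohort analysis:

* fatty liver index (FLI, Bedogni logistic score, 0–100),
* visceral adiposity index (VAI, Amato sex-specific formula) with its
  age-banded reference cutoffs,
* Framingham ATP III point score with the published points→10-year-risk lookup,
* NCEP ATP III metabolic syndrome classification (2005 revision),
* obesity flag (BMI strictly above 30 kg/m²),
* hair toxicity index (TI): weighted average of toxic-element concentrations,
* per-element reference-interval flagging.

Unit conventions: triglycerides and HDL enter FLI/MetS in mg/dL and VAI in
mmol/L; converters are provided. The Italian "Progetto Cuore" CV risk charts
are exposed only as a pluggable stub.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .schema import ElementSchema, TOXIC_SYMBOLS, default_element_schema

__all__ = [
    "fatty_liver_index",
    "fli_category",
    "visceral_adiposity_index",
    "vai_reference_cutoff",
    "framingham_risk",
    "mets_atpiii",
    "obesity_flag",
    "toxicity_index",
    "default_toxicity_weights",
    "flag_out_of_reference",
    "tg_mgdl_to_mmoll",
    "chol_mgdl_to_mmoll",
    "progetto_cuore_risk",
    "SubjectIndices",
]

# mg/dL → mmol/L conversion factors
TG_MGDL_TO_MMOLL = 0.01129
CHOL_MGDL_TO_MMOLL = 0.02586


def tg_mgdl_to_mmoll(tg_mgdl: float) -> float:
    """Convert triglycerides from mg/dL to mmol/L."""
    return tg_mgdl * TG_MGDL_TO_MMOLL


def chol_mgdl_to_mmoll(chol_mgdl: float) -> float:
    """Convert cholesterol (total/HDL/LDL) from mg/dL to mmol/L."""
    return chol_mgdl * CHOL_MGDL_TO_MMOLL


@dataclass(frozen=True)
class SubjectIndices:
    """Bundle of composite scores for one subject."""

    fli: float
    vai: float
    vai_cutoff: float | None
    framingham_points: int
    framingham_risk_percent: float
    mets: bool
    obesity: bool
    ti: float


# ---------------------------------------------------------------------------
# Fatty liver index (Bedogni)
# ---------------------------------------------------------------------------

def fatty_liver_index(tg: float, bmi: float, ggt: float, wc: float) -> float:
    """Fatty liver index on the 0–100 scale.

    Logistic transform of the Bedogni linear predictor

        L = 0.953·ln(TG) + 0.139·BMI + 0.718·ln(GGT) + 0.053·WC − 15.745
        FLI = 100 · e^L / (1 + e^L)

    with TG in mg/dL, BMI in kg/m², GGT in U/L and WC in cm. FLI < 30
    excludes fatty liver; FLI ≥ 60 points to it.
    """
    for name, v in (("tg", tg), ("bmi", bmi), ("ggt", ggt), ("wc", wc)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    lin = 0.953 * math.log(tg) + 0.139 * bmi + 0.718 * math.log(ggt) + 0.053 * wc - 15.745
    return 100.0 / (1.0 + math.exp(-lin))


def fli_category(fli: float) -> str:
    """Clinical reading of an FLI value: <30 excludes, ≥60 indicates fatty liver."""
    if fli < 30:
        return "fatty liver excluded"
    if fli >= 60:
        return "fatty liver indicated"
    return "indeterminate"


# ---------------------------------------------------------------------------
# Visceral adiposity index (Amato)
# ---------------------------------------------------------------------------

def visceral_adiposity_index(
    sex: str, wc: float, bmi: float, tg: float, hdl: float
) -> float:
    """Sex-specific visceral adiposity index.

    Men:   VAI = (WC / (39.68 + 1.88·BMI)) · (TG/1.03) · (1.31/HDL)
    Women: VAI = (WC / (36.58 + 1.89·BMI)) · (TG/0.81) · (1.52/HDL)

    WC in cm, BMI in kg/m², TG and HDL in **mmol/L**.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    for name, v in (("wc", wc), ("bmi", bmi), ("tg", tg), ("hdl", hdl)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    if tg > 30:
        raise ValueError(
            f"tg = {tg} mmol/L is not physiologic; triglycerides look like mg/dL "
            "— convert with tg_mgdl_to_mmoll()"
        )
    if sex == "male":
        return (wc / (39.68 + 1.88 * bmi)) * (tg / 1.03) * (1.31 / hdl)
    return (wc / (36.58 + 1.89 * bmi)) * (tg / 0.81) * (1.52 / hdl)


_VAI_BANDS = ((30.0, 42.0, 2.23), (42.0, 52.0, 1.92), (52.0, 66.0, 1.93))


def vai_reference_cutoff(age: float) -> float:
    """Age-banded VAI reference cutoff.

    <2.23 for ages in [30, 42), <1.92 for [42, 52), <1.93 for [52, 66),
    <2.0 for ages ≥ 66. No cutoff is defined below age 30.
    """
    if age < 30:
        raise ValueError(f"no VAI reference cutoff is defined below age 30 (got {age})")
    for lo, hi, cutoff in _VAI_BANDS:
        if lo <= age < hi:
            return cutoff
    return 2.0


# ---------------------------------------------------------------------------
# Framingham ATP III point score
# ---------------------------------------------------------------------------
# Office-based NCEP ATP III tables (age, total cholesterol by age decade,
# smoking by age decade, HDL, SBP by treatment), and the points→10-year-CHD-risk
# lookup. Age groups for cholesterol/smoking: 20-39, 40-49, 50-59, 60-69, 70-79.

_AGE_POINTS = {
    "male": ((20, 34, -9), (35, 39, -4), (40, 44, 0), (45, 49, 3), (50, 54, 6),
             (55, 59, 8), (60, 64, 10), (65, 69, 11), (70, 74, 12), (75, 79, 13)),
    "female": ((20, 34, -7), (35, 39, -3), (40, 44, 0), (45, 49, 3), (50, 54, 6),
               (55, 59, 8), (60, 64, 10), (65, 69, 12), (70, 74, 14), (75, 79, 16)),
}

# rows: TC bands (<160, 160-199, 200-239, 240-279, >=280); cols: age decades
_TC_POINTS = {
    "male": ((0, 0, 0, 0, 0), (4, 3, 2, 1, 0), (7, 5, 3, 1, 0),
             (9, 6, 4, 2, 1), (11, 8, 5, 3, 1)),
    "female": ((0, 0, 0, 0, 0), (4, 3, 2, 1, 1), (8, 6, 4, 2, 1),
               (11, 8, 5, 3, 2), (13, 10, 7, 4, 2)),
}

_SMOKER_POINTS = {"male": (8, 5, 3, 1, 1), "female": (9, 7, 4, 2, 1)}

# SBP bands (<120, 120-129, 130-139, 140-159, >=160) × (untreated, treated)
_SBP_POINTS = {
    "male": ((0, 0), (0, 1), (1, 2), (1, 2), (2, 3)),
    "female": ((0, 0), (1, 3), (2, 4), (3, 5), (4, 6)),
}

_RISK_LOOKUP = {
    "male": {0: 1, 1: 1, 2: 1, 3: 1, 4: 1, 5: 2, 6: 2, 7: 3, 8: 4, 9: 5,
             10: 6, 11: 8, 12: 10, 13: 12, 14: 16, 15: 20, 16: 25},
    "female": {9: 1, 10: 1, 11: 1, 12: 1, 13: 2, 14: 2, 15: 3, 16: 4, 17: 5,
               18: 6, 19: 8, 20: 11, 21: 14, 22: 17, 23: 22, 24: 27},
}
# points below the table floor read "<1%", above the ceiling ">=30%"
_RISK_FLOOR = {"male": 0, "female": 9}
_RISK_CEIL = {"male": 17, "female": 25}


def _age_decade(age: float) -> int:
    # column index for the TC/smoking tables: 20-39, 40-49, 50-59, 60-69, 70-79
    return 0 if age < 40 else 1 if age < 50 else 2 if age < 60 else 3 if age < 70 else 4


def framingham_risk(
    age: float,
    sex: str,
    total_chol: float,
    hdl: float,
    sbp: float,
    treated_bp: bool,
    smoker: bool,
    diabetes: bool = False,
) -> tuple[int, float]:
    """ATP III Framingham point score and 10-year hard-CHD risk percent.

    total_chol and hdl in mg/dL, sbp in mmHg, age 20–79 years. Returns
    (points, risk_percent); a "<1%" lookup reads 0.5 and ">=30%" reads 30.0.
    The ``diabetes`` flag is accepted for completeness but does not enter the
    ATP III point sum (ATP III scores diabetes as a CHD risk equivalent
    outside this table).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 20 <= age <= 79:
        raise ValueError(f"age {age} outside the 20–79 range of the point tables")

    points = 0
    for lo, hi, pts in _AGE_POINTS[sex]:
        if lo <= age <= hi:
            points += pts
            break
    decade = _age_decade(age)

    tc_band = 0 if total_chol < 160 else 1 if total_chol < 200 else \
        2 if total_chol < 240 else 3 if total_chol < 280 else 4
    points += _TC_POINTS[sex][tc_band][decade]

    if smoker:
        points += _SMOKER_POINTS[sex][decade]

    if hdl >= 60:
        points -= 1
    elif hdl >= 50:
        points += 0
    elif hdl >= 40:
        points += 1
    else:
        points += 2

    sbp_band = 0 if sbp < 120 else 1 if sbp < 130 else \
        2 if sbp < 140 else 3 if sbp < 160 else 4
    points += _SBP_POINTS[sex][sbp_band][1 if treated_bp else 0]

    if points < _RISK_FLOOR[sex]:
        risk = 0.5
    elif points >= _RISK_CEIL[sex]:
        risk = 30.0
    else:
        risk = float(_RISK_LOOKUP[sex][points])
    return points, risk


# ---------------------------------------------------------------------------
# NCEP ATP III metabolic syndrome (2005 revision)
# ---------------------------------------------------------------------------

def mets_atpiii(
    wc: float,
    sex: str,
    tg: float,
    hdl: float,
    sbp: float,
    dbp: float,
    bp_treated: bool,
    glucose: float,
) -> bool:
    """Metabolic syndrome: at least 3 of the 5 ATP III components.

    Components (TG, HDL, glucose in mg/dL; WC cm; BP mmHg):
      1. central obesity: WC > 102 (men) / > 88 (women)
      2. triglycerides ≥ 150
      3. low HDL: < 40 (men) / < 50 (women)
      4. blood pressure ≥ 130/85 or on antihypertensive treatment
      5. fasting glucose ≥ 100
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    for name, v in (("wc", wc), ("tg", tg), ("hdl", hdl), ("sbp", sbp),
                    ("dbp", dbp), ("glucose", glucose)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing MetS component {name}; no silent imputation")
    components = [
        wc > (102.0 if sex == "male" else 88.0),
        tg >= 150.0,
        hdl < (40.0 if sex == "male" else 50.0),
        bool(bp_treated) or sbp >= 130.0 or dbp >= 85.0,
        glucose >= 100.0,
    ]
    return sum(components) >= 3


def obesity_flag(bmi: float) -> bool:
    """Obesity defined strictly as BMI > 30 kg/m² (30.0 exactly is not obese)."""
    if not bmi > 0:
        raise ValueError(f"bmi must be > 0, got {bmi}")
    return bmi > 30.0


# ---------------------------------------------------------------------------
# Hair toxicity index
# ---------------------------------------------------------------------------

def default_toxicity_weights(schema: ElementSchema | None = None) -> dict[str, float]:
    """Per-gram relative toxicity weights for the 13 toxic elements.

    The laboratory weighting behind the original toxicity index is
    proprietary; the packaged default operationalizes "relative toxicity per
    gram" as the inverse of each element's tolerated hair level,
    wᵢ = 1 / reference_upperᵢ, so elements with stricter reference limits
    weigh more. Fully overridable wherever a weights mapping is accepted.
    """
    schema = schema or default_element_schema()
    return {e.symbol: 1.0 / e.reference_upper for e in schema.toxic}


def toxicity_index(
    concentrations: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Weighted-average hair toxicity index over the 13 toxic elements.

    TI = Σ wᵢ·cᵢ / Σ wᵢ with concentrations cᵢ in μg/g. Higher TI means a
    more toxic overall combination of hair metals. Zero exactly when every
    toxic concentration is zero.
    """
    weights = dict(weights) if weights is not None else default_toxicity_weights()
    missing = [s for s in TOXIC_SYMBOLS if s not in concentrations]
    if missing:
        raise ValueError(f"missing toxic element concentrations: {missing}")
    missing_w = [s for s in TOXIC_SYMBOLS if s not in weights]
    if missing_w:
        raise ValueError(f"missing toxicity weights: {missing_w}")
    num = 0.0
    den = 0.0
    for s in TOXIC_SYMBOLS:
        c = float(concentrations[s])
        w = float(weights[s])
        if c < 0:
            raise ValueError(f"negative concentration for {s}: {c}")
        if w <= 0:
            raise ValueError(f"non-positive weight for {s}: {w}")
        num += w * c
        den += w
    return num / den


def flag_out_of_reference(
    concentrations: Mapping[str, float], schema: ElementSchema | None = None
) -> dict[str, str]:
    """Classify each concentration as 'low' / 'normal' / 'high' vs its interval.

    Toxic elements have upper-limit-only intervals and can only come back
    'normal' or 'high'.
    """
    schema = schema or default_element_schema()
    flags: dict[str, str] = {}
    for symbol, value in concentrations.items():
        elem = schema[symbol]  # raises KeyError with suggestions if unknown
        if elem.reference_lower is not None and value < elem.reference_lower:
            flags[symbol] = "low"
        elif value > elem.reference_upper:
            flags[symbol] = "high"
        else:
            flags[symbol] = "normal"
    return flags


# ---------------------------------------------------------------------------
# Progetto Cuore stub
# ---------------------------------------------------------------------------

ProgettoCuoreChart = Callable[..., float]


def progetto_cuore_risk(*args, chart: ProgettoCuoreChart | None = None, **kwargs) -> float:
    """Italian CUORE project CV risk — pluggable stub.

    The CUORE risk charts are not packaged; pass a ``chart`` callable to use
    a concrete implementation.
    """
    if chart is None:
        raise NotImplementedError(
            "the Progetto Cuore risk charts are not packaged; supply chart="
        )
    return float(chart(*args, **kwargs))


def compute_subject_indices(
    *,
    age: float,
    sex: str,
    bmi: float,
    wc: float,
    tg_mgdl: float,
    hdl_mgdl: float,
    ggt: float,
    total_chol: float,
    sbp: float,
    dbp: float,
    glucose: float,
    bp_treated: bool,
    smoker: bool,
    diabetes: bool,
    toxic_concentrations: Mapping[str, float],
    toxicity_weights: Mapping[str, float] | None = None,
) -> SubjectIndices:
    """All composite scores for one subject from raw primitives (mg/dL units)."""
    fli = fatty_liver_index(tg_mgdl, bmi, ggt, wc)
    vai = visceral_adiposity_index(
        sex, wc, bmi, tg_mgdl_to_mmoll(tg_mgdl), chol_mgdl_to_mmoll(hdl_mgdl)
    )
    cutoff = vai_reference_cutoff(age) if age >= 30 else None
    points, risk = framingham_risk(
        age, sex, total_chol, hdl_mgdl, sbp, bp_treated, smoker, diabetes
    )
    mets = mets_atpiii(wc, sex, tg_mgdl, hdl_mgdl, sbp, dbp, bp_treated, glucose)
    return SubjectIndices(
        fli=fli,
        vai=vai,
        vai_cutoff=cutoff,
        framingham_points=points,
        framingham_risk_percent=risk,
        mets=mets,
        obesity=obesity_flag(bmi),
        ti=toxicity_index(toxic_concentrations, toxicity_weights),
    )
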