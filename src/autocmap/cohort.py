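"""Synthetic cohort generation for the overweight–obesity hair-mineralogram study.

The study's raw subject-level data are not publicly available, so this module
emulates them: a 95-subject cohort with 25 clinical/biometric variables
(anthropometrics, blood pressure, blood count, lipids, glucose metabolism,
inflammation markers and the composite indices), the 31-element hair panel
with right-skewed concentrations calibrated to the published per-element
mean/SD/min/max, and a planted latent-factor correlation structure: a
"metabolic" factor tying waist circumference, BMI, triglycerides, insulin,
glycaemia, HbA1c, fibrinogen and uric acid, and an "exposure" factor tying
the 13 toxic elements (and hence the toxicity index) together.

Derived indices (FLI, VAI, Framingham, MetS, obesity, TI) are computed from
the simulated primitives, never sampled independently, so their associations
with the primitives are structural, as in real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, special

from .indices import (
    fatty_liver_index,
    framingham_risk,
    mets_atpiii,
    obesity_flag,
    chol_mgdl_to_mmoll,
    tg_mgdl_to_mmoll,
    toxicity_index,
    visceral_adiposity_index,
)
from .schema import ElementSchema, TOXIC_SYMBOLS, default_element_schema

__all__ = [
    "MarginalSpec",
    "LatentStructure",
    "CohortTable",
    "DERIVED_VARIABLES",
    "lognormal_params_from_moments",
    "truncated_lognormal_params",
    "sample_marginal",
    "default_study_spec",
    "simulate_cohort",
]

DEFAULT_N = 95  # study cohort size


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one cohort variable.

    family: 'truncated_gaussian', 'lognormal' (truncated) or 'bernoulli'
    (mean = success probability). mean/sd are on the scale of the variable;
    lower/upper are hard physiologic truncation bounds.
    """

    variable_name: str
    family: str
    mean: float
    sd: float
    lower: float
    upper: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("truncated_gaussian", "lognormal", "bernoulli"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.sd > 0:
            raise ValueError(f"{self.variable_name}: sd must be > 0")
        if not self.lower < self.upper:
            raise ValueError(f"{self.variable_name}: lower must be < upper")
        if self.family == "lognormal" and not self.mean > 0:
            raise ValueError(f"{self.variable_name}: lognormal mean must be > 0")


@dataclass(frozen=True)
class LatentStructure:
    """Latent factors inducing cross-variable correlation.

    ``loadings`` maps variable name → factor name → loading in [−1, 1];
    idiosyncratic noise absorbs the remaining variance so each variable's
    standardized score has unit variance when noise_sd = 1.
    """

    factor_names: tuple[str, ...]
    loadings: dict[str, dict[str, float]]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        for var, fl in self.loadings.items():
            for f, lam in fl.items():
                if f not in self.factor_names:
                    raise ValueError(f"{var}: unknown factor {f!r}")
                if not -1.0 <= lam <= 1.0:
                    raise ValueError(f"{var}: loading on {f} outside [-1, 1]")
            if sum(lam * lam for lam in fl.values()) > 1.0 + 1e-12:
                raise ValueError(f"{var}: total loading variance exceeds 1")

    def loading_vector(self, variable: str) -> np.ndarray:
        fl = self.loadings.get(variable, {})
        return np.array([fl.get(f, 0.0) for f in self.factor_names])


@dataclass
class CohortTable:
    """Subjects × variables table with units and a missing-value mask."""

    subject_ids: list[str]
    variables: list[tuple[str, str]]  # (name, unit)
    values: np.ndarray  # float, n_subjects × n_variables
    missing_mask: np.ndarray = field(default=None)  # bool, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.variables) != p:
            raise ValueError("values shape does not match subject_ids/variables")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("NaN outside missing_mask")

    @property
    def variable_names(self) -> list[str]:
        return [name for name, _ in self.variables]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# ---------------------------------------------------------------------------
# Lognormal calibration
# ---------------------------------------------------------------------------

def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Closed-form (mu, sigma) so LN(mu, sigma) has exactly the given mean/sd."""
    if not mean > 0 or not sd > 0:
        raise ValueError("mean and sd must be > 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _trunc_ln_moments(
    mu: float, sigma: float, lower: float, upper: float
) -> tuple[float, float]:
    """Mean and sd of LN(mu, sigma) truncated to [lower, upper]."""
    a = (math.log(lower) - mu) / sigma if lower > 0 else -np.inf
    b = (math.log(upper) - mu) / sigma
    p = special.ndtr(b) - special.ndtr(a)
    if p <= 0:
        return np.nan, np.nan

    def raw_moment(k: int) -> float:
        # exp(k·mu + k²σ²/2) · (Φ(b−kσ) − Φ(a−kσ)) / p, computed in log space
        term = special.ndtr(b - k * sigma) - special.ndtr(a - k * sigma)
        if term <= 0:
            return 0.0
        log_m = k * mu + (k * sigma) ** 2 / 2.0 + math.log(term) - math.log(p)
        return math.exp(min(log_m, 700.0))

    m1 = raw_moment(1)
    var = max(raw_moment(2) - m1 * m1, 0.0)
    return m1, math.sqrt(var)


@lru_cache(maxsize=256)
def truncated_lognormal_params(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """(mu, sigma) so the lognormal *truncated to [lower, upper]* matches mean/sd.

    Starts from the closed-form untruncated inversion and refines jointly;
    if the joint solve cannot reach the target second moment (possible for
    extremely heavy-tailed marginals whose printed SD is near the truncation
    ceiling), sigma is kept from the closed form and mu alone is solved so the
    truncated mean is exact. A target mean at or below the lower bound
    (possible through rounding of the published summaries) is nudged just
    inside the support.
    """
    if not mean > 0 or not sd > 0:
        raise ValueError("mean and sd must be > 0")
    if not lower < upper:
        raise ValueError("lower must be < upper")
    lo_eff = max(lower, 0.0)
    target_mean = mean
    if target_mean <= lo_eff:
        target_mean = lo_eff + 0.1 * (upper - lo_eff)
    if target_mean >= upper:
        target_mean = upper - 0.1 * (upper - lo_eff)

    mu0, s0 = lognormal_params_from_moments(target_mean, sd)

    def resid(theta: np.ndarray) -> np.ndarray:
        mu, logsig = theta
        m, s = _trunc_ln_moments(mu, math.exp(logsig), lo_eff, upper)
        if not np.isfinite(m):
            return np.array([1e6, 1e6])
        return np.array([(m - target_mean) / target_mean, (s - sd) / sd])

    sol = optimize.least_squares(
        resid, x0=[mu0, math.log(s0)], bounds=([-50, -8], [50, 4]), xtol=1e-14
    )
    if sol.success and float(np.abs(sol.fun).max()) < 1e-8:
        return float(sol.x[0]), float(math.exp(sol.x[1]))

    # fallback: exact truncated mean, sigma from the closed form
    def mean_err(mu: float) -> float:
        m, _ = _trunc_ln_moments(mu, s0, lo_eff, upper)
        if not np.isfinite(m):  # truncation probability underflowed: the
            # truncated mass collapses onto the nearer bound
            m = lo_eff if mu < math.log(max(lo_eff, 1e-300)) else upper
        return m - target_mean

    lo_mu, hi_mu = mu0 - 30.0, mu0 + 30.0
    if mean_err(lo_mu) * mean_err(hi_mu) > 0:  # degenerate; keep closed form
        return mu0, s0
    mu = optimize.brentq(mean_err, lo_mu, hi_mu, xtol=1e-13)
    return float(mu), s0


# ---------------------------------------------------------------------------
# Marginal sampling (inverse-CDF through a standard-normal score)
# ---------------------------------------------------------------------------

def _values_from_scores(spec: MarginalSpec, u: np.ndarray) -> np.ndarray:
    """Map standard-normal scores to the spec's truncated marginal.

    Inverse-CDF coupling: p = Φ(u) is mapped through the truncated marginal's
    quantile function, so the marginal is exact and the map is monotone in u
    (latent-factor correlation is preserved with the intended sign).
    """
    p = special.ndtr(u)
    if spec.family == "bernoulli":
        return (p < spec.mean).astype(float)
    if spec.family == "truncated_gaussian":
        a = (spec.lower - spec.mean) / spec.sd
        b = (spec.upper - spec.mean) / spec.sd
        pa, pb = special.ndtr(a), special.ndtr(b)
        q = special.ndtri(np.clip(pa + p * (pb - pa), 1e-15, 1 - 1e-15))
        return np.clip(spec.mean + spec.sd * q, spec.lower, spec.upper)
    # truncated lognormal calibrated so the truncated mean matches spec.mean
    mu, sigma = truncated_lognormal_params(spec.mean, spec.sd, spec.lower, spec.upper)
    lo = max(spec.lower, 0.0)
    a = (math.log(lo) - mu) / sigma if lo > 0 else -np.inf
    b = (math.log(spec.upper) - mu) / sigma
    pa, pb = special.ndtr(a), special.ndtr(b)
    q = special.ndtri(np.clip(pa + p * (pb - pa), 1e-15, 1 - 1e-15))
    return np.clip(np.exp(mu + sigma * q), spec.lower, spec.upper)


def sample_marginal(spec: MarginalSpec, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. values from one variable's truncated marginal."""
    rng = np.random.default_rng(seed)
    return _values_from_scores(spec, rng.standard_normal(n))


# ---------------------------------------------------------------------------
# Default study specification
# ---------------------------------------------------------------------------

# name, unit, family, mean, sd, lower, upper  — clinical/biometric variables.
# Marginals follow the published cohort summary; right-skewed analytes
# (CRP, TG, glycaemia, HbA1c, homocysteine) are lognormal, the rest Gaussian.
_CLINICAL_ROWS: tuple[tuple[str, str, str, float, float, float, float], ...] = (
    ("AGE", "years", "truncated_gaussian", 51.0, 12.0, 30.0, 79.0),
    ("BMI", "kg/m2", "truncated_gaussian", 32.7, 5.7, 27.5, 54.7),
    ("WC", "cm", "truncated_gaussian", 99.0, 13.0, 75.0, 137.0),
    ("SBP", "mmHg", "truncated_gaussian", 124.0, 17.0, 85.0, 170.0),
    ("DBP", "mmHg", "truncated_gaussian", 79.0, 11.0, 55.0, 100.0),
    ("HR", "bpm", "truncated_gaussian", 72.0, 9.0, 52.0, 100.0),
    ("WBC", "10^9/L", "truncated_gaussian", 6.90, 1.79, 3.69, 14.39),
    ("RBC", "10^12/L", "truncated_gaussian", 4.85, 0.48, 3.71, 6.49),
    ("HGB", "g/dL", "truncated_gaussian", 13.7, 1.3, 10.4, 17.4),
    ("HCT", "%", "truncated_gaussian", 41.0, 3.0, 32.0, 50.0),
    ("PLT", "10^9/L", "truncated_gaussian", 248.0, 59.0, 72.0, 414.0),
    ("FIB", "mg/dL", "truncated_gaussian", 332.0, 61.0, 70.0, 491.0),
    ("CRP", "mg/dL", "lognormal", 0.51, 0.77, 0.03, 4.48),
    ("UA", "mg/dL", "truncated_gaussian", 4.9, 1.2, 1.8, 8.2),
    ("CREA", "mg/dL", "truncated_gaussian", 0.74, 0.13, 0.51, 1.16),
    ("TRIGLY", "mg/dL", "lognormal", 109.0, 47.0, 43.0, 279.0),
    ("CHOL_T", "mg/dL", "truncated_gaussian", 216.0, 41.0, 126.0, 336.0),
    ("LDL_C", "mg/dL", "truncated_gaussian", 132.0, 36.0, 58.0, 226.0),
    ("HCY", "umol/L", "lognormal", 10.9, 3.8, 5.0, 27.8),
    ("GLY", "mg/dL", "lognormal", 96.0, 27.0, 57.0, 297.0),
    ("INS", "mIU/mL", "truncated_gaussian", 12.50, 6.01, 0.40, 32.60),
    ("GLYCHB", "%", "lognormal", 5.9, 0.7, 4.4, 9.5),
    # auxiliary primitives required by the index formulas; marginals are
    # population-plausible defaults, NOT calibrated to the study (documented)
    ("SEX", "female=1", "bernoulli", 0.5, 0.5, 0.0, 1.0),
    ("HDL", "mg/dL", "truncated_gaussian", 52.0, 13.0, 20.0, 100.0),
    ("GGT", "U/L", "lognormal", 30.0, 20.0, 5.0, 300.0),
    ("SMOKER", "yes=1", "bernoulli", 0.25, 0.433, 0.0, 1.0),
    ("BP_TREATED", "yes=1", "bernoulli", 0.30, 0.458, 0.0, 1.0),
    # CV risk per the Italian CUORE charts is sampled from its published
    # marginal (the charts themselves are not reimplemented)
    ("CV_RISK", "%", "lognormal", 4.1, 5.5, 0.2, 29.0),
    # composite indices: specs document the published marginals, but the
    # simulator computes these from the primitives above (never samples them)
    ("FLI", "", "truncated_gaussian", 57.6, 28.5, 5.0, 99.7),
    ("VAI", "", "lognormal", 3.8, 2.6, 0.9, 17.5),
    ("FRAM", "points", "truncated_gaussian", 3.8, 3.9, 0.0, 20.0),
)

# (mean, sd, min, max) per element, μg/g, in panel order
_ELEMENT_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "Al": (7.64, 13.12, 0.70, 94.00), "Sb": (0.05, 0.12, 0.01, 1.10),
    "As": (0.04, 0.04, 0.01, 0.27), "Ba": (1.29, 1.63, 0.04, 11.00),
    "Bi": (0.06, 0.18, 0.00, 1.60), "Cd": (0.74, 6.66, 0.00, 65.00),
    "Pb": (1.59, 3.49, 0.04, 29.00), "Hg": (1.64, 1.49, 0.09, 7.80),
    "U": (0.11, 0.12, 0.01, 0.63), "Ni": (0.52, 0.82, 0.04, 6.20),
    "Ag": (1.68, 5.13, 0.01, 38.00), "Sn": (0.86, 1.48, 0.02, 7.80),
    "Ti": (0.74, 0.44, 0.24, 2.40), "Cu": (17.01, 14.96, 6.70, 140.00),
    "Zn": (176.6, 63.7, 61.0, 440.0), "Mn": (0.27, 0.37, 0.03, 3.20),
    "Cr": (0.47, 0.10, 0.33, 0.94), "V": (0.05, 0.04, 0.01, 0.33),
    "Mo": (0.03, 0.01, 0.01, 0.08), "B": (0.97, 0.82, 0.07, 4.70),
    "I": (1.14, 3.06, 0.07, 26.00), "Li": (0.02, 0.08, 0.00, 0.75),
    "Se": (0.94, 2.54, 0.21, 25.00), "Sr": (9.70, 8.16, 0.16, 35.00),
    "S": (47376.0, 1955.0, 43400.0, 51400.0), "Co": (0.05, 0.09, 0.00, 0.49),
    "Fe": (15.07, 6.22, 3.90, 36.00), "Ge": (0.03, 0.01, 0.03, 0.05),
    "Rb": (0.08, 0.17, 0.00, 1.10), "Zr": (0.05, 0.06, 0.01, 0.40),
    "Au": (0.14, 0.34, 0.00, 3.00),
}

# variables computed from primitives rather than sampled
DERIVED_VARIABLES: tuple[str, ...] = ("FLI", "VAI", "FRAM")
_COMPUTED_EXTRA: tuple[tuple[str, str], ...] = (
    ("MET_S", "bool"), ("OB", "bool"), ("TI", ""),
)

_METABOLIC_VARS = ("WC", "BMI", "TRIGLY", "INS", "GLY", "GLYCHB", "FIB", "UA")
_DEFAULT_LOADING = 0.6


def default_study_spec() -> tuple[list[MarginalSpec], LatentStructure, ElementSchema]:
    """Marginal specs, latent structure and element schema of the default study.

    Covers the 25 published clinical variables plus age and the auxiliary
    primitives the index formulas need (sex, HDL, GGT, smoking, BP treatment),
    and all 31 hair elements as truncated lognormals calibrated to the
    published mean/SD within the published min/max. Default cohort size: 95.
    """
    specs = [MarginalSpec(name, fam, m, s, lo, hi, unit)
             for name, unit, fam, m, s, lo, hi in _CLINICAL_ROWS]
    for sym, (m, s, lo, hi) in _ELEMENT_MOMENTS.items():
        specs.append(MarginalSpec(sym, "lognormal", m, s, max(lo, 0.0), hi, "ug/g"))

    loadings: dict[str, dict[str, float]] = {}
    for v in _METABOLIC_VARS:
        loadings[v] = {"metabolic": _DEFAULT_LOADING}
    for sym in TOXIC_SYMBOLS:
        loadings[sym] = {"exposure": _DEFAULT_LOADING}
    structure = LatentStructure(("metabolic", "exposure"), loadings)
    return specs, structure, default_element_schema()


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    specs: list[MarginalSpec],
    structure: LatentStructure,
    n: int = DEFAULT_N,
    seed: int = 0,
) -> CohortTable:
    """Simulate a cohort: sampled primitives plus computed composite indices.

    Deterministic for a fixed seed. Variables are sampled in declaration order
    from their truncated marginals, correlated through the latent factors;
    FLI, VAI, Framingham points, MetS, obesity and TI are then computed from
    the simulated primitives whenever the required primitives are present.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    spec_names = [s.variable_name for s in specs]
    unknown = [v for v in structure.loadings if v not in spec_names]
    if unknown:
        raise ValueError(f"latent structure loads unknown variables: {unknown}")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(structure.factor_names)))

    columns: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for spec in specs:
        eps = rng.standard_normal(n)  # drawn for every spec to keep the
        # stream aligned regardless of which variables are derived
        if spec.variable_name in DERIVED_VARIABLES:
            continue
        lam = structure.loading_vector(spec.variable_name)
        s_idio = structure.noise_sd * math.sqrt(max(1.0 - float(lam @ lam), 0.0))
        u = z @ lam + s_idio * eps
        scale = math.sqrt(float(lam @ lam) + s_idio**2)
        if scale > 0:
            u = u / scale
        columns[spec.variable_name] = _values_from_scores(spec, u)
        units[spec.variable_name] = spec.unit

    _append_derived(columns, units)

    names = list(columns)
    values = np.column_stack([columns[v] for v in names])
    return CohortTable(
        subject_ids=[f"S{i+1:03d}" for i in range(n)],
        variables=[(v, units[v]) for v in names],
        values=values,
    )


def _append_derived(columns: dict[str, np.ndarray], units: dict[str, str]) -> None:
    """Compute composite indices from simulated primitives, where available."""
    need = ("AGE", "SEX", "BMI", "WC", "TRIGLY", "HDL", "GGT", "CHOL_T",
            "SBP", "DBP", "GLY", "SMOKER", "BP_TREATED")
    if any(v not in columns for v in need):
        return
    n = len(columns["BMI"])
    have_elements = all(sym in columns for sym in TOXIC_SYMBOLS)

    fli = np.empty(n)
    vai = np.empty(n)
    fram = np.empty(n)
    mets = np.empty(n)
    ob = np.empty(n)
    ti = np.empty(n) if have_elements else None
    for i in range(n):
        sex = "female" if columns["SEX"][i] > 0.5 else "male"
        tg = columns["TRIGLY"][i]
        hdl = columns["HDL"][i]
        fli[i] = fatty_liver_index(tg, columns["BMI"][i], columns["GGT"][i], columns["WC"][i])
        vai[i] = visceral_adiposity_index(
            sex, columns["WC"][i], columns["BMI"][i],
            tg_mgdl_to_mmoll(tg), chol_mgdl_to_mmoll(hdl),
        )
        points, _ = framingham_risk(
            columns["AGE"][i], sex, columns["CHOL_T"][i], hdl, columns["SBP"][i],
            bool(columns["BP_TREATED"][i]), bool(columns["SMOKER"][i]),
            diabetes=bool(columns["GLY"][i] >= 126.0),
        )
        fram[i] = points
        mets[i] = float(mets_atpiii(
            columns["WC"][i], sex, tg, hdl, columns["SBP"][i], columns["DBP"][i],
            bool(columns["BP_TREATED"][i]), columns["GLY"][i],
        ))
        ob[i] = float(obesity_flag(columns["BMI"][i]))
        if have_elements:
            conc = {sym: columns[sym][i] for sym in TOXIC_SYMBOLS}
            ti[i] = toxicity_index(conc)

    columns["FLI"] = fli
    units["FLI"] = ""
    columns["VAI"] = vai
    units["VAI"] = ""
    columns["FRAM"] = fram
    units["FRAM"] = "points"
    columns["MET_S"] = mets
    units["MET_S"] = "bool"
    columns["OB"] = ob
    units["OB"] = "bool"
    if have_elements:
        columns["TI"] = ti
        units["TI"] = ""
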