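"""Spot-urine estimators of 24-h urinary sodium excretion.

Three estimators with explicit unit contracts:

* **MyCoSS** — a direct-regression equation developed for Malaysian adults:
  ``909.368 + 24.052·weight(kg) − 0.11·age²(y²) + 538.38·[male]
  + 0.269·spotNa(mg/L) − 5.469·spotCr(mg/dL) + 5.541·spotK(mmol/L)``,
  returning mg/day.
* **Tanaka** — ratio method: spot Na/Cr scaled by predicted 24-h creatinine
  (PRCr from age, weight, height in cm), returning mmol/day.
* **INTERSALT** — sex-specific direct regression over spot chemistry
  (mmol/L), BMI and age, returning mmol/day.

Records store spot sodium in mg/L and height in metres; each predictor
performs its own documented conversions at the call boundary. Output-unit
conversion (mmol → mg → g salt) is always an explicit separate step via
:mod:`spotna24.units` — never baked into coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import NA_MG_PER_MMOL, SodiumAmount, convert_creatinine

__all__ = [
    "MycossCoefficients",
    "TanakaCoefficients",
    "IntersaltCoefficients",
    "predict_mycoss",
    "predict_tanaka",
    "predict_intersalt",
]

#: spot sodium below this (mg/L) is plausibly an mmol/L entry → warning
_SPOT_NA_MG_L_SUSPECT = 400.0


@dataclass(frozen=True)
class MycossCoefficients:
    """Published MyCoSS equation coefficients (output mg/day)."""

    intercept: float = 909.368    # mg/day
    b_weight: float = 24.052      # per kg
    b_age2: float = -0.11         # per year²
    b_male: float = 538.38        # mg/day
    b_spot_na: float = 0.269      # per mg/L
    b_spot_cr: float = -5.469     # per mg/dL
    b_spot_k: float = 5.541       # per mmol/L


@dataclass(frozen=True)
class TanakaCoefficients:
    """Tanaka estimator constants (output mmol/day).

    ``prcr_const`` defaults to the canonical −2244.45; the variant printed
    in some secondary sources, −224.45, yields implausible predicted
    creatinine and is selectable for audit via ``variant="as_printed"``.
    """

    scale: float = 21.98
    exponent: float = 0.392
    prcr_age: float = -2.04       # per year
    prcr_weight: float = 14.89    # per kg
    prcr_height_cm: float = 16.14  # per cm
    prcr_const: float = -2244.45

    def __post_init__(self):
        if not 0.0 < self.exponent < 1.0:
            raise ValueError(f"exponent must be in (0, 1), got {self.exponent}")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @classmethod
    def as_printed(cls) -> "TanakaCoefficients":
        return cls(prcr_const=-224.45)


@dataclass(frozen=True)
class IntersaltCoefficients:
    """INTERSALT sex-specific coefficient sets (output mmol/day).

    Order: (constant, spot Na mmol/L, spot Cr mmol/L, spot K mmol/L,
    BMI kg/m², age y, age² y²). The male set has no age² term.
    """

    male: tuple = (25.46, 0.46, -2.75, -0.13, 4.10, 0.26, 0.0)
    female: tuple = (5.07, 0.34, -2.16, -0.09, 2.39, 2.35, -0.03)


def _columns(data, names):
    """Extract covariate columns from a DataFrame / record / mapping.

    Returns (dict of float arrays, scalar_input flag).
    """
    if hasattr(data, "to_frame") and not isinstance(data, pd.DataFrame):
        data = data.to_frame()
    if isinstance(data, pd.DataFrame):
        missing = [c for c in names if c not in data.columns]
        if missing:
            raise ValueError(f"input is missing required columns: {missing}")
        return {c: data[c].to_numpy(dtype=float) if c != "sex"
                else data[c].to_numpy() for c in names}, False
    # single record-ish: mapping or attribute access
    out = {}
    for c in names:
        if isinstance(data, dict):
            if c not in data:
                raise ValueError(f"input is missing required field {c!r}")
            out[c] = data[c]
        else:
            if not hasattr(data, c):
                raise ValueError(f"input is missing required field {c!r}")
            out[c] = getattr(data, c)
    return {c: (np.asarray([v]) if c == "sex" else np.asarray([v], dtype=float))
            for c, v in out.items()}, True


def _male_indicator(sex_col) -> np.ndarray:
    sex = np.asarray(sex_col).astype(str)
    ok = np.isin(np.char.upper(sex), ("M", "F"))
    if not ok.all():
        bad = sorted(set(sex[~ok]))
        raise ValueError(f"sex must be coded 'M'/'F', got {bad}")
    return (np.char.upper(sex) == "M").astype(float)


def _wrap(values: np.ndarray, unit: str, scalar: bool) -> SodiumAmount:
    return SodiumAmount(float(values[0]) if scalar else values, unit)


def predict_mycoss(data, coefficients: MycossCoefficients | None = None) -> SodiumAmount:
    """MyCoSS estimate of 24-h sodium, mg/day.

    ``data`` is a cohort DataFrame, a ParticipantRecord, or a mapping with
    the cohort column names. Spot sodium is consumed in mg/L; values below
    400 raise a unit-suspicion warning (plausibly mmol/L), not an error.
    """
    c = coefficients or MycossCoefficients()
    cols, scalar = _columns(data, ["sex", "age_y", "weight_kg", "spot_na_mg_l",
                                   "spot_cr_mg_dl", "spot_k_mmol_l"])
    male = _male_indicator(cols["sex"])
    spot_na = cols["spot_na_mg_l"]
    low = spot_na[~np.isnan(spot_na)] < _SPOT_NA_MG_L_SUSPECT
    if low.any():
        warnings.warn(
            f"{int(low.sum())} spot sodium value(s) below "
            f"{_SPOT_NA_MG_L_SUSPECT:g} mg/L — check they are not mmol/L",
            stacklevel=2)
    est = (c.intercept
           + c.b_weight * cols["weight_kg"]
           + c.b_age2 * cols["age_y"] ** 2
           + c.b_male * male
           + c.b_spot_na * spot_na
           + c.b_spot_cr * cols["spot_cr_mg_dl"]
           + c.b_spot_k * cols["spot_k_mmol_l"])
    return _wrap(est, "mg/day", scalar)


def predict_tanaka(data, coefficients: TanakaCoefficients | None = None,
                   variant: str = "canonical", *, on_invalid: str = "raise") -> SodiumAmount:
    """Tanaka estimate of 24-h sodium, mmol/day.

    estimate = scale · (spotNa_mmol / (spotCr_mgdl · 10) · PRCr)^exponent,
    PRCr = −2.04·age + 14.89·weight + 16.14·height_cm + const.

    Spot sodium is converted mg/L → mmol/L and height m → cm here, at the
    boundary. ``on_invalid``: "raise" (default) errors on spot Cr = 0 or
    PRCr ≤ 0; "nan" returns NaN for those records instead.
    """
    if variant not in ("canonical", "as_printed"):
        raise ValueError(f"variant must be 'canonical' or 'as_printed', got {variant!r}")
    if coefficients is None:
        coefficients = (TanakaCoefficients() if variant == "canonical"
                        else TanakaCoefficients.as_printed())
    c = coefficients
    cols, scalar = _columns(data, ["age_y", "weight_kg", "height_m",
                                   "spot_na_mg_l", "spot_cr_mg_dl"])
    spot_na_mmol = cols["spot_na_mg_l"] / NA_MG_PER_MMOL
    spot_cr = cols["spot_cr_mg_dl"]
    prcr = (c.prcr_age * cols["age_y"] + c.prcr_weight * cols["weight_kg"]
            + c.prcr_height_cm * cols["height_m"] * 100.0 + c.prcr_const)

    zero_cr = spot_cr == 0
    bad_prcr = prcr <= 0
    if on_invalid == "raise":
        if zero_cr.any():
            raise ZeroDivisionError("spot creatinine is 0 mg/dL: the Tanaka "
                                    "sodium/creatinine ratio is undefined")
        if bad_prcr.any():
            raise ValueError(
                "predicted 24-h creatinine (PRCr) <= 0 for some records; a "
                "fractional power of a non-positive base is undefined — check "
                "covariates or use the canonical PRCr constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        base = spot_na_mmol / (spot_cr * 10.0) * prcr
        est = np.where(base == 0, 0.0,
                       c.scale * np.sign(base) * np.abs(base) ** c.exponent)
    est = np.where(zero_cr | bad_prcr | (base < 0), np.nan, est)
    return _wrap(est, "mmol/day", scalar)


def predict_intersalt(data, coefficients: IntersaltCoefficients | None = None) -> SodiumAmount:
    """INTERSALT estimate of 24-h sodium, mmol/day.

    Spot sodium mg/L → mmol/L and creatinine mg/dL → mmol/L conversions
    happen here; BMI is weight/height². The female set carries the −0.03·age²
    term; the male set has none.
    """
    c = coefficients or IntersaltCoefficients()
    cols, scalar = _columns(data, ["sex", "age_y", "weight_kg", "height_m",
                                   "spot_na_mg_l", "spot_cr_mg_dl", "spot_k_mmol_l"])
    height = cols["height_m"]
    if np.isnan(height).any() or np.isnan(cols["weight_kg"]).any():
        raise ValueError("BMI inputs (weight_kg, height_m) contain missing values")
    if (height <= 0).any():
        raise ValueError("height_m must be > 0 to form BMI")
    male = _male_indicator(cols["sex"])
    bmi = cols["weight_kg"] / height ** 2
    na_mmol = cols["spot_na_mg_l"] / NA_MG_PER_MMOL
    cr_mmol = convert_creatinine(cols["spot_cr_mg_dl"], "mg/dL", "mmol/L")
    covs = np.column_stack([
        np.ones_like(male), na_mmol, cr_mmol, cols["spot_k_mmol_l"],
        bmi, cols["age_y"], cols["age_y"] ** 2,
    ])
    est = np.where(male == 1.0,
                   covs @ np.asarray(c.male, dtype=float),
                   covs @ np.asarray(c.female, dtype=float))
    return _wrap(est, "mmol/day", scalar)
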