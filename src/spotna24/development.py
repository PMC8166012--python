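"""Prediction-equation development: random split, stepwise OLS, double
cross-validation with shrinkage, pooled final fit, and the correlation-based
sample-size calculation.

The development design mirrors the standard double cross-validation scheme
for regression equations: the cohort is randomly halved; an equation is
fitted in each half; each half's standardized beta weights are applied to
the *other* half's z-scored predictors to form per-subject composites, and
the correlation of composite with outcome gives the four multiple
correlations R[1,1], R[1,2], R[2,2], R[2,1]. Shrinkage — R² with own
weights minus R² with cross-applied weights — near zero licenses pooling
the halves into a single final equation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, linalg

from .equations import MycossCoefficients

__all__ = [
    "CANDIDATE_PREDICTORS",
    "RegressionFit",
    "CrossValidationResult",
    "ShrinkageError",
    "design_matrix",
    "split_cohort",
    "fit_ols",
    "stepwise_select",
    "double_cross_validate",
    "finalize_equation",
    "sample_size_correlation",
    "fit_to_coefficients",
    "equation_to_json",
    "equation_from_json",
]

#: default candidate set offered to stepwise selection. Age enters squared
#: (the published equation's age term is quadratic); add "age" via the
#: ``extra`` argument of :func:`design_matrix` to offer linear age too.
CANDIDATE_PREDICTORS = ["male", "weight", "height", "age2",
                        "spot_na", "spot_cr", "spot_k"]

_PREDICTOR_SOURCES = {
    "male": ("sex", lambda s: (s.astype(str).str.upper() == "M").astype(float)),
    "weight": ("weight_kg", None),
    "height": ("height_m", None),
    "age": ("age_y", None),
    "age2": ("age_y", lambda s: s.astype(float) ** 2),
    "spot_na": ("spot_na_mg_l", None),
    "spot_cr": ("spot_cr_mg_dl", None),
    "spot_k": ("spot_k_mmol_l", None),
}


class ShrinkageError(RuntimeError):
    """Raised when double-CV shrinkage exceeds the pooling threshold."""


@dataclass
class RegressionFit:
    """An OLS fit with both raw and standardized coefficients.

    ``beta[j] = b[j] · SD(x_j) / SD(y)`` (sample SDs); ``r`` is the multiple
    correlation √R². ``diagnostics`` carries residual-normality and
    heteroscedasticity summaries (no pass/fail gate is applied).
    """

    labels: list[str]
    b: np.ndarray
    se: np.ndarray
    p: np.ndarray
    beta: np.ndarray
    intercept: float
    intercept_se: float
    r: float
    r2: float
    resid_sd: float
    n: int
    outcome: str = "na24_mg"
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = X.loc[:, self.labels] if self.labels else X.iloc[:, :0]
        return self.intercept + (X.to_numpy(dtype=float) @ self.b
                                 if self.labels else 0.0)

    def coef(self, label: str) -> float:
        return float(self.b[self.labels.index(label)])


@dataclass(frozen=True)
class CrossValidationResult:
    """The four multiple correlations of double cross-validation.

    R[h, g] correlates group *h*'s outcome with the composite formed from
    group *g*'s standardized beta weights on group *h*'s z-scores.
    shrinkage1 = R11² − R12²; shrinkage2 = R22² − R21².
    """

    r11: float
    r12: float
    r22: float
    r21: float

    @property
    def shrinkage1(self) -> float:
        return self.r11 ** 2 - self.r12 ** 2

    @property
    def shrinkage2(self) -> float:
        return self.r22 ** 2 - self.r21 ** 2

    @property
    def max_abs_shrinkage(self) -> float:
        return max(abs(self.shrinkage1), abs(self.shrinkage2))


def design_matrix(records: pd.DataFrame,
                  labels: list[str] | None = None) -> pd.DataFrame:
    """Build the regression design from cohort columns.

    Labels name derived predictors: ``male`` (indicator from sex), ``age2``
    (age squared, years²), ``weight`` (kg), ``height`` (m), and the spot
    panel in its record units.
    """
    labels = list(labels) if labels is not None else list(CANDIDATE_PREDICTORS)
    out = {}
    for lab in labels:
        if lab not in _PREDICTOR_SOURCES:
            raise ValueError(f"unknown predictor label {lab!r}; "
                             f"known: {sorted(_PREDICTOR_SOURCES)}")
        col, fn = _PREDICTOR_SOURCES[lab]
        if col not in records.columns:
            raise ValueError(f"records are missing column {col!r} needed for "
                             f"predictor {lab!r}")
        s = records[col]
        out[lab] = (fn(s) if fn is not None else s.astype(float)).to_numpy()
    return pd.DataFrame(out, index=records.index)


def split_cohort(records: pd.DataFrame, seed: int,
                 ratio: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint split of the cohort into two development groups.

    At ratio 0.5 the sizes differ by at most one. Row order within each
    group follows the input. Seeded and reproducible.
    """
    n = len(records)
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n1 = int(round(n * ratio))
    n1 = min(max(n1, 1), n - 1)
    idx1 = np.sort(perm[:n1])
    idx2 = np.sort(perm[n1:])
    return (records.iloc[idx1].reset_index(drop=True),
            records.iloc[idx2].reset_index(drop=True))


def _check_design(X: pd.DataFrame, n: int) -> None:
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    constant = [c for c in X.columns if np.std(X[c].to_numpy(dtype=float)) == 0]
    if constant:
        raise ValueError(f"constant predictor columns: {constant}")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via pivoted QR: pivots beyond the rank
        _, _, piv = linalg.qr(design, pivoting=True, mode="economic")
        names = ["(intercept)"] + list(X.columns)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns involve: {bad}")


def fit_ols(y, X: pd.DataFrame, outcome: str = "na24_mg") -> RegressionFit:
    """Ordinary least squares of ``y`` on the predictor table ``X``.

    Reports unstandardized coefficients with SEs and two-sided t-based
    p-values (n − p − 1 df), standardized betas, multiple R, R² and
    residual SD, plus residual diagnostics (omnibus normality test,
    Breusch–Pagan heteroscedasticity test).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError(f"outcome length {n} != design rows {X.shape[0]}")
    _check_design(X, n)
    labels = list(X.columns)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, design).fit()

    sd_y = float(np.std(y, ddof=1))
    sd_x = np.std(X.to_numpy(dtype=float), axis=0, ddof=1)
    b = res.params[1:]
    beta = b * sd_x / sd_y if sd_y > 0 else np.zeros_like(b)
    resid = res.resid
    dof = n - len(labels) - 1
    diagnostics = {"n": n, "df_resid": dof,
                   "resid_mean": float(np.mean(resid)),
                   "resid_skew": float(stats.skew(resid)),
                   "resid_kurtosis": float(stats.kurtosis(resid))}
    if n >= 20:
        diagnostics["normality_p"] = float(stats.normaltest(resid).pvalue)
        bp = sm.stats.diagnostic.het_breuschpagan(resid, design)
        diagnostics["breusch_pagan_p"] = float(bp[1])
    return RegressionFit(
        labels=labels,
        b=np.asarray(b, dtype=float),
        se=np.asarray(res.bse[1:], dtype=float),
        p=np.asarray(res.pvalues[1:], dtype=float),
        beta=np.asarray(beta, dtype=float),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        r=float(np.sqrt(max(res.rsquared, 0.0))),
        r2=float(res.rsquared),
        resid_sd=float(np.sqrt(res.ssr / dof)) if dof > 0 else float("nan"),
        n=n,
        outcome=outcome,
        diagnostics=diagnostics,
    )


def stepwise_select(y, candidates: pd.DataFrame,
                    p_enter: float = 0.05, p_remove: float = 0.10,
                    outcome: str = "na24_mg") -> RegressionFit:
    """Stepwise OLS: iteratively add the most significant candidate
    (p < p_enter) and drop any retained predictor whose p rises above
    p_remove, until the model is stable.

    Requires ``p_remove > p_enter`` (guarantees termination: a variable
    cannot oscillate in and out). Selection is deterministic given the
    data. If no candidate reaches ``p_enter``, an intercept-only fit is
    returned with a warning.
    """
    if not 0.0 < p_enter < 1.0 or not 0.0 < p_remove <= 1.0:
        raise ValueError("p_enter and p_remove must be in (0, 1]")
    if p_remove <= p_enter and p_remove < 1.0:
        raise ValueError(f"p_remove ({p_remove}) must exceed p_enter "
                         f"({p_enter}) for the iteration to terminate")
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    remaining = list(candidates.columns)
    while True:
        changed = False
        # forward: best candidate by p-value
        best_p, best_lab = p_enter, None
        for lab in remaining:
            trial = fit_ols(y, candidates.loc[:, selected + [lab]], outcome)
            p_lab = trial.p[trial.labels.index(lab)]
            if p_lab < best_p:
                best_p, best_lab = p_lab, lab
        if best_lab is not None:
            selected.append(best_lab)
            remaining.remove(best_lab)
            changed = True
        # backward: drop the worst retained predictor above p_remove
        while selected:
            fit = fit_ols(y, candidates.loc[:, selected], outcome)
            worst = int(np.argmax(fit.p))
            if fit.p[worst] <= p_remove:
                break
            lab = fit.labels[worst]
            selected.remove(lab)
            remaining.append(lab)
            changed = True
        if not changed:
            break
    if not selected:
        warnings.warn("no candidate reached p_enter; returning intercept-only fit",
                      stacklevel=2)
        mean = float(np.mean(y))
        dof = len(y) - 1
        return RegressionFit(
            labels=[], b=np.array([]), se=np.array([]), p=np.array([]),
            beta=np.array([]), intercept=mean,
            intercept_se=float(np.std(y, ddof=1) / math.sqrt(len(y))),
            r=0.0, r2=0.0, resid_sd=float(np.std(y, ddof=1)), n=len(y),
            outcome=outcome, diagnostics={"n": len(y), "df_resid": dof},
        )
    return fit_ols(y, candidates.loc[:, selected], outcome)


def _zscore(X: np.ndarray, mean=None, sd=None):
    mean = X.mean(axis=0) if mean is None else mean
    sd = X.std(axis=0, ddof=1) if sd is None else sd
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant predictor column")
    return (X - mean) / sd, mean, sd


def double_cross_validate(group1: pd.DataFrame, group2: pd.DataFrame,
                          predictors: list[str] | None = None,
                          outcome: str = "na24_mg",
                          standardize: str = "own") -> CrossValidationResult:
    """Double cross-validation of a common predictor set across two groups.

    Each group's OLS fit yields standardized beta weights; composites
    Σ_j β_j(g)·z_j(h) are correlated with group *h*'s outcome to give
    R[h,g] (first index: evaluation group; second: weight source). The
    shrinkage differences R11²−R12² and R22²−R21² therefore compare, on the
    same half's data, its own in-sample weights against the weights carried
    over from the opposite half. ``standardize="own"`` (default) z-scores
    each group by its own mean/SD; ``"cross"`` standardizes the evaluation
    group by the weight-source group's moments.
    """
    predictors = list(predictors) if predictors is not None else list(CANDIDATE_PREDICTORS)
    if standardize not in ("own", "cross"):
        raise ValueError(f"standardize must be 'own' or 'cross', got {standardize!r}")
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be nonempty")
    X1 = design_matrix(group1, predictors)
    X2 = design_matrix(group2, predictors)
    y1 = group1[outcome].to_numpy(dtype=float)
    y2 = group2[outcome].to_numpy(dtype=float)
    fit1 = fit_ols(y1, X1, outcome)
    fit2 = fit_ols(y2, X2, outcome)

    z1, m1, s1 = _zscore(X1.to_numpy(dtype=float))
    z2, m2, s2 = _zscore(X2.to_numpy(dtype=float))

    def corr(c, y):
        return float(np.corrcoef(c, y)[0, 1])

    r11 = corr(z1 @ fit1.beta, y1)
    r22 = corr(z2 @ fit2.beta, y2)
    if standardize == "own":
        z1_for_12, z2_for_21 = z1, z2
    else:
        # standardize the evaluation group by the weight-source group's moments
        z1_for_12 = (X1.to_numpy(dtype=float) - m2) / s2
        z2_for_21 = (X2.to_numpy(dtype=float) - m1) / s1
    r12 = corr(z1_for_12 @ fit2.beta, y1)  # group-2 weights evaluated in group 1
    r21 = corr(z2_for_21 @ fit1.beta, y2)  # group-1 weights evaluated in group 2
    return CrossValidationResult(r11=r11, r12=r12, r22=r22, r21=r21)


def finalize_equation(records: pd.DataFrame,
                      predictors: list[str] | None = None,
                      cv: CrossValidationResult | None = None,
                      shrinkage_threshold: float = 0.05,
                      force: bool = False,
                      outcome: str = "na24_mg") -> RegressionFit:
    """Pooled fit over the full cohort, gated on small shrinkage.

    If a :class:`CrossValidationResult` is supplied and either shrinkage
    magnitude exceeds ``shrinkage_threshold``, the equation is refused
    (``ShrinkageError``) unless ``force=True``.
    """
    predictors = list(predictors) if predictors is not None else list(CANDIDATE_PREDICTORS)
    if cv is not None and not force and cv.max_abs_shrinkage > shrinkage_threshold:
        raise ShrinkageError(
            f"double-CV shrinkage ({cv.shrinkage1:+.4f}, {cv.shrinkage2:+.4f}) "
            f"exceeds threshold {shrinkage_threshold}; the subgroup equations "
            "do not replicate — pass force=True to pool anyway")
    X = design_matrix(records, predictors)
    return fit_ols(records[outcome].to_numpy(dtype=float), X, outcome)


def sample_size_correlation(target_r: float, alpha: float = 0.05,
                            power: float = 0.80) -> int:
    """Minimum n to detect a correlation ``target_r`` (Fisher z method).

    C = ½·ln((1+r)/(1−r)); n = ⌊((z_{1−α/2} + z_power)/C)²⌋ + 3, the squared
    term truncated before adding 3 (the convention of the statistical
    software commonly used for this calculation).
    """
    if not 0.0 < abs(target_r) < 1.0:
        raise ValueError(f"target_r must satisfy 0 < |r| < 1, got {target_r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must be in (0, 1), got {power}")
    c = 0.5 * math.log((1.0 + abs(target_r)) / (1.0 - abs(target_r)))
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return int((z / c) ** 2) + 3


def fit_to_coefficients(fit: RegressionFit) -> MycossCoefficients:
    """Map a fitted equation onto the MyCoSS coefficient slots.

    Requires the fit's predictors to be a subset of the canonical slots
    (male, weight, age2, spot_na, spot_cr, spot_k); absent predictors get
    coefficient 0.
    """
    slots = {"male": "b_male", "weight": "b_weight", "age2": "b_age2",
             "spot_na": "b_spot_na", "spot_cr": "b_spot_cr", "spot_k": "b_spot_k"}
    unknown = [lab for lab in fit.labels if lab not in slots]
    if unknown:
        raise ValueError(f"predictors {unknown} have no MyCoSS coefficient slot")
    kwargs = {"intercept": fit.intercept}
    kwargs.update({slots[lab]: 0.0 for lab in slots})
    for lab in fit.labels:
        kwargs[slots[lab]] = fit.coef(lab)
    return MycossCoefficients(**kwargs)


def equation_to_json(fit: RegressionFit, path=None, meta: dict | None = None) -> str:
    """Serialize a fitted equation (labels, coefficients, units, fit metadata)."""
    payload = {
        "outcome": fit.outcome,
        "outcome_unit": "mg/day",
        "intercept": fit.intercept,
        "predictors": [
            {"label": lab, "b": float(fit.b[i]), "se": float(fit.se[i]),
             "p": float(fit.p[i]), "beta": float(fit.beta[i])}
            for i, lab in enumerate(fit.labels)
        ],
        "r": fit.r, "r2": fit.r2, "resid_sd": fit.resid_sd, "n": fit.n,
        "meta": meta or {},
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def equation_from_json(source) -> RegressionFit:
    """Load a fitted equation written by :func:`equation_to_json`."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(text) as fh:
                payload = json.load(fh)
    preds = payload["predictors"]
    return RegressionFit(
        labels=[p["label"] for p in preds],
        b=np.array([p["b"] for p in preds], dtype=float),
        se=np.array([p["se"] for p in preds], dtype=float),
        p=np.array([p["p"] for p in preds], dtype=float),
        beta=np.array([p["beta"] for p in preds], dtype=float),
        intercept=float(payload["intercept"]),
        intercept_se=float("nan"),
        r=float(payload["r"]), r2=float(payload["r2"]),
        resid_sd=float(payload["resid_sd"]), n=int(payload["n"]),
        outcome=payload.get("outcome", "na24_mg"),
        diagnostics=dict(payload.get("meta", {})),
    )
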