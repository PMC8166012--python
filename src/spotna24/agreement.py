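"""Agreement between predicted and measured 24-h sodium.

Bland–Altman analysis on differences d = predicted − measured: mean bias,
its 95 % CI, and limits of agreement mean ± 1.96·SD(d) expected to contain
~95 % of individual differences. The 1.96 normal quantile is the default
multiplier (matching the convention the published limits back-calculate
to); a t-based alternative is available. Pearson correlations against the
measured outcome and a multi-equation comparison table complete the
validation surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .equations import (IntersaltCoefficients, MycossCoefficients,
                        TanakaCoefficients, predict_intersalt, predict_mycoss,
                        predict_tanaka)
from .units import convert_sodium

__all__ = [
    "AgreementResult",
    "CorrelationResult",
    "bland_altman",
    "pearson_r",
    "standard_estimators",
    "compare_equations",
]

_LOA_Z = 1.96


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of predicted − measured differences (mg/day)."""

    n: int
    mean_bias: float
    bias_ci_low: float
    bias_ci_high: float
    loa_low: float
    loa_high: float
    sd_diff: float
    #: two-sided p for mean difference = 0 (same quantile convention as the CI)
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def bland_altman(predicted, measured, ci_method: str = "z") -> AgreementResult:
    """Bland–Altman agreement of paired predictions with measurements.

    Differences are predicted − measured (never silently reversed).
    ``ci_method="z"`` uses the 1.96 normal quantile for both the bias CI
    and the limits of agreement; ``"t"`` uses the t(n−1) 97.5 % quantile.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError(f"length mismatch: predicted {predicted.shape} vs "
                         f"measured {measured.shape}")
    d = predicted - measured
    n = d.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if ci_method not in ("z", "t"):
        raise ValueError(f"ci_method must be 'z' or 't', got {ci_method!r}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    q = _LOA_Z if ci_method == "z" else float(stats.t.ppf(0.975, n - 1))
    half_ci = q * sd / np.sqrt(n)
    if sd == 0:
        p = 1.0 if mean == 0 else 0.0
    else:
        z = mean / (sd / np.sqrt(n))
        p = (2.0 * stats.norm.sf(abs(z)) if ci_method == "z"
             else 2.0 * stats.t.sf(abs(z), n - 1))
    return AgreementResult(
        n=n, mean_bias=mean,
        bias_ci_low=mean - half_ci, bias_ci_high=mean + half_ci,
        loa_low=mean - q * sd, loa_high=mean + q * sd,
        sd_diff=sd, p_value=float(p),
    )


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def standard_estimators(mycoss: MycossCoefficients | None = None,
                        tanaka: TanakaCoefficients | None = None,
                        intersalt: IntersaltCoefficients | None = None):
    """The three standard estimators as (name, cohort → mg/day array) pairs.

    Tanaka records with an undefined estimate (spot Cr = 0 or PRCr ≤ 0)
    come back NaN and are skipped by :func:`compare_equations`.
    """
    return [
        ("mycoss", lambda df: np.asarray(
            convert_sodium(predict_mycoss(df, mycoss), "mg/day").value)),
        ("tanaka", lambda df: np.asarray(convert_sodium(
            predict_tanaka(df, tanaka, on_invalid="nan"), "mg/day").value)),
        ("intersalt", lambda df: np.asarray(
            convert_sodium(predict_intersalt(df, intersalt), "mg/day").value)),
    ]


def compare_equations(cohort: pd.DataFrame, estimators,
                      outcome: str = "na24_mg",
                      ci_method: str = "z") -> pd.DataFrame:
    """Agreement + correlation of each estimator against measured 24-h
    sodium, one row per estimator, ordered by |mean bias| ascending.

    ``estimators`` is an iterable of (name, fn) where ``fn(cohort)`` returns
    per-subject estimates in mg/day (NaN = estimator undefined for that
    record; such records are dropped for that row with ``n`` adjusted and
    ``n_skipped`` reported).
    """
    measured = cohort[outcome].to_numpy(dtype=float)
    rows = []
    for name, fn in estimators:
        pred = np.asarray(fn(cohort), dtype=float)
        ok = ~(np.isnan(pred) | np.isnan(measured))
        n_skipped = int((~ok).sum())
        agr = bland_altman(pred[ok], measured[ok], ci_method=ci_method)
        cor = pearson_r(pred[ok], measured[ok])
        rows.append({
            "equation": name, "n": agr.n, "n_skipped": n_skipped,
            "mean_bias": agr.mean_bias,
            "ci_low": agr.bias_ci_low, "ci_high": agr.bias_ci_high,
            "loa_low": agr.loa_low, "loa_high": agr.loa_high,
            "sd_diff": agr.sd_diff, "bias_p": agr.p_value,
            "pearson_r": cor.r, "p": cor.p_value,
        })
    table = pd.DataFrame(rows)
    return (table.reindex(table["mean_bias"].abs().sort_values(kind="stable").index)
            .reset_index(drop=True))
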