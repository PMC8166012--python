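"""Published reference values for the MyCoSS validation cohort.

Agreement and correlation statistics reported for the MyCoSS equation and
its comparators (Tanaka, INTERSALT) on the original Malaysian validation
cohort (n = 768). These are inputs for internal-consistency checks — e.g.
the midpoint of the reported limits of agreement must recover the reported
mean bias — and for side-by-side display next to synthetic-cohort runs.
All sodium quantities are mg/day.
"""

from __future__ import annotations

__all__ = [
    "PUBLISHED_N",
    "PUBLISHED_AGREEMENT",
    "PUBLISHED_CORRELATIONS",
    "PUBLISHED_SHRINKAGE",
]

PUBLISHED_N = 768

#: per-equation mean bias (predicted − measured), 95 % CI, and limits of
#: agreement as reported on the validation cohort, mg/day.
PUBLISHED_AGREEMENT = {
    "mycoss": {
        "mean_bias": -0.35, "ci_low": -72.26, "ci_high": 71.56,
        "loa_upper": 1986.89, "loa_lower": -1987.60,
    },
    "tanaka": {
        "mean_bias": 629.83, "ci_low": 532.19, "ci_high": 727.47,
        "loa_upper": 3327.99, "loa_lower": -2068.33,
    },
    "intersalt": {
        "mean_bias": 360.82, "ci_low": 284.34, "ci_high": 437.29,
        "loa_upper": 2473.99, "loa_lower": -1752.35,
    },
}

#: Pearson r of each predictor with measured 24-h sodium on the
#: validation cohort.
PUBLISHED_CORRELATIONS = {
    "spot_na": 0.219,
    "mycoss": 0.501,
    "tanaka": 0.232,
    "intersalt": 0.400,
}

#: double cross-validation shrinkage reported for the two subgroups.
PUBLISHED_SHRINKAGE = (-0.016, 0.017)
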