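"""Exact unit conversions for sodium and creatinine quantities.

Sodium moves between three reporting scales: mg/day (elemental sodium),
mmol/day (1 mmol Na = 23 mg), and g salt/day (1 mg Na = 2.54/1000 g NaCl).
Creatinine appears in four units across the literature this package bridges:
spot concentrations in mg/dL or mmol/L, daily excretion in g/day or mmol/day,
linked by the molar mass of creatinine, 113.12 g/mol.

Conversions are exact constant multiplications; silent unit coercion is
deliberately impossible — every estimator declares its unit contract and
callers convert explicitly through this module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SodiumAmount",
    "convert_sodium",
    "convert_creatinine",
    "NA_MG_PER_MMOL",
    "SALT_G_PER_NA_MG",
    "CREATININE_MOLAR_MASS",
    "SODIUM_UNITS",
]

#: mg of elemental sodium per mmol.
NA_MG_PER_MMOL = 23.0
#: g of NaCl per mg of elemental sodium (2.54 ÷ 1000).
SALT_G_PER_NA_MG = 2.54 / 1000.0
#: molar mass of creatinine, g/mol.
CREATININE_MOLAR_MASS = 113.12

SODIUM_UNITS = ("mg/day", "mmol/day", "g_salt/day")

# factor taking one unit of X to mg/day
_TO_MG = {
    "mg/day": 1.0,
    "mmol/day": NA_MG_PER_MMOL,
    "g_salt/day": 1.0 / SALT_G_PER_NA_MG,
}

_CREATININE_CONC = {"mg/dL": 1.0, "mmol/L": CREATININE_MOLAR_MASS / 10.0}
_CREATININE_DAILY = {"g/day": 1.0, "mmol/day": CREATININE_MOLAR_MASS / 1000.0}


@dataclass(frozen=True)
class SodiumAmount:
    """A sodium quantity tagged with its reporting unit.

    ``value`` may be a scalar or an ndarray (per-subject estimates).
    """

    value: float | np.ndarray
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in SODIUM_UNITS:
            raise ValueError(
                f"unknown sodium unit {self.unit!r}; expected one of {SODIUM_UNITS}"
            )

    def to(self, unit: str) -> "SodiumAmount":
        return convert_sodium(self, unit)


def convert_sodium(amount: SodiumAmount, to_unit: str) -> SodiumAmount:
    """Convert a :class:`SodiumAmount` to ``to_unit``.

    mmol/day → mg/day multiplies by 23; mg/day → g salt/day multiplies by
    2.54/1000. Round trips are exact to machine precision.
    """
    if to_unit not in _TO_MG:
        raise ValueError(f"unknown sodium unit {to_unit!r}; expected one of {SODIUM_UNITS}")
    if to_unit == amount.unit:
        return amount
    mg = np.asarray(amount.value, dtype=float) * _TO_MG[amount.unit]
    out = mg / _TO_MG[to_unit]
    if np.ndim(amount.value) == 0:
        out = float(out)
    return replace(amount, value=out, unit=to_unit)


def convert_creatinine(value, from_unit: str, to_unit: str):
    """Convert creatinine between mg/dL, mmol/L (concentrations) and
    g/day, mmol/day (daily excretion).

    mg/dL → mmol/L multiplies by 10/113.12; g/day → mmol/day by 1000/113.12.
    Concentration and daily-excretion units are dimensionally incompatible and
    conversion between the families raises.
    """
    if from_unit == to_unit:
        return value
    for family in (_CREATININE_CONC, _CREATININE_DAILY):
        if from_unit in family and to_unit in family:
            v = np.asarray(value, dtype=float) * (family[from_unit] / family[to_unit])
            return float(v) if np.ndim(value) == 0 else v
    known = sorted(_CREATININE_CONC) + sorted(_CREATININE_DAILY)
    if from_unit not in known or to_unit not in known:
        bad = from_unit if from_unit not in known else to_unit
        raise ValueError(f"unknown creatinine unit {bad!r}; expected one of {known}")
    raise ValueError(
        f"cannot convert creatinine {from_unit!r} → {to_unit!r}: "
        "concentration and daily excretion are dimensionally incompatible"
    )
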