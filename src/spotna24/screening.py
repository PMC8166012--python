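"""Eligibility and 24-h collection completeness screening.

Eligibility: adults (≥ 18 y) who are not pregnant, not fasting, have no
diagnosed kidney disease, and were able to collect 24-h urine. A complete
24-h collection requires (in the order evaluated): total volume ≥ 500 mL,
recorded timing ≥ 20 h, no missing void, and a sex-specific daily
creatinine rule (6 mmol/day men, 4 mmol/day women). Low daily creatinine
indicates an incomplete collection, so the default direction excludes
records *below* the threshold; the inverted literal reading is available
via ``cr_rule_direction="exclude_above"``. Spot urine is checked only for
presence and non-negativity — no appropriateness criteria are applied.

Every rule failure is reported (not just the first), with stable labels,
and screening is a pure function of its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .units import convert_creatinine

__all__ = [
    "CompletenessCriteria",
    "ScreeningResult",
    "check_eligibility",
    "assess_completeness",
    "screen_cohort",
    "write_screening_log",
]

_ELIGIBILITY_FIELDS = ["age_y", "pregnant", "fasting", "kidney_disease"]
_COMPLETENESS_FIELDS = ["vol24_ml", "dur_h", "missing_void", "cr24_g", "sex"]


@dataclass(frozen=True)
class CompletenessCriteria:
    min_volume: float = 500.0             # mL
    min_duration: float = 20.0            # h
    require_no_missing_void: bool = True
    cr_threshold_male: float = 6.0        # mmol/day
    cr_threshold_female: float = 4.0      # mmol/day
    cr_rule_direction: str = "exclude_below"

    def validate(self) -> None:
        for name in ("min_volume", "min_duration", "cr_threshold_male",
                     "cr_threshold_female"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.cr_rule_direction not in ("exclude_below", "exclude_above"):
            raise ValueError(
                "cr_rule_direction must be 'exclude_below' or 'exclude_above', "
                f"got {self.cr_rule_direction!r}"
            )


@dataclass
class ScreeningResult:
    """Partition of the input into kept records and labelled exclusions."""

    kept: pd.DataFrame
    #: (record id, ordered list of failed-rule labels)
    excluded: list[tuple[str, list[str]]]
    #: long-format detail: one row per (id, rule) with observed value and threshold
    log: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "rule", "observed", "threshold"]))


def _get(record, name):
    try:
        v = record[name] if not hasattr(record, name) else getattr(record, name)
    except (KeyError, AttributeError):
        raise ValueError(f"record is missing required field {name!r}") from None
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def check_eligibility(record) -> list[str]:
    """Return the ordered list of failed eligibility rules ([] = pass).

    Rules, in order: age_lt_18, pregnant, fasting, kidney_disease,
    no_24h_collection (24-h fields absent = unable to collect).
    """
    for name in _ELIGIBILITY_FIELDS:
        if _get(record, name) is None:
            raise ValueError(f"record is missing required field {name!r}")
    failures = []
    if float(_get(record, "age_y")) < 18.0:
        failures.append("age_lt_18")
    for flag in ("pregnant", "fasting", "kidney_disease"):
        if bool(_get(record, flag)):
            failures.append(flag)
    vol = _get(record, "vol24_ml")
    dur = _get(record, "dur_h")
    if vol is None or dur is None:
        failures.append("no_24h_collection")
    return failures


def _completeness_failures(record, criteria: CompletenessCriteria):
    """(label, observed, threshold) for each failed rule, printed order."""
    criteria.validate()
    vol = _get(record, "vol24_ml")
    dur = _get(record, "dur_h")
    if vol is None or dur is None:
        raise ValueError("record is missing 24-h volume or duration")
    vol, dur = float(vol), float(dur)
    if vol < 0 or dur < 0:
        raise ValueError(f"24-h volume/duration must be non-negative, got "
                         f"volume={vol}, duration={dur}")
    failures = []
    if vol < criteria.min_volume:
        failures.append((f"volume_lt_{criteria.min_volume:g}", vol, criteria.min_volume))
    if dur < criteria.min_duration:
        failures.append((f"duration_lt_{criteria.min_duration:g}", dur,
                         criteria.min_duration))
    if criteria.require_no_missing_void and bool(_get(record, "missing_void")):
        failures.append(("missing_void", 1.0, 0.0))
    cr_g = _get(record, "cr24_g")
    if cr_g is None:
        raise ValueError("record is missing required field 'cr24_g'")
    cr_mmol = convert_creatinine(float(cr_g), "g/day", "mmol/day")
    sex = str(_get(record, "sex")).upper()
    thr = criteria.cr_threshold_male if sex == "M" else criteria.cr_threshold_female
    if criteria.cr_rule_direction == "exclude_below":
        if cr_mmol < thr:
            failures.append((f"creatinine_lt_{thr:g}", cr_mmol, thr))
    else:
        if cr_mmol >= thr:
            failures.append((f"creatinine_ge_{thr:g}", cr_mmol, thr))
    return failures


def assess_completeness(record, criteria: CompletenessCriteria | None = None) -> list[str]:
    """Ordered failed completeness rules for one 24-h collection ([] = pass)."""
    criteria = criteria or CompletenessCriteria()
    return [label for label, _, _ in _completeness_failures(record, criteria)]


def _spot_failures(record):
    failures = []
    for col, label in (("spot_na_mg_l", "spot_na"), ("spot_k_mmol_l", "spot_k"),
                       ("spot_cr_mg_dl", "spot_cr")):
        v = _get(record, col)
        if v is None:
            failures.append((f"{label}_missing", float("nan"), 0.0))
        elif float(v) < 0:
            failures.append((f"{label}_negative", float(v), 0.0))
    return failures


def screen_cohort(records: pd.DataFrame,
                  criteria: CompletenessCriteria | None = None,
                  *, require_spot: bool = True) -> ScreeningResult:
    """Screen a cohort: eligibility, completeness, and (by default) spot
    availability. Kept records preserve input order; every input record
    lands in exactly one of kept/excluded. Per-record validation problems
    become exclusion labels rather than exceptions.
    """
    criteria = criteria or CompletenessCriteria()
    criteria.validate()
    keep_mask = []
    excluded: list[tuple[str, list[str]]] = []
    log_rows = []
    for rec in records.itertuples(index=False):
        rid = str(rec.id)
        try:
            fails = [(lab, float("nan"), float("nan"))
                     for lab in check_eligibility(rec)]
            if "no_24h_collection" not in [f[0] for f in fails]:
                fails += _completeness_failures(rec, criteria)
            if require_spot:
                fails += _spot_failures(rec)
        except ValueError as exc:
            fails = [(f"invalid_record:{exc}", float("nan"), float("nan"))]
        keep_mask.append(not fails)
        if fails:
            excluded.append((rid, [f[0] for f in fails]))
            log_rows.extend({"id": rid, "rule": lab, "observed": obs,
                             "threshold": thr} for lab, obs, thr in fails)
    kept = records.loc[keep_mask].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["id", "rule", "observed", "threshold"])
    return ScreeningResult(kept=kept, excluded=excluded, log=log)


def write_screening_log(result: ScreeningResult, path,
                        *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        result.log.to_csv(fh, index=False)
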