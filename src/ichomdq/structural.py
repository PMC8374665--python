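"""Structural data-quality checks: uniqueness, consistency, completeness.

All checks consume a parsed :class:`~ichomdq.table.VisitTable` and return a
:class:`~ichomdq.result.CheckResult` whose score is expressed in percent,
``100 * (1 - violations/assessed)``.  Uniqueness and rule checks are
record-level ratios; type/range consistency and completeness are scored per
variable and combined by unweighted mean over variables.  Every check is
invariant to row order.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dictionary import DataDictionary, ParseStatus, ValueKind
from .result import CheckResult, Finding, VariableScore, round_half_up
from .table import VisitTable

__all__ = [
    "uniqueness_result1",
    "uniqueness_result2",
    "consistency_by_type",
    "consistency_by_range",
    "consistency_by_rules",
    "consistency_overall",
    "completeness",
    "Rule",
    "DEFAULT_RULES",
]

VISIT_ID = "Visit ID"
PATIENT_ID = "Patient ID"
ARRIVAL = "Date of arrival"
DISCHARGE = "Date of discharge"
DEATH = "Date of death"

_OK = ParseStatus.OK.value
_MISSING = ParseStatus.MISSING.value
_FAIL = ParseStatus.TYPE_FAILURE.value


def _row_signatures(raw: pd.DataFrame, cols: Sequence[str]) -> pd.Series:
    """Exact per-row signature over ``cols`` (tuple of raw strings)."""
    return pd.Series(list(map(tuple, raw[cols].to_numpy())), index=raw.index)


# ---------------------------------------------------------------------------
# uniqueness
# ---------------------------------------------------------------------------

def uniqueness_result1(table: VisitTable) -> CheckResult:
    """Partial duplicates sharing a visit identifier.

    A record counts against uniqueness when its visit ID is shared with at
    least one other record that *differs* in one or more of the other
    fields.  Records that share a visit ID but agree on every field are
    exact full duplicates: they are excluded from this result and reported
    separately as an informational finding (``extra['exact_duplicate_rows']``).
    """
    raw = table.raw
    n = len(raw)
    other_cols = [c for c in raw.columns if c != VISIT_ID]
    findings: list[Finding] = []
    numerator = 0
    exact_dup_rows = 0

    sizes = raw.groupby(VISIT_ID, sort=False)[VISIT_ID].transform("size")
    dup_mask = sizes > 1
    if dup_mask.any():
        dups = raw.loc[dup_mask]
        sigs = _row_signatures(dups, other_cols)
        for vid, idx in dups.groupby(VISIT_ID, sort=False).groups.items():
            group_sigs = sigs.loc[idx]
            if group_sigs.nunique() > 1:
                numerator += len(idx)
                for i in idx:
                    findings.append(
                        Finding(int(i), "uniqueness_1", VISIT_ID,
                                f"visit ID {vid!r} shared with differing record(s)")
                    )
            # rows whose full content repeats within the group
            counts = group_sigs.value_counts()
            repeated = counts[counts > 1].sum()
            exact_dup_rows += int(repeated)

    res = CheckResult("uniqueness_1", numerator, n, findings=findings)
    res.extra["exact_duplicate_rows"] = exact_dup_rows
    return res


def uniqueness_result2(table: VisitTable) -> CheckResult:
    """Same-day clones under different visit identifiers.

    A record counts when at least one other record carries the same patient
    ID and arrival date, identical values on all fields other than the
    visit ID, and a *different* visit ID.  (Same patient and day are implied
    by identical clinical data, since those fields are part of the record.)
    """
    raw = table.raw
    n = len(raw)
    other_cols = [c for c in raw.columns if c != VISIT_ID]
    findings: list[Finding] = []
    numerator = 0

    # cheap 64-bit prefilter, then exact tuple confirmation within candidates
    hashes = pd.util.hash_pandas_object(raw[other_cols], index=False)
    sizes = hashes.groupby(hashes).transform("size")
    cand = raw.loc[sizes > 1]
    if len(cand):
        sigs = _row_signatures(cand, other_cols)
        for sig, idx in sigs.groupby(sigs, sort=False).groups.items():
            if len(idx) < 2:
                continue
            vids = raw.loc[idx, VISIT_ID]
            if vids.nunique() > 1:
                # every member has a same-day identical record under another ID
                counted = [i for i in idx if (vids != vids.loc[i]).any()]
                numerator += len(counted)
                for i in counted:
                    findings.append(
                        Finding(int(i), "uniqueness_2", None,
                                "identical clinical data recorded the same day "
                                "under a different visit ID")
                    )
    return CheckResult("uniqueness_2", numerator, n, findings=findings)


# ---------------------------------------------------------------------------
# consistency
# ---------------------------------------------------------------------------

def consistency_by_type(table: VisitTable) -> CheckResult:
    """Compliance of non-missing fields with their declared type.

    Per variable: share of non-missing fields whose text does not parse as
    the declared kind.  Variables with no assessable field score 100 and
    are flagged vacuous.  The check score is the unweighted mean over
    variables.
    """
    status = table.status
    per_var: list[VariableScore] = []
    findings: list[Finding] = []
    warnings: list[str] = []
    for spec in table.dictionary:
        st = status[spec.name]
        assessable = int((st != _MISSING).sum())
        failures = np.flatnonzero((st == _FAIL).to_numpy())
        vac = assessable == 0
        if vac:
            warnings.append(f"{spec.name}: no assessable fields (all missing)")
        per_var.append(VariableScore(spec.name, len(failures), assessable, vacuous=vac))
        for i in failures:
            findings.append(
                Finding(int(i), "consistency_type", spec.name,
                        f"value {table.raw.at[i, spec.name]!r} is not a valid "
                        f"{spec.kind.value}")
            )
    num = sum(v.numerator for v in per_var)
    den = sum(v.denominator for v in per_var)
    return CheckResult(
        "consistency_type", num, den, per_variable=per_var,
        findings=findings, aggregation="variable_mean", warnings=warnings,
    )


def consistency_by_range(
    table: VisitTable,
    *,
    date_windows: Optional[Mapping[str, tuple[_dt.date, _dt.date]]] = None,
) -> CheckResult:
    """Compliance of well-typed fields with ranges, domains and date windows.

    Violations are numeric values outside the variable's plausibility range
    (zero-coded heights/weights fall here by design), categorical codes
    outside the allowed response options, negative counts, and dates outside
    the applicable window.  By default only the arrival date is checked
    against the table's extraction window.  Unknown-coded (999) responses
    are legal and never violations.  Scored per variable, mean over
    variables.
    """
    if date_windows is None:
        ws, we = table.window()
        date_windows = {ARRIVAL: (ws, we)} if ws or we else {}

    per_var: list[VariableScore] = []
    findings: list[Finding] = []
    warnings: list[str] = []
    for spec in table.dictionary:
        st = table.status[spec.name]
        ok = (st == _OK).to_numpy()
        unk = table.unknown[spec.name].to_numpy()
        assessable = int(ok.sum())
        viol = np.zeros(len(table), dtype=bool)
        checkable = ok & ~unk
        typed = table.typed(spec.name)
        if spec.kind is ValueKind.NUMERIC and spec.numeric_range is not None:
            lo, hi = spec.numeric_range
            vals = typed.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                viol = checkable & ((vals < lo) | (vals > hi))
        elif spec.kind is ValueKind.CATEGORICAL and spec.allowed_codes:
            vals = typed.to_numpy(dtype=float)
            allowed = np.array(sorted(spec.allowed_codes), dtype=float)
            viol = checkable & ~np.isin(vals, allowed)
        elif spec.kind is ValueKind.COUNT:
            vals = typed.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                viol = checkable & (vals < 0)
        elif spec.kind is ValueKind.DATE and spec.name in date_windows:
            ws, we = date_windows[spec.name]
            dates = typed
            if ws is not None:
                viol |= (checkable & (dates < pd.Timestamp(ws)).to_numpy())
            if we is not None:
                viol |= (checkable & (dates > pd.Timestamp(we)).to_numpy())
        vac = assessable == 0
        if vac:
            warnings.append(f"{spec.name}: no assessable fields")
        nviol = int(viol.sum())
        per_var.append(VariableScore(spec.name, nviol, assessable, vacuous=vac))
        for i in np.flatnonzero(viol):
            findings.append(
                Finding(int(i), "consistency_range", spec.name,
                        f"value {table.raw.at[i, spec.name]!r} out of range/domain")
            )
    num = sum(v.numerator for v in per_var)
    den = sum(v.denominator for v in per_var)
    return CheckResult(
        "consistency_range", num, den, per_variable=per_var,
        findings=findings, aggregation="variable_mean", warnings=warnings,
    )


@dataclass(frozen=True)
class Rule:
    """A declarative two-field comparison rule, e.g. arrival <= discharge."""

    field_a: str
    comparator: str  # le | lt | ge | gt | eq
    field_b: str

    def label(self) -> str:
        return f"{self.field_a} {self.comparator} {self.field_b}"


DEFAULT_RULES: tuple[Rule, ...] = (
    Rule(ARRIVAL, "le", DISCHARGE),
    Rule(DISCHARGE, "le", DEATH),
)

_COMPARATORS = {
    "le": np.less_equal,
    "lt": np.less,
    "ge": np.greater_equal,
    "gt": np.greater,
    "eq": np.equal,
}


def consistency_by_rules(
    table: VisitTable, rules: Sequence[Rule] = DEFAULT_RULES
) -> CheckResult:
    """Compliance with basic multivariate rules between fields.

    A rule is evaluable on a record only when both referenced fields carry
    well-typed values (missing, unknown-coded or malformed fields make the
    rule non-evaluable there).  The denominator counts records where at
    least one rule is evaluable; the numerator counts records violating at
    least one evaluable rule.
    """
    n = len(table)
    evaluable_any = np.zeros(n, dtype=bool)
    violated_any = np.zeros(n, dtype=bool)
    per_rule: dict[str, dict] = {}
    findings: list[Finding] = []
    for rule in rules:
        if rule.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {rule.comparator!r}")
        a = table.typed(rule.field_a)
        b = table.typed(rule.field_b)
        ev = (a.notna() & b.notna()).to_numpy()
        comp = _COMPARATORS[rule.comparator]
        with np.errstate(invalid="ignore"):
            holds = comp(a.to_numpy(), b.to_numpy())
        viol = ev & ~holds
        evaluable_any |= ev
        violated_any |= viol
        per_rule[rule.label()] = {
            "evaluable": int(ev.sum()),
            "violations": int(viol.sum()),
        }
        for i in np.flatnonzero(viol):
            findings.append(
                Finding(int(i), "consistency_rules", rule.field_a,
                        f"rule violated: {rule.label()}")
            )
    res = CheckResult(
        "consistency_rules", int(violated_any.sum()), int(evaluable_any.sum()),
        findings=findings,
    )
    res.extra["per_rule"] = per_rule
    if not evaluable_any.any():
        res.warnings.append("no record had an evaluable rule")
    return res


def consistency_overall(
    by_type: CheckResult, by_range: CheckResult, by_rules: CheckResult
) -> float:
    """Unweighted mean of the three consistency component scores (2 dp)."""
    return round_half_up((by_type.score + by_range.score + by_rules.score) / 3.0)


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------

def completeness(table: VisitTable) -> CheckResult:
    """Proportion of complete (non-empty) fields per variable.

    The unknown response 999 is a recorded value and counts as complete;
    per-variable unknown rates are reported separately and never lower the
    score.  A variable with a valid-incompleteness rule (date of death,
    which exists only when the patient died during the visit) is scored on
    the records where the rule says the field should exist; its raw
    unconditional completeness is reported in ``extra`` alongside.  Overall
    score is the unweighted mean over variables.
    """
    n = len(table)
    status = table.status
    per_var: list[VariableScore] = []
    warnings: list[str] = []
    unknown_rates: dict[str, float] = {}
    unconditional: dict[str, float] = {}

    death_subset = _died_during_visit(table)

    for spec in table.dictionary:
        st = status[spec.name]
        present = (st != _MISSING).to_numpy()
        if spec.valid_incompleteness is not None:
            should = death_subset
            den = int(should.sum())
            num = int((should & ~present).sum())
            vac = den == 0
            if vac:
                warnings.append(
                    f"{spec.name}: no record satisfies the valid-incompleteness "
                    "condition; conditional completeness is vacuous"
                )
            per_var.append(VariableScore(spec.name, num, den, vacuous=vac))
            unconditional[spec.name] = (
                round_half_up(100.0 * present.mean()) if n else 100.0
            )
        else:
            per_var.append(VariableScore(spec.name, int((~present).sum()), n))
        if spec.unknown_code is not None:
            npresent = int(present.sum())
            nunk = int(table.unknown[spec.name].sum())
            unknown_rates[spec.name] = (
                round_half_up(100.0 * nunk / npresent) if npresent else 0.0
            )

    num = sum(v.numerator for v in per_var)
    den = sum(v.denominator for v in per_var)
    res = CheckResult(
        "completeness", num, den, per_variable=per_var,
        aggregation="variable_mean", warnings=warnings,
    )
    res.extra["unknown_rate"] = unknown_rates
    res.extra["unconditional_completeness"] = unconditional
    return res


def _died_during_visit(table: VisitTable) -> np.ndarray:
    """Records where the patient verifiably died during the visit.

    Identified from the data alone: a well-formed date of death lying
    within the visit's [arrival, discharge] interval.
    """
    death = table.typed(DEATH)
    arrival = table.typed(ARRIVAL)
    discharge = table.typed(DISCHARGE)
    mask = death.notna() & arrival.notna() & discharge.notna()
    within = (death >= arrival) & (death <= discharge)
    return (mask & within).to_numpy()
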