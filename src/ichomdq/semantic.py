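"""Temporal-stability profiling and correctness checks.

Stability is assessed qualitatively via monthly relative frequencies of
binary indicators (share of visit records that month carrying a 1), with a
low-support flag for thin months; an optional change-point convenience
locates abrupt documentation shifts.  Correctness checks probe BMI
plausibility, height/weight value inversion and the temporal order of
past-medical-condition flags (once a history is recorded for a patient it
must be recorded in all subsequent visits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .result import CheckResult, Finding, round_half_up
from .structural import ARRIVAL, PATIENT_ID, VISIT_ID
from .table import VisitTable

__all__ = [
    "MonthlySeries",
    "monthly_frequency",
    "detect_shift",
    "bmi",
    "bmi_plausibility",
    "inversion_candidates",
    "history_order_violations",
    "correctness_overall",
    "HISTORY_CONDITIONS",
    "DEFAULT_BMI_BOUNDS",
    "DEFAULT_MONTH_SUPPORT",
]

HEIGHT = "Height"
WEIGHT = "Weight"

#: The four past-medical-condition flags probed by the temporal-order check.
HISTORY_CONDITIONS: tuple[str, ...] = (
    "Atrial fibrillation",
    "Hypertension",
    "Diabetes mellitus",
    "Prior myocardial infarction",
)

DEFAULT_BMI_BOUNDS = (10.0, 70.0)  # kg/m^2, suspicious below / implausible above
DEFAULT_MONTH_SUPPORT = 10  # months with fewer records are flagged low-support


# ---------------------------------------------------------------------------
# temporal stability
# ---------------------------------------------------------------------------

@dataclass
class MonthlySeries:
    """Per-month relative frequency of a binary indicator.

    ``frequency`` is numerator/denominator, NaN (undefined, not zero) for
    empty months; months with fewer than ``support_threshold`` records are
    flagged low-support.
    """

    variable: str
    months: list[pd.Period]
    numerator: np.ndarray
    denominator: np.ndarray
    support_threshold: int = DEFAULT_MONTH_SUPPORT

    def __post_init__(self) -> None:
        self.numerator = np.asarray(self.numerator, dtype=int)
        self.denominator = np.asarray(self.denominator, dtype=int)
        if np.any(self.numerator > self.denominator):
            raise ValueError("numerator exceeds denominator")
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError("months must be strictly increasing")

    @property
    def frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(self.denominator > 0,
                         self.numerator / np.maximum(self.denominator, 1),
                         np.nan)
        return f

    @property
    def low_support(self) -> np.ndarray:
        return self.denominator < self.support_threshold

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": [str(m) for m in self.months],
                "numerator": self.numerator,
                "denominator": self.denominator,
                "frequency": self.frequency,
                "low_support": self.low_support,
            }
        )


def monthly_frequency(
    table: VisitTable,
    variable: str,
    support_threshold: int = DEFAULT_MONTH_SUPPORT,
) -> MonthlySeries:
    """Monthly relative frequency of a 0/1/999 indicator.

    Records are binned by the calendar month of their arrival date; the
    numerator counts value 1, the denominator all records that month (0 and
    999 contribute to the denominator only).  Records with unparseable or
    missing arrival dates are excluded.  Every calendar month between the
    first and last observed month (or the table's extraction window, when
    present) appears, empty months with undefined frequency.
    """
    arrival = table.typed(ARRIVAL)
    vals = table.typed(variable)
    okdate = arrival.notna()
    months = arrival[okdate].dt.to_period("M")
    ones = ((vals == 1) & okdate)[okdate]

    den = months.value_counts().sort_index()
    num = months[ones.to_numpy()].value_counts().sort_index()

    ws, we = table.window()
    if len(den):
        start, end = den.index.min(), den.index.max()
    elif ws is not None and we is not None:
        start, end = pd.Period(ws, "M"), pd.Period(we, "M")
    else:
        return MonthlySeries(variable, [], np.array([]), np.array([]),
                             support_threshold)
    if ws is not None:
        start = min(start, pd.Period(ws, "M"))
    if we is not None:
        end = max(end, pd.Period(we, "M"))
    idx = pd.period_range(start, end, freq="M")
    den = den.reindex(idx, fill_value=0)
    num = num.reindex(idx, fill_value=0)
    return MonthlySeries(variable, list(idx), num.to_numpy(), den.to_numpy(),
                         support_threshold)


def detect_shift(
    series: MonthlySeries,
    window: int = 12,
    min_relative_change: float = 0.5,
    min_months: int = 3,
) -> Optional[tuple[pd.Period, float, float]]:
    """Locate an abrupt change in a monthly frequency series.

    For each candidate month ``m``, compares the mean frequency over the
    supported months in the trailing window ``[m - window, m)`` against the
    leading window ``[m, m + window)``; returns ``(m, before, after)`` for
    the month with the largest absolute gap, provided the gap exceeds
    ``min_relative_change`` of the before-mean.  Low-support and empty
    months are excluded from the means; a window contributing fewer than
    ``min_months`` supported months disqualifies the candidate.  Returns
    None when no candidate qualifies.  This detector is a convenience
    extension: the underlying assessment of stability is qualitative.
    """
    freq = series.frequency
    usable = ~series.low_support & ~np.isnan(freq)
    n = len(freq)
    best: Optional[tuple[pd.Period, float, float]] = None
    best_gap = -1.0
    for i in range(1, n):
        lo, hi = max(0, i - window), min(n, i + window)
        before_idx = np.arange(lo, i)[usable[lo:i]]
        after_idx = np.arange(i, hi)[usable[i:hi]]
        if len(before_idx) < min_months or len(after_idx) < min_months:
            continue
        before = float(freq[before_idx].mean())
        after = float(freq[after_idx].mean())
        gap = abs(after - before)
        if gap > best_gap:
            best_gap = gap
            best = (series.months[i], before, after)
    if best is None:
        return None
    _, before, after = best
    denom = max(abs(before), 1e-12)
    if best_gap / denom < min_relative_change:
        return None
    return best


# ---------------------------------------------------------------------------
# correctness
# ---------------------------------------------------------------------------

def bmi(height_cm: float, weight_kg: float) -> float:
    """Body-mass index in kg/m^2 from height in cm and weight in kg.

    Both arguments must be strictly positive: zero-coded measurements are
    missing values, not measurements, and are excluded upstream.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be strictly positive")
    return weight_kg / (height_cm / 100.0) ** 2


def _bmi_series(table: VisitTable) -> tuple[pd.Series, np.ndarray]:
    h = table.typed(HEIGHT)
    w = table.typed(WEIGHT)
    computable = (h.notna() & w.notna() & (h > 0) & (w > 0)).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        b = w / (h / 100.0) ** 2
    return b.where(pd.Series(computable, index=b.index)), computable


def bmi_plausibility(
    table: VisitTable,
    low: float = DEFAULT_BMI_BOUNDS[0],
    high: float = DEFAULT_BMI_BOUNDS[1],
) -> CheckResult:
    """Count records whose BMI is suspiciously low (<low) or implausibly high (>high).

    The denominator is *all* records; records without a computable BMI
    (zero-coded or missing height/weight) are skipped and tallied in
    ``extra['not_computable']``.  Bounds are strict inequalities.
    """
    b, computable = _bmi_series(table)
    vals = b.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        low_mask = computable & (vals < low)
        high_mask = computable & (vals > high)
    findings = [
        Finding(int(i), "bmi_plausibility", HEIGHT,
                f"BMI {vals[i]:.1f} below {low}")
        for i in np.flatnonzero(low_mask)
    ] + [
        Finding(int(i), "bmi_plausibility", WEIGHT,
                f"BMI {vals[i]:.1f} above {high}")
        for i in np.flatnonzero(high_mask)
    ]
    res = CheckResult(
        "bmi_plausibility",
        int(low_mask.sum() + high_mask.sum()),
        len(table),
        findings=findings,
    )
    res.extra.update(
        n_low=int(low_mask.sum()),
        n_high=int(high_mask.sum()),
        not_computable=int((~computable).sum()),
        bounds=[low, high],
    )
    return res


def inversion_candidates(
    table: VisitTable,
    low: float = DEFAULT_BMI_BOUNDS[0],
    high: float = DEFAULT_BMI_BOUNDS[1],
) -> list[Finding]:
    """Records whose weight (kg) exceeds their height (cm).

    Such points fall below the main diagonal of the height/weight scatter
    and are very unlikely to be true.  A candidate whose *swapped* values
    give a BMI inside [low, high] is additionally labelled swap-plausible:
    it is consistent with a value inversion between the two fields.
    """
    h = table.typed(HEIGHT)
    w = table.typed(WEIGHT)
    cand = (h.notna() & w.notna() & (h > 0) & (w > 0) & (w > h)).to_numpy()
    findings = []
    for i in np.flatnonzero(cand):
        hh, ww = float(h.iloc[i]), float(w.iloc[i])
        swapped = bmi(ww, hh)  # treat recorded weight as height and vice versa
        plausible = low <= swapped <= high
        label = "swap-plausible" if plausible else "swap-implausible"
        findings.append(
            Finding(int(i), "hw_inversion", None,
                    f"weight {ww:g} kg exceeds height {hh:g} cm; swapped BMI "
                    f"{swapped:.1f} ({label})")
        )
    return findings


def history_order_violations(
    table: VisitTable,
    conditions: Sequence[str] = HISTORY_CONDITIONS,
) -> dict[str, CheckResult]:
    """Temporal-order check for past-medical-condition flags.

    Once any visit record of a patient carries flag 1 for a condition,
    every subsequent record (ordered by arrival date, ties by visit ID)
    reporting 0 for that condition is a violation — a history cannot be
    un-diagnosed.  The unknown response 999 neither violates nor resets
    the state.  Rates are expressed against *all* records of the table,
    one result per condition.
    """
    n = len(table)
    arrival = table.typed(ARRIVAL)
    order = pd.DataFrame(
        {
            "patient": table.raw[PATIENT_ID],
            "arrival": arrival,
            "vid": table.raw[VISIT_ID],
        }
    )
    orderable = order["arrival"].notna()
    sdf = (
        order[orderable]
        .sort_values(["patient", "arrival", "vid"], kind="mergesort")
    )
    ordered_idx = sdf.index
    grp = sdf["patient"].to_numpy()
    results: dict[str, CheckResult] = {}
    for cond in conditions:
        v = table.typed(cond).to_numpy(dtype=float)[ordered_idx]
        is_one = pd.Series((v == 1).astype(int))
        # history recorded strictly before this visit, within the patient
        seen_before = is_one.groupby(grp).shift(fill_value=0).groupby(grp).cummax()
        viol_mask = (v == 0) & (seen_before.to_numpy() == 1)
        violations = [int(i) for i in ordered_idx[viol_mask]]
        findings = [
            Finding(i, "history_order", cond,
                    "flag 0 after an earlier record of history 1")
            for i in violations
        ]
        results[cond] = CheckResult(
            f"history_order[{cond}]", len(violations), n, findings=findings
        )
    return results


def correctness_overall(
    bmi_result: CheckResult, order_results: dict[str, CheckResult]
) -> float:
    """Aggregate correctness score: unweighted mean over component checks.

    Components are the BMI-plausibility score and one temporal-order score
    per condition.  The aggregation rule is a convention of this package;
    alternative weightings can be applied to the retained component scores.
    """
    scores = [bmi_result.score] + [r.score for r in order_results.values()]
    return round_half_up(sum(scores) / len(scores))
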