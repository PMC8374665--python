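"""Dimension-level aggregation and machine/human-readable quality reports.

A :class:`QualityReport` carries one score per assessed dimension
(uniqueness, consistency, completeness, correctness) with its component
breakdown, plus the bundle of monthly stability series.  Stability
contributes series and optional shift findings but never a scalar score,
and the report deliberately has no single composite quality number: the
dimensions are reported side by side.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .result import CheckResult, Finding, round_half_up
from .semantic import (
    DEFAULT_BMI_BOUNDS,
    DEFAULT_MONTH_SUPPORT,
    HISTORY_CONDITIONS,
    MonthlySeries,
    bmi_plausibility,
    detect_shift,
    history_order_violations,
    inversion_candidates,
    monthly_frequency,
)
from .structural import (
    completeness,
    consistency_by_range,
    consistency_by_rules,
    consistency_by_type,
    consistency_overall,
    uniqueness_result1,
    uniqueness_result2,
)
from .table import VisitTable

__all__ = ["QualityReport", "aggregate_dimension", "run_assessment",
           "findings_to_csv", "ALL_CHECKS"]

ALL_CHECKS = ("uniqueness", "consistency", "completeness", "correctness",
              "stability")

#: indicators profiled for temporal stability by default: the four past
#: medical conditions and the four medication classes
DEFAULT_STABILITY_VARIABLES = (
    "Atrial fibrillation", "Hypertension", "Diabetes mellitus",
    "Prior myocardial infarction",
    "Beta blocker", "Calcium channel blocker", "Digoxin", "Diuretics",
)


def aggregate_dimension(component_scores: Sequence[float]) -> float:
    """Unweighted mean of component scores, rounded half-up to 2 decimals."""
    if not component_scores:
        raise ValueError("a dimension needs at least one component score")
    return round_half_up(sum(component_scores) / len(component_scores))


@dataclass
class QualityReport:
    """Assembled outcome of one assessment run."""

    dimensions: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)
    findings: list[Finding] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    tool_version: str = __version__

    def to_dict(self) -> dict:
        return {
            "tool": {"name": "ichomdq", "version": self.tool_version},
            "provenance": self.provenance,
            "dimensions": self.dimensions,
            "stability": self.stability,
            "findings_total": len(self.findings),
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True,
                          allow_nan=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @staticmethod
    def read_json(path: str | Path) -> dict:
        return json.loads(Path(path).read_text(encoding="utf-8"))

    def summary(self) -> str:
        """Short human-readable rendering of the dimension scores."""
        lines = []
        for dim in ("uniqueness", "consistency", "completeness", "correctness"):
            d = self.dimensions.get(dim)
            if not d or not d.get("computed", False):
                lines.append(f"{dim:>13}: not computed")
                continue
            lines.append(f"{dim:>13}: {_fmt_score(d['score'])}%")
            for cid, comp in d.get("components", {}).items():
                lines.append(f"{'':>15}- {cid}: {_fmt_score(comp['score'])}%"
                             f" ({comp['numerator']}/{comp['denominator']})")
        st = self.stability
        if st.get("computed", False):
            n = len(st.get("series", {}))
            lines.append(f"{'stability':>13}: {n} monthly series (qualitative)")
        else:
            lines.append(f"{'stability':>13}: not computed")
        return "\n".join(lines)


def _fmt_score(x: float) -> str:
    """Render 98.0 as '98' and 97.07 as '97.07' (trailing zeros dropped)."""
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s or "0"


def run_assessment(
    table: VisitTable,
    checks: Sequence[str] = ALL_CHECKS,
    *,
    min_month_support: int = DEFAULT_MONTH_SUPPORT,
    bmi_bounds: tuple[float, float] = DEFAULT_BMI_BOUNDS,
    stability_variables: Sequence[str] = DEFAULT_STABILITY_VARIABLES,
    with_shift_detection: bool = False,
) -> QualityReport:
    """Execute the selected quality checks on one table and assemble a report.

    Unselected dimensions are marked not-computed in the report rather than
    omitted.  Shift detection on the stability series is off by default:
    the stability assessment itself is qualitative.
    """
    report = QualityReport()
    report.provenance = {
        "source": table.provenance.source,
        "window_start": _iso(table.provenance.window_start),
        "window_end": _iso(table.provenance.window_end),
        "n_records": len(table),
        "dictionary_version": table.dictionary.version,
    }
    dims = report.dimensions
    for dim in ("uniqueness", "consistency", "completeness", "correctness"):
        dims[dim] = {"computed": False}
    report.stability = {"computed": False}

    if "uniqueness" in checks:
        u1, u2 = uniqueness_result1(table), uniqueness_result2(table)
        dims["uniqueness"] = _dimension([u1, u2])
        report.findings += u1.findings + u2.findings

    if "consistency" in checks:
        ct = consistency_by_type(table)
        cr = consistency_by_range(table)
        cl = consistency_by_rules(table)
        dims["consistency"] = _dimension([ct, cr, cl])
        assert dims["consistency"]["score"] == consistency_overall(ct, cr, cl)
        report.findings += ct.findings + cr.findings + cl.findings

    if "completeness" in checks:
        co = completeness(table)
        dims["completeness"] = _dimension([co])
        report.findings += co.findings

    if "correctness" in checks:
        bp = bmi_plausibility(table, *bmi_bounds)
        orders = history_order_violations(table)
        inv = inversion_candidates(table, *bmi_bounds)
        dims["correctness"] = _dimension([bp, *orders.values()])
        dims["correctness"]["n_inversion_candidates"] = len(inv)
        dims["correctness"]["n_swap_plausible"] = sum(
            1 for f in inv if "swap-plausible" in f.detail
        )
        report.findings += bp.findings + inv
        for r in orders.values():
            report.findings += r.findings

    if "stability" in checks:
        series = {}
        shifts = {}
        for var in stability_variables:
            s = monthly_frequency(table, var, min_month_support)
            series[var] = json.loads(
                s.as_frame().to_json(orient="records")
            )
            if with_shift_detection:
                hit = detect_shift(s)
                if hit is not None:
                    month, before, after = hit
                    shifts[var] = {
                        "month": str(month),
                        "before_mean": round(before, 4),
                        "after_mean": round(after, 4),
                    }
        report.stability = {"computed": True, "series": series}
        if with_shift_detection:
            report.stability["shifts"] = shifts

    return report


def _dimension(components: list[CheckResult]) -> dict:
    return {
        "computed": True,
        "score": aggregate_dimension([c.score for c in components]),
        "components": {c.check_id: c.to_dict() for c in components},
    }


def _iso(d: Optional[_dt.date]) -> Optional[str]:
    return d.isoformat() if d is not None else None


def findings_to_csv(findings: Sequence[Finding], path: str | Path) -> Path:
    """Export record-level findings as CSV (record index, variable, check, detail)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "record_index": [f.record_index for f in findings],
            "variable": [f.variable or "" for f in findings],
            "check_id": [f.check_id for f in findings],
            "detail": [f.detail for f in findings],
        }
    )
    df.to_csv(path, index=False)
    return path
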