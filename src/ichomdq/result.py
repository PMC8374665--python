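"""Check-result containers shared by all quality dimensions."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

__all__ = ["Finding", "VariableScore", "CheckResult", "round_half_up"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (97.075 -> 97.08)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Finding:
    """One record-level observation produced by a check."""

    record_index: int
    check_id: str
    variable: Optional[str] = None
    detail: str = ""


@dataclass
class VariableScore:
    """Per-variable numerator/denominator for a field-level check."""

    variable: str
    numerator: int  # violating / incomplete fields
    denominator: int  # assessable fields
    vacuous: bool = False  # no assessable fields: scored 100 with a warning

    @property
    def fraction(self) -> float:
        if self.denominator == 0:
            return 0.0
        return self.numerator / self.denominator

    @property
    def score(self) -> float:
        return round_half_up(100.0 * (1.0 - self.fraction))


@dataclass
class CheckResult:
    """Outcome of one quality check.

    ``score`` is ``100 * (1 - numerator/denominator)`` for ratio checks and
    the unweighted mean of per-variable scores for field-level checks, both
    rounded half-up to 2 decimals; the raw fraction is retained via the
    stored numerator/denominator and per-variable breakdown.
    """

    check_id: str
    numerator: int
    denominator: int
    per_variable: list[VariableScore] = field(default_factory=list)
    findings: list[Finding] = field(default_factory=list)
    aggregation: str = "ratio"  # "ratio" | "variable_mean"
    warnings: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= max(self.denominator, 0):
            raise ValueError(
                f"{self.check_id}: numerator {self.numerator} outside "
                f"[0, {self.denominator}]"
            )

    @property
    def fraction(self) -> float:
        if self.denominator == 0:
            return 0.0
        return self.numerator / self.denominator

    @property
    def score(self) -> float:
        if self.aggregation == "variable_mean":
            if not self.per_variable:
                return 100.0
            return round_half_up(
                sum(v.score for v in self.per_variable) / len(self.per_variable)
            )
        return round_half_up(100.0 * (1.0 - self.fraction))

    def variable_score(self, name: str) -> VariableScore:
        for v in self.per_variable:
            if v.variable == name:
                return v
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "check_id": self.check_id,
            "numerator": int(self.numerator),
            "denominator": int(self.denominator),
            "score": self.score,
            "aggregation": self.aggregation,
            "per_variable": [
                {
                    "variable": v.variable,
                    "numerator": int(v.numerator),
                    "denominator": int(v.denominator),
                    "score": v.score,
                    "vacuous": v.vacuous,
                }
                for v in self.per_variable
            ],
            "n_findings": len(self.findings),
            "warnings": list(self.warnings),
            "extra": self.extra,
        }
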