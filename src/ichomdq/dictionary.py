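"""Machine-readable ICHOM heart-failure data dictionary and value parsing.

The dictionary describes the 21-item ICHOM heart-failure subset used for
visit-level data-quality assessment, plus a visit identifier, organised in
six areas (identifiers, demographic factors, baseline health status,
treatment, burden of care, mortality).  Categorical items use the ICHOM
response coding ``0=No, 1=Yes, 999=Unknown``; dates use the DD/MM/YYYY
dialect (ISO 8601 is also accepted on input).
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "Area",
    "ValueKind",
    "ParseStatus",
    "ParsedValue",
    "VariableSpec",
    "DataDictionary",
    "CodeList",
    "default_dictionary",
    "parse_value",
    "hf_icd9_codes",
    "HEART_FAILURE_ICD9",
]


class Area(str, Enum):
    """The six variable areas of the ICHOM heart-failure subset."""

    IDENTIFIERS = "identifiers"
    DEMOGRAPHIC = "demographic"
    BASELINE_HEALTH = "baseline_health"
    TREATMENT = "treatment"
    BURDEN_OF_CARE = "burden_of_care"
    MORTALITY = "mortality"


class ValueKind(str, Enum):
    IDENTIFIER = "identifier"
    DATE = "date"
    NUMERIC = "numeric"
    CATEGORICAL = "categorical"
    COUNT = "count"


class ParseStatus(str, Enum):
    OK = "ok"
    MISSING = "missing"
    TYPE_FAILURE = "type_failure"


@dataclass(frozen=True)
class ParsedValue:
    """Outcome of parsing one raw field: a status and, when ok, a typed value.

    ``value`` is ``datetime.date`` for dates, ``float`` for numerics,
    ``int`` for categorical/count codes, ``str`` for identifiers and
    ``None`` otherwise.  A raw ``999`` on a variable whose unknown code is
    999 parses ok with ``is_unknown`` set, whatever the variable kind.
    """

    status: ParseStatus
    value: object = None
    is_unknown: bool = False


#: Accepted date layouts: the ICHOM DD/MM/YYYY dialect and ISO 8601.
_DATE_DDMMYYYY = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_DATE_ISO = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_INT = re.compile(r"^[+-]?\d+$")


@dataclass(frozen=True)
class VariableSpec:
    """Schema of one ICHOM variable: its kind, domain and format.

    ``allowed_codes`` constrains categorical variables; ``numeric_range``
    is an inclusive plausibility interval (values outside it — including
    the zero-coded missing heights/weights — are *range* violations, not
    type failures).  ``valid_incompleteness`` names a rule under which the
    field is legitimately absent (used only by date of death: the field
    exists only when the patient died during the visit).
    """

    name: str
    area: Area
    kind: ValueKind
    allowed_codes: frozenset[int] = frozenset()
    numeric_range: Optional[Tuple[float, float]] = None
    units: Optional[str] = None
    date_format: str = "DD/MM/YYYY"
    unknown_code: Optional[int] = None
    valid_incompleteness: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variable name must be non-empty")
        if self.numeric_range is not None:
            lo, hi = self.numeric_range
            if not lo < hi:
                raise ValueError(
                    f"{self.name}: numeric_range min must be < max, got {self.numeric_range}"
                )
        if self.unknown_code is not None and self.kind is ValueKind.CATEGORICAL:
            if self.unknown_code not in self.allowed_codes:
                raise ValueError(
                    f"{self.name}: unknown_code {self.unknown_code} not in allowed_codes"
                )


def parse_value(raw: object, spec: VariableSpec) -> ParsedValue:
    """Parse one raw field against a variable spec.

    Total over ordinary text: every input yields exactly one of the three
    statuses and the function never raises.  An empty (or None/NaN) field
    is *missing*; text of the wrong shape for the variable kind is a
    *type_failure*; everything else parses *ok*.  The unknown code 999 is
    a legal response, not missingness.
    """
    if raw is None:
        return ParsedValue(ParseStatus.MISSING)
    if not isinstance(raw, str):
        # tolerate float NaN from pandas and stray numerics
        if isinstance(raw, float) and raw != raw:
            return ParsedValue(ParseStatus.MISSING)
        raw = str(raw)
    text = raw.strip()
    if text == "":
        return ParsedValue(ParseStatus.MISSING)

    if spec.unknown_code is not None and _INT.match(text) and int(text) == spec.unknown_code:
        return ParsedValue(ParseStatus.OK, spec.unknown_code, is_unknown=True)

    kind = spec.kind
    if kind is ValueKind.IDENTIFIER:
        return ParsedValue(ParseStatus.OK, text)

    if kind is ValueKind.DATE:
        m = _DATE_DDMMYYYY.match(text)
        if m:
            d, mo, y = (int(g) for g in m.groups())
        else:
            m = _DATE_ISO.match(text)
            if not m:
                return ParsedValue(ParseStatus.TYPE_FAILURE)
            y, mo, d = (int(g) for g in m.groups())
        try:
            return ParsedValue(ParseStatus.OK, _dt.date(y, mo, d))
        except ValueError:
            return ParsedValue(ParseStatus.TYPE_FAILURE)

    if kind is ValueKind.NUMERIC:
        try:
            return ParsedValue(ParseStatus.OK, float(text))
        except ValueError:
            return ParsedValue(ParseStatus.TYPE_FAILURE)

    # categorical and count variables are integer-coded
    if _INT.match(text):
        return ParsedValue(ParseStatus.OK, int(text))
    return ParsedValue(ParseStatus.TYPE_FAILURE)


@dataclass(frozen=True)
class DataDictionary:
    """Ordered collection of variable specs with a version label."""

    variables: Tuple[VariableSpec, ...]
    version: str = "ichom-hf-pilot-1"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ValueError("variable names must be unique within a dictionary")

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def by_kind(self, kind: ValueKind) -> list[VariableSpec]:
        return [v for v in self.variables if v.kind is kind]

    def by_area(self, area: Area) -> list[VariableSpec]:
        return [v for v in self.variables if v.area is area]

    def with_overrides(self, overrides: Mapping[str, Mapping[str, object]]) -> "DataDictionary":
        """Return a copy with per-variable overrides applied.

        ``overrides`` maps variable name to a dict with any of the keys
        ``range`` ([min, max]), ``codes`` (list of ints), ``format``
        (date format), ``unknown_code``.
        """
        new = []
        unknown = set(overrides) - set(self.names)
        if unknown:
            raise KeyError(f"override for unknown variable(s): {sorted(unknown)}")
        for v in self.variables:
            ov = overrides.get(v.name)
            if not ov:
                new.append(v)
                continue
            kwargs: dict = {}
            if "range" in ov:
                lo, hi = ov["range"]  # type: ignore[misc]
                kwargs["numeric_range"] = (float(lo), float(hi))
            if "codes" in ov:
                kwargs["allowed_codes"] = frozenset(int(c) for c in ov["codes"])  # type: ignore[arg-type]
            if "format" in ov:
                kwargs["date_format"] = str(ov["format"])
            if "unknown_code" in ov:
                kwargs["unknown_code"] = (
                    None if ov["unknown_code"] is None else int(ov["unknown_code"])  # type: ignore[arg-type]
                )
            new.append(replace(v, **kwargs))
        return DataDictionary(tuple(new), version=self.version + "+overrides")


# -- the built-in ICHOM heart-failure dictionary ------------------------------

_YN_UNKNOWN = frozenset({0, 1, 999})

#: Default plausibility ranges for height (cm) and weight (kg).  The source
#: protocol for the pilot assessment does not publish the exact bounds it
#: used; these are configurable assumptions wide enough for an adult
#: heart-failure cohort.  Zero is deliberately outside both ranges so that
#: zero-coded missing measurements surface as range violations.
DEFAULT_HEIGHT_RANGE_CM = (100.0, 250.0)
DEFAULT_WEIGHT_RANGE_KG = (20.0, 350.0)

VALID_INCOMPLETE_DEATH = "only_if_died_during_visit"


def _flag(name: str, area: Area) -> VariableSpec:
    return VariableSpec(
        name=name,
        area=area,
        kind=ValueKind.CATEGORICAL,
        allowed_codes=_YN_UNKNOWN,
        unknown_code=999,
    )


def default_dictionary() -> DataDictionary:
    """The 22-variable visit-level dictionary of the heart-failure pilot.

    Twenty-one ICHOM items plus the visit identifier added to distinguish
    visit records.  Repeated calls return equal dictionaries.
    """
    variables = (
        VariableSpec("Patient ID", Area.IDENTIFIERS, ValueKind.IDENTIFIER),
        VariableSpec("Visit ID", Area.IDENTIFIERS, ValueKind.IDENTIFIER),
        # "Age" is the ICHOM item name; the recorded value is the birth date.
        VariableSpec("Age", Area.DEMOGRAPHIC, ValueKind.DATE),
        VariableSpec(
            "Sex",
            Area.DEMOGRAPHIC,
            ValueKind.CATEGORICAL,
            allowed_codes=frozenset({1, 2}),
        ),
        _flag("Atrial fibrillation", Area.BASELINE_HEALTH),
        _flag("Prior myocardial infarction", Area.BASELINE_HEALTH),
        _flag("Hypertension", Area.BASELINE_HEALTH),
        _flag("Diabetes mellitus", Area.BASELINE_HEALTH),
        _flag("Echocardiogram performed", Area.BASELINE_HEALTH),
        VariableSpec(
            "Height",
            Area.BASELINE_HEALTH,
            ValueKind.NUMERIC,
            numeric_range=DEFAULT_HEIGHT_RANGE_CM,
            units="cm",
        ),
        VariableSpec(
            "Weight",
            Area.BASELINE_HEALTH,
            ValueKind.NUMERIC,
            numeric_range=DEFAULT_WEIGHT_RANGE_KG,
            units="kg",
        ),
        _flag("Alcohol use", Area.BASELINE_HEALTH),
        _flag("Smoking status", Area.BASELINE_HEALTH),
        _flag("Beta blocker", Area.TREATMENT),
        _flag("Calcium channel blocker", Area.TREATMENT),
        _flag("Digoxin", Area.TREATMENT),
        _flag("Diuretics", Area.TREATMENT),
        VariableSpec("Date of arrival", Area.BURDEN_OF_CARE, ValueKind.DATE),
        VariableSpec("Date of discharge", Area.BURDEN_OF_CARE, ValueKind.DATE),
        VariableSpec(
            "Hospital admissions", Area.BURDEN_OF_CARE, ValueKind.COUNT, unknown_code=999
        ),
        VariableSpec(
            "Hospital appointments", Area.BURDEN_OF_CARE, ValueKind.COUNT, unknown_code=999
        ),
        VariableSpec(
            "Date of death",
            Area.MORTALITY,
            ValueKind.DATE,
            unknown_code=999,
            valid_incompleteness=VALID_INCOMPLETE_DEATH,
        ),
    )
    return DataDictionary(variables)


# -- code lists ---------------------------------------------------------------


@dataclass(frozen=True)
class CodeList:
    """A labelled set of diagnosis/medication codes with a match mode.

    ``exact`` matches a code verbatim; ``prefix`` matches any code that
    starts with one of the listed codes (the usual convention for ATC and
    for dotted ICD-9 hierarchies).
    """

    label: str
    codes: frozenset[str]
    match: str = "exact"  # "exact" | "prefix"

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"code list {self.label!r} must be non-empty")
        if any(not c for c in self.codes):
            raise ValueError(f"code list {self.label!r} contains an empty code")
        if self.match not in ("exact", "prefix"):
            raise ValueError(f"unknown match mode {self.match!r}")

    def matches(self, code: str) -> bool:
        if self.match == "exact":
            return code in self.codes
        return any(code.startswith(p) for p in self.codes)

    def matches_any(self, codes: Iterable[str]) -> bool:
        return any(self.matches(c) for c in codes)


#: ICD-9 codes defining the congestive-heart-failure cohort (the 428 family).
HEART_FAILURE_ICD9: Sequence[str] = (
    "428", "428.0", "428.1", "428.2", "428.20", "428.21", "428.22", "428.23",
    "428.3", "428.30", "428.31", "428.32", "428.33",
    "428.4", "428.40", "428.41", "428.42", "428.43", "428.9",
)


def hf_icd9_codes() -> CodeList:
    """The built-in heart-failure ICD-9 code list (19 dotted codes, exact match)."""
    return CodeList("heart_failure_icd9", frozenset(HEART_FAILURE_ICD9), match="exact")
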