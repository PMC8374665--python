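"""The flat visit-centered table every quality check consumes.

A :class:`VisitTable` wraps a pandas DataFrame of *raw* string values (one
row per visit record, one column per dictionary variable) together with the
dictionary and per-cell parse results.  Raw values are preserved verbatim so
that writing a table back to CSV round-trips exactly; typed views (dates,
numerics, integer codes) are computed lazily and cached.  Row order carries
no meaning: every check is row-order invariant.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .dictionary import (
    DataDictionary,
    ParseStatus,
    ParsedValue,
    ValueKind,
    VariableSpec,
    parse_value,
)

__all__ = ["VisitTable", "VisitRecord", "Provenance"]


@dataclass(frozen=True)
class Provenance:
    """Where a table came from and the extraction window it covers."""

    source: str = "unknown"
    window_start: Optional[_dt.date] = None
    window_end: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        if (
            self.window_start is not None
            and self.window_end is not None
            and self.window_start > self.window_end
        ):
            raise ValueError("extraction window start must be <= end")


@dataclass(frozen=True)
class VisitRecord:
    """One visit record: raw text, typed values and parse status per variable."""

    raw: dict
    parsed: dict  # name -> ParsedValue

    def status(self, name: str) -> ParseStatus:
        return self.parsed[name].status

    def value(self, name: str):
        return self.parsed[name].value


def _parse_column(raw: pd.Series, spec: VariableSpec):
    """Vectorised parse of one raw column.

    Returns (status: Series[str], typed: Series, unknown: Series[bool]).
    ``typed`` is datetime64 for dates, float for numeric/count/categorical
    (NaN where not ok or unknown-coded), object for identifiers.
    """
    s = raw.fillna("").astype(str).str.strip()
    missing = s == ""
    status = pd.Series(np.where(missing, ParseStatus.MISSING.value, ParseStatus.OK.value),
                       index=s.index)
    unknown = pd.Series(False, index=s.index)
    if spec.unknown_code is not None:
        unknown = (~missing) & (s == str(spec.unknown_code))

    candidates = ~missing & ~unknown
    kind = spec.kind
    if kind is ValueKind.IDENTIFIER:
        typed = s.where(candidates, other=None)
        return status, typed, unknown

    if kind is ValueKind.DATE:
        txt = s.where(candidates, other="")
        parsed = pd.to_datetime(txt, format="%d/%m/%Y", errors="coerce")
        iso_try = parsed.isna() & candidates
        if iso_try.any():
            iso = pd.to_datetime(txt[iso_try], format="%Y-%m-%d", errors="coerce")
            parsed = parsed.copy()
            parsed[iso_try] = iso
        fail = candidates & parsed.isna()
        status[fail] = ParseStatus.TYPE_FAILURE.value
        return status, parsed, unknown

    if kind is ValueKind.NUMERIC:
        typed = pd.to_numeric(s.where(candidates, other=""), errors="coerce")
        fail = candidates & typed.isna()
        status[fail] = ParseStatus.TYPE_FAILURE.value
        return status, typed, unknown

    # categorical / count: integer-coded
    ok_int = s.str.fullmatch(r"[+-]?\d+")
    typed = pd.to_numeric(s.where(candidates & ok_int, other=""), errors="coerce")
    fail = candidates & ~ok_int.fillna(False).astype(bool)
    status[fail] = ParseStatus.TYPE_FAILURE.value
    return status, typed, unknown


class VisitTable:
    """Flat ICHOM visit table: raw values plus parsed views.

    Parameters
    ----------
    raw
        DataFrame of raw string values; columns must exactly match the
        dictionary's variable names (any order; stored in dictionary order).
    dictionary
        The variable schema the table conforms to.
    provenance
        Source label and extraction window.
    """

    def __init__(
        self,
        raw: pd.DataFrame,
        dictionary: DataDictionary,
        provenance: Provenance | None = None,
    ) -> None:
        missing = set(dictionary.names) - set(raw.columns)
        if missing:
            raise ValueError(f"raw table lacks dictionary column(s): {sorted(missing)}")
        extra = set(raw.columns) - set(dictionary.names)
        if extra:
            raise ValueError(f"raw table has non-dictionary column(s): {sorted(extra)}")
        self.raw = (
            raw[dictionary.names]
            .reset_index(drop=True)
            .fillna("")
            .astype(str)
        )
        # normalise pandas' stringified NaN back to empty
        self.raw = self.raw.replace("nan", "")
        self.dictionary = dictionary
        self.provenance = provenance or Provenance()
        self._status: Optional[pd.DataFrame] = None
        self._typed: dict = {}
        self._unknown: Optional[pd.DataFrame] = None

    # -- basic container protocol --------------------------------------------

    def __len__(self) -> int:
        return len(self.raw)

    def __iter__(self) -> Iterator[VisitRecord]:
        for _, row in self.raw.iterrows():
            parsed = {
                v.name: parse_value(row[v.name], v) for v in self.dictionary
            }
            yield VisitRecord(raw=dict(row), parsed=parsed)

    def record(self, i: int) -> VisitRecord:
        row = self.raw.iloc[i]
        parsed = {v.name: parse_value(row[v.name], v) for v in self.dictionary}
        return VisitRecord(raw=dict(row), parsed=parsed)

    # -- parsed views ---------------------------------------------------------

    def _ensure_parsed(self) -> None:
        if self._status is not None:
            return
        status = {}
        unknown = {}
        for spec in self.dictionary:
            st, typed, unk = _parse_column(self.raw[spec.name], spec)
            status[spec.name] = st
            unknown[spec.name] = unk
            self._typed[spec.name] = typed
        self._status = pd.DataFrame(status)
        self._unknown = pd.DataFrame(unknown)

    @property
    def status(self) -> pd.DataFrame:
        """Per-cell parse status ('ok' | 'missing' | 'type_failure')."""
        self._ensure_parsed()
        assert self._status is not None
        return self._status

    @property
    def unknown(self) -> pd.DataFrame:
        """Per-cell boolean mask: raw value equals the variable's unknown code."""
        self._ensure_parsed()
        assert self._unknown is not None
        return self._unknown

    def typed(self, name: str) -> pd.Series:
        """Typed view of one column (datetime64 / float / object).

        Cells that are missing, type failures or unknown-coded are NaT/NaN.
        """
        self._ensure_parsed()
        return self._typed[name]

    # -- convenience ----------------------------------------------------------

    def with_raw(self, raw: pd.DataFrame) -> "VisitTable":
        """A new table with the same dictionary/provenance and different rows."""
        return VisitTable(raw, self.dictionary, self.provenance)

    def window(self) -> Tuple[Optional[_dt.date], Optional[_dt.date]]:
        return self.provenance.window_start, self.provenance.window_end

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VisitTable):
            return NotImplemented
        return self.raw.equals(other.raw) and self.dictionary == other.dictionary
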