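"""CSV I/O for flat visit tables, code lists and dictionary overrides.

Flat visit tables are UTF-8 CSV with a header row of variable names and an
empty cell for missing; raw values round-trip verbatim through
:func:`write_visit_table` / :func:`read_visit_table`.  Code lists are plain
text (one code per line, ``#`` comments allowed) or two-column CSV
(code, description).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Mapping, Optional
import warnings

import pandas as pd
import yaml

from .dictionary import CodeList, DataDictionary, default_dictionary
from .table import Provenance, VisitTable

__all__ = [
    "SchemaError",
    "read_visit_table",
    "write_visit_table",
    "read_code_list",
    "write_code_list",
    "load_dictionary",
]


class SchemaError(ValueError):
    """The file's columns do not match the data dictionary."""


def read_visit_table(
    path: str | Path,
    dictionary: Optional[DataDictionary] = None,
    *,
    lax: bool = False,
    provenance: Optional[Provenance] = None,
) -> VisitTable:
    """Read a flat ICHOM visit table from CSV.

    Header names must match the dictionary's variables (order-insensitive).
    A missing column is always a :class:`SchemaError`; an extra column is a
    :class:`SchemaError` in strict mode (default) or a warning in ``lax``
    mode, where it is dropped.
    """
    dictionary = dictionary or default_dictionary()
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(dictionary.names) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {sorted(missing)}")
    extra = set(raw.columns) - set(dictionary.names)
    if extra:
        if not lax:
            raise SchemaError(f"{path.name}: unexpected column(s): {sorted(extra)}")
        warnings.warn(f"{path.name}: ignoring unexpected column(s): {sorted(extra)}")
        raw = raw[dictionary.names]
    return VisitTable(raw, dictionary, provenance or Provenance(source=str(path)))


def write_visit_table(table: VisitTable, path: str | Path) -> Path:
    """Write the raw values of a visit table to CSV (round-trip exact)."""
    path = Path(path)
    table.raw.to_csv(path, index=False)
    return path


def read_code_list(
    path: str | Path, label: Optional[str] = None, *, match: str = "exact"
) -> CodeList:
    """Read a code list from plain text (one code per line) or 2-column CSV.

    A line containing a comma is treated as ``code,description``; blank
    lines and ``#`` comments are skipped.  An empty file violates the
    code-list invariant and raises ``ValueError``.
    """
    path = Path(path)
    codes: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code = line.split(",", 1)[0].strip()
        if code and code.lower() != "code":  # tolerate a CSV header row
            codes.append(code)
    return CodeList(label or path.stem, frozenset(codes), match=match)


def write_code_list(codes: CodeList, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(sorted(codes.codes)) + "\n", encoding="utf-8")
    return path


def load_dictionary(path: str | Path) -> DataDictionary:
    """Load the default dictionary with per-variable overrides from YAML.

    The file maps variable names to any of ``range: [lo, hi]``,
    ``codes: [..]``, ``format``, ``unknown_code``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        overrides: Mapping[str, Mapping[str, object]] = yaml.safe_load(fh) or {}
    return default_dictionary().with_overrides(overrides)


def parse_iso_date(text: str) -> _dt.date:
    return _dt.date.fromisoformat(text)
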