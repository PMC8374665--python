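"""Independent brute-force recounts used to cross-check every structural check.

These oracles deliberately avoid the library's vectorised paths: uniqueness
is full pairwise comparison over raw rows, field checks call the scalar
parser cell by cell, and the temporal-order scan is a per-patient loop.
"""

import datetime as dt

from ichomdq.dictionary import ParseStatus, ValueKind, parse_value


def _rows_and_vid(raw):
    cols = list(raw.columns)
    vid = cols.index("Visit ID")
    rows = raw.values.tolist()
    others = [[v for k, v in enumerate(r) if k != vid] for r in rows]
    vids = [r[vid] for r in rows]
    return vids, others


def brute_uniqueness1(raw):
    """Rows sharing a visit ID with >=1 other row differing somewhere else."""
    vids, others = _rows_and_vid(raw)
    n = len(vids)
    hits = 0
    for i in range(n):
        for j in range(n):
            if i != j and vids[i] == vids[j] and others[i] != others[j]:
                hits += 1
                break
    return hits


def brute_uniqueness2(raw):
    """Rows with a same-day identical twin under a different visit ID."""
    vids, others = _rows_and_vid(raw)
    n = len(vids)
    hits = 0
    for i in range(n):
        for j in range(n):
            if i != j and vids[i] != vids[j] and others[i] == others[j]:
                hits += 1
                break
    return hits


def brute_type_counts(raw, dictionary):
    """Per variable: (type failures, non-missing cells), via the scalar parser."""
    out = {}
    for spec in dictionary:
        fail = assessable = 0
        for v in raw[spec.name]:
            p = parse_value(v, spec)
            if p.status is not ParseStatus.MISSING:
                assessable += 1
            if p.status is ParseStatus.TYPE_FAILURE:
                fail += 1
        out[spec.name] = (fail, assessable)
    return out


def brute_range_counts(raw, dictionary, window):
    """Per variable: (range/domain violations, well-typed cells)."""
    out = {}
    for spec in dictionary:
        viol = ok = 0
        for v in raw[spec.name]:
            p = parse_value(v, spec)
            if p.status is not ParseStatus.OK:
                continue
            ok += 1
            if p.is_unknown:
                continue
            if spec.kind is ValueKind.NUMERIC and spec.numeric_range:
                lo, hi = spec.numeric_range
                if not lo <= p.value <= hi:
                    viol += 1
            elif spec.kind is ValueKind.CATEGORICAL and spec.allowed_codes:
                if p.value not in spec.allowed_codes:
                    viol += 1
            elif spec.kind is ValueKind.COUNT:
                if p.value < 0:
                    viol += 1
            elif spec.kind is ValueKind.DATE and spec.name == "Date of arrival":
                if not window[0] <= p.value <= window[1]:
                    viol += 1
        out[spec.name] = (viol, ok)
    return out


def brute_completeness_counts(raw, dictionary):
    """Per variable without a validity rule: (empty cells, all cells)."""
    out = {}
    for spec in dictionary:
        if spec.valid_incompleteness is not None:
            continue
        empty = sum(1 for v in raw[spec.name] if str(v).strip() == "")
        out[spec.name] = (empty, len(raw))
    return out


def _parse_date(text):
    for fmt in ("%d/%m/%Y", "%Y-%m-%d"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


def brute_rule_counts(raw):
    """(violating records, evaluable records) under the two default date rules."""
    viol = evaluable = 0
    for i in range(len(raw)):
        arr = _parse_date(raw.at[i, "Date of arrival"])
        dis = _parse_date(raw.at[i, "Date of discharge"])
        dea = _parse_date(raw.at[i, "Date of death"])
        any_eval = False
        any_viol = False
        if arr and dis:
            any_eval = True
            if arr > dis:
                any_viol = True
        if dis and dea:
            any_eval = True
            if dis > dea:
                any_viol = True
        evaluable += any_eval
        viol += any_viol
    return viol, evaluable


def brute_history_order(raw, condition):
    """Violating record indices for one condition, per-patient scan."""
    rows = []
    for i in range(len(raw)):
        arr = _parse_date(raw.at[i, "Date of arrival"])
        if arr is None:
            continue
        rows.append((raw.at[i, "Patient ID"], arr, raw.at[i, "Visit ID"], i))
    rows.sort()
    seen = {}
    violations = []
    for pid, _arr, _vid, i in rows:
        v = raw.at[i, condition]
        if v == "1":
            seen[pid] = True
        elif v == "0" and seen.get(pid):
            violations.append(i)
    return violations
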