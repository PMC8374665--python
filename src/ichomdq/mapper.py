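"""Map a relational EHR source to the flat visit-centered ICHOM table.

The mapping mirrors the extraction procedure under assessment: patient and
visit identifiers form the left spine of a successive left-outer-join;
diagnoses join via visit identifiers, while drug and measure events join by
(patient ID, arrival date).  That date-matching join is deliberately
faithful to the flawed real-world process: two visits of one patient on the
same day both receive that day's clinical data (same-day duplicate rows),
two differing measurements on one date multiply a visit into partially
duplicated rows (visit-ID collisions), absent measurements are zero-coded
because the target format accepts only numerics, and the absence of a
diagnosis code maps to "No" rather than "Unknown" — the mechanism that
turns missing history data into false negatives.
"""

from __future__ import annotations

import datetime as _dt
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dictionary import CodeList, DataDictionary, default_dictionary, hf_icd9_codes
from .synthetic import (
    DEFAULT_ATC_CODES,
    DEFAULT_CONDITION_CODES,
    DEFAULT_FLAG_CODES,
    RelationalSource,
    WINDOW_END,
    WINDOW_START,
)
from .table import Provenance, VisitTable

__all__ = ["map_to_ichom", "select_cohort", "default_code_lists"]

_CONDITIONS = tuple(DEFAULT_CONDITION_CODES)
_FLAGS = tuple(DEFAULT_FLAG_CODES)
_MEDICATIONS = tuple(DEFAULT_ATC_CODES)


def default_code_lists() -> dict[str, CodeList]:
    """Stub code lists for comorbidities, habits and medications.

    The corresponding appendices of the assessment protocol are not
    published; these prefix lists are documented defaults meant to be
    replaced by site-specific configuration.
    """
    lists: dict[str, CodeList] = {}
    for name, code in {**DEFAULT_CONDITION_CODES, **DEFAULT_FLAG_CODES}.items():
        lists[name] = CodeList(name, frozenset({code}), match="prefix")
    for name, code in DEFAULT_ATC_CODES.items():
        lists[name] = CodeList(name, frozenset({code}), match="prefix")
    return lists


def _fmt(date_iso: str) -> str:
    return _dt.date.fromisoformat(date_iso).strftime("%d/%m/%Y")


def _match_mask(codes: pd.Series, clist: CodeList) -> np.ndarray:
    if clist.match == "exact":
        return codes.isin(clist.codes).to_numpy()
    prefixes = tuple(sorted(clist.codes))
    return codes.str.startswith(prefixes).fillna(False).to_numpy()


def select_cohort(
    source: RelationalSource,
    hf_codes: Optional[CodeList] = None,
    window: tuple[_dt.date, _dt.date] = (WINDOW_START, WINDOW_END),
) -> RelationalSource:
    """Keep the patients having at least one heart-failure diagnosis in-window.

    All rows of retained patients are kept across all five tables.  An
    empty cohort yields a warning, not an error.
    """
    hf_codes = hf_codes or hf_icd9_codes()
    diag = source.diagnoses.merge(
        source.visits[["visit_id", "patient_id", "arrival_date"]],
        on="visit_id", how="left",
    )
    in_window = (diag["arrival_date"] >= window[0].isoformat()) & (
        diag["arrival_date"] <= window[1].isoformat()
    )
    hit = _match_mask(diag["icd9_code"].astype(str), hf_codes) & in_window.to_numpy()
    keep_patients = set(diag.loc[hit, "patient_id"])
    if not keep_patients:
        import warnings

        warnings.warn("cohort selection matched no patients")
    patients = source.patients[source.patients["patient_id"].isin(keep_patients)]
    visits = source.visits[source.visits["patient_id"].isin(keep_patients)]
    diagnoses = source.diagnoses[source.diagnoses["visit_id"].isin(set(visits["visit_id"]))]
    drugs = source.drugs[source.drugs["patient_id"].isin(keep_patients)]
    measures = source.measures[source.measures["patient_id"].isin(keep_patients)]
    return RelationalSource(
        patients.reset_index(drop=True),
        visits.reset_index(drop=True),
        diagnoses.reset_index(drop=True),
        drugs.reset_index(drop=True),
        measures.reset_index(drop=True),
    )


def map_to_ichom(
    source: RelationalSource,
    dictionary: Optional[DataDictionary] = None,
    code_lists: Optional[Mapping[str, CodeList]] = None,
    *,
    unknown_as_999: bool = False,
    window: tuple[_dt.date, _dt.date] = (WINDOW_START, WINDOW_END),
) -> VisitTable:
    """Produce the flat visit-centered ICHOM table from a relational source.

    One output row per (visit, joined height/weight combination).  History
    flags are 1 when any diagnosis of the patient up to and including the
    visit date matches the condition's code list, else 0 — never 999 unless
    ``unknown_as_999`` (a strict mode that encodes absence of evidence as
    Unknown instead of No).  Missing height/weight joins are zero-coded.
    Output rows follow a stable (patient ID, arrival date, visit ID) order.
    """
    source.check_integrity()
    dictionary = dictionary or default_dictionary()
    lists = dict(default_code_lists())
    if code_lists:
        lists.update(code_lists)

    visits = source.visits.sort_values(
        ["patient_id", "arrival_date", "visit_id"], kind="mergesort"
    ).reset_index(drop=True)
    patients = source.patients.set_index("patient_id")

    out = pd.DataFrame(index=visits.index)
    out["Patient ID"] = visits["patient_id"]
    out["Visit ID"] = visits["visit_id"]
    out["Age"] = visits["patient_id"].map(patients["birth_date"]).map(_fmt)
    out["Sex"] = visits["patient_id"].map(patients["sex"]).astype(int).astype(str)

    # diagnosis rows annotated with the arrival date of their visit
    diag = source.diagnoses.merge(
        source.visits[["visit_id", "patient_id", "arrival_date"]],
        on="visit_id", how="left",
    )
    codes = diag["icd9_code"].astype(str)

    absent = "999" if unknown_as_999 else "0"
    for cond in _CONDITIONS:
        hit = diag.loc[_match_mask(codes, lists[cond])]
        first = hit.groupby("patient_id")["arrival_date"].min()
        first_for_visit = visits["patient_id"].map(first)
        flag = visits["arrival_date"] >= first_for_visit
        out[cond] = np.where(first_for_visit.notna() & flag, "1", absent)

    # per-visit status flags share all data recorded on the same day
    for flag_name in _FLAGS:
        hit = diag.loc[_match_mask(codes, lists[flag_name])]
        keys = set(zip(hit["patient_id"], hit["arrival_date"]))
        present = [
            (p, d) in keys
            for p, d in zip(visits["patient_id"], visits["arrival_date"])
        ]
        out[flag_name] = np.where(present, "1", absent)

    # treatments: ATC prefix match on (patient, arrival date)
    drug_codes = source.drugs["atc_code"].astype(str) if len(source.drugs) else pd.Series(dtype=str)
    for med in _MEDICATIONS:
        if len(source.drugs):
            hit = source.drugs.loc[_match_mask(drug_codes, lists[med])]
            keys = set(zip(hit["patient_id"], hit["date"]))
        else:
            keys = set()
        present = [
            (p, d) in keys
            for p, d in zip(visits["patient_id"], visits["arrival_date"])
        ]
        out[med] = np.where(present, "1", "0")

    # burden of care: the patient's visits in the 365 days before arrival
    adm, app = _burden_counts(visits)
    out["Hospital admissions"] = adm
    out["Hospital appointments"] = app

    out["Date of arrival"] = visits["arrival_date"].map(_fmt)
    out["Date of discharge"] = visits["discharge_date"].map(_fmt)

    death = visits["patient_id"].map(patients["death_date"]).fillna("")
    died_here = (
        (death != "")
        & (death >= visits["arrival_date"])
        & (death <= visits["discharge_date"])
    )
    out["Date of death"] = np.where(died_here, death.map(
        lambda d: _fmt(d) if d else ""), "")

    # measures: cross product of same-date height and weight values; the
    # (patient, arrival, visit ID) order set on the visit spine is preserved
    out = _join_measures(out, visits, source.measures)
    prov = Provenance(source="mapped", window_start=window[0], window_end=window[1])
    return VisitTable(out[dictionary.names], dictionary, prov)


def _burden_counts(visits: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Hospitalisations and same-day appointments in the prior 365 days."""
    admissions: list[str] = []
    appointments: list[str] = []
    by_patient: dict[str, list[tuple[str, str]]] = {}
    for p, a, d in zip(visits["patient_id"], visits["arrival_date"],
                       visits["discharge_date"]):
        by_patient.setdefault(p, []).append((a, d))
    for p, a in zip(visits["patient_id"], visits["arrival_date"]):
        a_date = _dt.date.fromisoformat(a)
        n_adm = n_app = 0
        for oa, od in by_patient[p]:
            delta = (a_date - _dt.date.fromisoformat(oa)).days
            if 0 < delta <= 365:
                if oa == od:
                    n_app += 1
                else:
                    n_adm += 1
        admissions.append(str(n_adm))
        appointments.append(str(n_app))
    return admissions, appointments


def _fmt_value(v: float) -> str:
    if float(v) == int(float(v)):
        return str(int(float(v)))
    return f"{float(v):g}"


def _join_measures(
    out: pd.DataFrame, visits: pd.DataFrame, measures: pd.DataFrame
) -> pd.DataFrame:
    """Attach height/weight by (patient, date); multiply rows per combination."""
    if not len(measures):
        out = out.copy()
        out["Height"] = "0"
        out["Weight"] = "0"
        return out
    combos: dict[tuple[str, str], list[tuple[str, str]]] = {}
    grouped = measures.groupby(["patient_id", "date"])
    for (p, d), grp in grouped:
        heights = [
            _fmt_value(v) for v in grp.loc[grp["measure"] == "height", "value"]
        ] or ["0"]
        weights = [
            _fmt_value(v) for v in grp.loc[grp["measure"] == "weight", "value"]
        ] or ["0"]
        combos[(p, d)] = [(h, w) for h in heights for w in weights]

    rows = []
    for i in out.index:
        key = (visits.at[i, "patient_id"], visits.at[i, "arrival_date"])
        for h, w in combos.get(key, [("0", "0")]):
            row = out.loc[i].copy()
            row["Height"] = h
            row["Weight"] = w
            rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)
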