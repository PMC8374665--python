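import datetime as dt

import pandas as pd
import pytest

from ichomdq import VisitTable, default_dictionary
from ichomdq.table import Provenance

#: a fully valid visit row used as the template for hand-built tables
ROW_TEMPLATE = {
    "Patient ID": "P0001",
    "Visit ID": "V0001",
    "Age": "14/05/1949",
    "Sex": "1",
    "Atrial fibrillation": "0",
    "Prior myocardial infarction": "0",
    "Hypertension": "1",
    "Diabetes mellitus": "0",
    "Echocardiogram performed": "1",
    "Height": "170",
    "Weight": "65",
    "Alcohol use": "0",
    "Smoking status": "999",
    "Beta blocker": "1",
    "Calcium channel blocker": "0",
    "Digoxin": "0",
    "Diuretics": "1",
    "Date of arrival": "05/03/2010",
    "Date of discharge": "08/03/2010",
    "Hospital admissions": "1",
    "Hospital appointments": "2",
    "Date of death": "",
}

WINDOW = (dt.date(2006, 1, 1), dt.date(2017, 11, 7))


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


def build_table(rows, dictionary=None, window=WINDOW):
    """Build a VisitTable from partial row dicts, filling the template.

    Each row automatically receives a distinct visit ID (and patient ID,
    when not given) so hand-built tables are clean unless a test says
    otherwise.
    """
    dictionary = dictionary or default_dictionary()
    full = []
    for i, r in enumerate(rows):
        row = dict(ROW_TEMPLATE)
        row["Visit ID"] = f"V{i:04d}"
        row["Patient ID"] = f"P{i:04d}"
        row.update(r)
        full.append(row)
    raw = pd.DataFrame(full, columns=dictionary.names)
    prov = Provenance(source="test", window_start=window[0], window_end=window[1])
    return VisitTable(raw, dictionary, prov)


@pytest.fixture
def make_table():
    return build_table
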