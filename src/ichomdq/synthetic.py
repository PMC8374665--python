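"""Seeded synthetic EHR generator with planted data-quality errors.

Emulates the study conditions of a 2006–2017 hospital visit stream for a
congestive-heart-failure cohort: a flat visit-centered ICHOM table (or a
small relational source of patients / visits / diagnoses / drugs / measures
tables), ICHOM 0/1/999 response coding, DD/MM/YYYY dates, and every error
class observed in the pilot assessment — visit-ID collisions, same-day
clones, zero-coded height/weight, out-of-range measurements, early arrival
dates, implausible BMIs, value inversions, and history-flag flips — planted
at configurable rates or exact counts and recorded in a ground-truth
ledger.  A documentation regime shift (reduced recording of past medical
conditions from 2011) and gradual medication-recording trends are part of
the generative model itself, since they are practice phenomena rather than
record-level errors.

Identical (config, seed) pairs produce byte-identical output: every stage
draws from its own named substream in a fixed order, so disabling one error
class does not perturb the others.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .dictionary import DataDictionary, default_dictionary, hf_icd9_codes
from .table import Provenance, VisitTable

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "RelationalSource",
    "generate_flat",
    "generate_source",
    "inject_temporal_patterns",
    "plant_errors",
]

WINDOW_START = _dt.date(2006, 1, 1)
WINDOW_END = _dt.date(2017, 11, 7)

_CONDITIONS = (
    "Atrial fibrillation",
    "Hypertension",
    "Diabetes mellitus",
    "Prior myocardial infarction",
)
_PER_VISIT_FLAGS = ("Echocardiogram performed", "Alcohol use", "Smoking status")
_MEDICATIONS = ("Beta blocker", "Calcium channel blocker", "Digoxin", "Diuretics")

#: Default stub code lists for the unpublished comorbidity / medication /
#: habit appendices (ICD-9 prefixes and ATC prefixes).  Override via config.
DEFAULT_CONDITION_CODES: Mapping[str, str] = {
    "Atrial fibrillation": "427.31",
    "Hypertension": "401",
    "Diabetes mellitus": "250",
    "Prior myocardial infarction": "410",
}
DEFAULT_FLAG_CODES: Mapping[str, str] = {
    "Echocardiogram performed": "88.72",
    "Alcohol use": "305.0",
    "Smoking status": "305.1",
}
DEFAULT_ATC_CODES: Mapping[str, str] = {
    "Beta blocker": "C07",
    "Calcium channel blocker": "C08",
    "Digoxin": "C01AA05",
    "Diuretics": "C03",
}

_DEPARTMENTS = ("cardiology", "emergency", "internal medicine", "geriatrics")


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class ErrorPlan:
    """How many records each error class affects.

    Each field is either an absolute count (int) or a fraction of the table
    (float below 1).  In ``exact_count`` mode fractions are rounded to exact
    counts and planting is deterministic given the seed; in ``rate`` mode
    counts are converted to per-row probabilities and the realised number is
    binomial.  Defaults mirror the error burden reported by the pilot
    assessment: 1.2% visit-ID collisions, 2.8% same-day clones, 85%
    zero-coded height/weight, 54 out-of-range heights, 20 out-of-range
    weights, 16 early arrival dates, 16 low-BMI and 180 high-BMI records,
    and history-flip rates of 6.33% / 12.11% / 6.12% / 12.11% for atrial
    fibrillation, hypertension, diabetes and myocardial infarction.
    """

    duplicate_id: float | int = 0.012
    same_day_duplicate: float | int = 0.028
    zero_height_weight: float | int = 0.85
    out_of_range_height: float | int = 54
    out_of_range_weight: float | int = 20
    early_arrival_dates: float | int = 16
    hw_inversion: float | int = 0
    low_bmi: float | int = 16
    high_bmi: float | int = 180
    history_flip: Mapping[str, float] = field(
        default_factory=lambda: {
            "Atrial fibrillation": 0.0633,
            "Hypertension": 0.1211,
            "Diabetes mellitus": 0.0612,
            "Prior myocardial infarction": 0.1211,
        }
    )

    @classmethod
    def none(cls) -> "ErrorPlan":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0, {})


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Cohort size and visit intensity default to a desk-scale rendering of
    the pilot population (about ten visits per patient across the 2006–2017
    extraction window).  Demographic defaults are arbitrary but realistic
    for a heart-failure cohort; the regime shift (past-condition recording
    multiplied by 0.3 from 2011) and gentle medication-recording uptrends
    reproduce the documented stability phenomena.
    """

    n_patients: int = 1000
    mean_visits_per_patient: float = 10.0
    window: tuple[_dt.date, _dt.date] = (WINDOW_START, WINDOW_END)
    seed: int = 0
    mode: str = "exact_count"  # "exact_count" | "rate"
    death_probability_per_visit: float = 0.02
    # demographics (descriptives of the source cohort are unpublished)
    male_fraction: float = 0.55
    age_range_years: tuple[int, int] = (40, 95)
    same_day_fraction: float = 0.55  # share of visits that are same-day appointments
    condition_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "Atrial fibrillation": 0.35,
            "Hypertension": 0.60,
            "Diabetes mellitus": 0.40,
            "Prior myocardial infarction": 0.35,
        }
    )
    per_visit_flag_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "Echocardiogram performed": 0.30,
            "Alcohol use": 0.08,
            "Smoking status": 0.15,
        }
    )
    medication_base: Mapping[str, float] = field(
        default_factory=lambda: {
            "Beta blocker": 0.10,
            "Calcium channel blocker": 0.08,
            "Digoxin": 0.06,
            "Diuretics": 0.12,
        }
    )
    #: additive change in per-visit recording probability per elapsed month
    medication_trend: Mapping[str, float] = field(
        default_factory=lambda: {
            "Beta blocker": 0.0025,
            "Calcium channel blocker": 0.0006,
            "Digoxin": 0.0001,
            "Diuretics": 0.0020,
        }
    )
    regime_shift: tuple[_dt.date, float] = (_dt.date(2011, 1, 1), 0.3)
    #: months whose visit volume is thinned (emulating months with <10 records)
    thin_months: tuple[_dt.date, _dt.date] = (_dt.date(2016, 1, 1), _dt.date(2016, 6, 30))
    thin_factor: float = 0.1
    monthly_volume_slope: float = 0.0
    # relational-source knobs
    same_day_visit_rate: float = 0.015  # second same-day visit in another department
    measure_rate: float = 0.15  # share of visit dates with a height/weight measure
    duplicate_measure_rate: float = 0.012  # second, differing weight the same date
    errors: ErrorPlan = field(default_factory=ErrorPlan)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.window[0] >= self.window[1]:
            raise ConfigError("window start must precede end")
        if self.mode not in ("exact_count", "rate"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in (
            "death_probability_per_visit", "male_fraction", "same_day_fraction",
            "thin_factor", "same_day_visit_rate", "measure_rate",
            "duplicate_measure_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")

    def clean(self) -> "GeneratorConfig":
        """A copy with no planted errors, no regime shift and flat trends.

        Produces a pristine table: monotone history flags, documented
        measurements, unique identifiers.
        """
        return replace(
            self,
            errors=ErrorPlan.none(),
            regime_shift=(self.regime_shift[0], 1.0),
            medication_trend={m: 0.0 for m in _MEDICATIONS},
        )

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "GeneratorConfig":
        data = dict(data)
        if "window" in data:
            a, b = data["window"]  # type: ignore[misc]
            data["window"] = (_as_date(a), _as_date(b))
        if "thin_months" in data:
            a, b = data["thin_months"]  # type: ignore[misc]
            data["thin_months"] = (_as_date(a), _as_date(b))
        if "regime_shift" in data:
            d, m = data["regime_shift"]  # type: ignore[misc]
            data["regime_shift"] = (_as_date(d), float(m))
        if "errors" in data and not isinstance(data["errors"], ErrorPlan):
            data["errors"] = ErrorPlan(**data["errors"])  # type: ignore[arg-type]
        return cls(**data)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _as_date(x) -> _dt.date:
    if isinstance(x, _dt.date):
        return x
    return _dt.date.fromisoformat(str(x))


@dataclass
class GroundTruth:
    """Ledger of every planted error: affected rows and pre-error values.

    ``classes`` maps an error-class name to a DataFrame with columns
    ``row`` (0-based row index in the planted table), ``variable`` and
    ``true_value`` (empty string where the class has no single true value,
    e.g. clone rows record the full overwritten row in ``true_value`` as a
    dict).  Classes touching disjoint column groups may share rows; such
    overlaps are deliberate and flagged.
    """

    classes: dict[str, pd.DataFrame] = field(default_factory=dict)
    overlapping_classes: tuple[str, ...] = ()

    def affected(self, cls: str) -> list[int]:
        if cls not in self.classes or self.classes[cls].empty:
            return []
        return sorted(set(int(r) for r in self.classes[cls]["row"]))

    def count(self, cls: str) -> int:
        return len(self.affected(cls))

    @property
    def empty(self) -> bool:
        return all(df.empty for df in self.classes.values())

    def add(self, cls: str, rows, variable=None, true_value=None) -> None:
        rows = list(rows)
        df = pd.DataFrame(
            {
                "row": rows,
                "variable": variable if isinstance(variable, list) else [variable] * len(rows),
                "true_value": true_value if isinstance(true_value, list) else [true_value] * len(rows),
            }
        )
        if cls in self.classes:
            df = pd.concat([self.classes[cls], df], ignore_index=True)
        self.classes[cls] = df


@dataclass
class RelationalSource:
    """Five-table relational EHR source.

    ``visits`` reference patients; ``diagnoses`` reference visits; drug and
    measure events link to patients by (patient ID, date) only — the date-
    matching organisation whose mapping artifacts the quality checks are
    designed to expose.
    """

    patients: pd.DataFrame  # patient_id, birth_date, sex, death_date
    visits: pd.DataFrame  # visit_id, patient_id, arrival_date, discharge_date, department
    diagnoses: pd.DataFrame  # visit_id, icd9_code, history_flag
    drugs: pd.DataFrame  # patient_id, date, atc_code
    measures: pd.DataFrame  # patient_id, date, measure, value

    def check_integrity(self) -> None:
        dangling_v = set(self.visits["patient_id"]) - set(self.patients["patient_id"])
        if dangling_v:
            raise ValueError(f"visits reference unknown patients: {sorted(dangling_v)[:5]}")
        dangling_d = set(self.diagnoses["visit_id"]) - set(self.visits["visit_id"])
        if dangling_d:
            raise ValueError(f"diagnoses reference unknown visits: {sorted(dangling_d)[:5]}")
        for name in ("drugs", "measures"):
            tbl = getattr(self, name)
            dangling = set(tbl["patient_id"]) - set(self.patients["patient_id"])
            if dangling:
                raise ValueError(f"{name} reference unknown patients: {sorted(dangling)[:5]}")


# ---------------------------------------------------------------------------
# RNG plumbing: one named substream per stage, spawned in a fixed order
# ---------------------------------------------------------------------------

_STREAMS = (
    "demographics", "visits", "conditions", "flags", "medications",
    "measures", "death", "source_extra",
    "plant_same_day", "plant_duplicate_id", "plant_zero", "plant_oor_height",
    "plant_oor_weight", "plant_low_bmi", "plant_high_bmi", "plant_inversion",
    "plant_early_dates", "plant_history_flip",
    "inject_history", "inject_drugs",
)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _fmt(d: _dt.date) -> str:
    return d.strftime("%d/%m/%Y")


def _month_index(d: _dt.date, start: _dt.date) -> int:
    return (d.year - start.year) * 12 + (d.month - start.month)


# ---------------------------------------------------------------------------
# clean flat generation
# ---------------------------------------------------------------------------

def _day_weights(cfg: GeneratorConfig) -> np.ndarray:
    """Per-day sampling weight over the window: volume trend + thinned months."""
    start, end = cfg.window
    n_days = (end - start).days + 1
    dates = pd.date_range(start, end, freq="D")
    months = (dates.year - start.year) * 12 + (dates.month - start.month)
    weights = np.clip(1.0 + cfg.monthly_volume_slope * months.to_numpy(), 0.0, None)
    t0, t1 = cfg.thin_months
    thin = np.asarray((dates >= pd.Timestamp(t0)) & (dates <= pd.Timestamp(t1)))
    weights[thin] *= cfg.thin_factor
    assert len(weights) == n_days
    return weights / weights.sum()


def _sample_arrival_days(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Sample ``n`` distinct day offsets within the window, month-weighted."""
    n = min(n, len(weights))
    chosen = rng.choice(len(weights), size=n, replace=False, p=weights)
    return np.sort(chosen)


def generate_flat(config: GeneratorConfig) -> VisitTable:
    """Generate a pristine flat ICHOM visit table (before error planting).

    Every variable is fully documented: heights and weights are recorded at
    each visit, identifiers are unique, each patient's visits fall on
    distinct days, history flags follow ever-diagnosed semantics (subject to
    the configured recording regime shift), and the date of death is written
    exactly on the visit during which the patient died.
    """
    cfg = config
    rng = _streams(cfg.seed)
    start, _end = cfg.window
    shift_date, shift_mult = cfg.regime_shift

    r_dem = rng["demographics"]
    r_vis = rng["visits"]
    r_cond = rng["conditions"]
    r_flag = rng["flags"]
    r_med = rng["medications"]
    r_meas = rng["measures"]
    r_death = rng["death"]

    rows: list[dict] = []
    visit_counter = 0
    p_geo = 1.0 / max(cfg.mean_visits_per_patient, 1.0)
    weights = _day_weights(cfg)

    for p in range(cfg.n_patients):
        pid = f"P{p:06d}"
        n_visits = int(r_vis.geometric(p_geo))
        day_offsets = _sample_arrival_days(r_vis, weights, n_visits)
        arrivals = [start + _dt.timedelta(int(d)) for d in day_offsets]
        n_visits = len(arrivals)

        sex = 1 if r_dem.random() < cfg.male_fraction else 2
        age0 = r_dem.uniform(*cfg.age_range_years)
        birth = arrivals[0] - _dt.timedelta(days=int(age0 * 365.25) + int(r_dem.integers(0, 365)))

        height = int(np.clip(r_meas.normal(168, 9), 145, 200))
        bmi0 = float(np.clip(r_meas.normal(28, 5), 16, 48))
        weight0 = bmi0 * (height / 100.0) ** 2

        onsets: dict[str, Optional[int]] = {}
        for cond in _CONDITIONS:
            if r_cond.random() < cfg.condition_prevalence.get(cond, 0.0):
                onsets[cond] = int(r_cond.integers(0, n_visits))
            else:
                onsets[cond] = None

        # same-day appointment vs inpatient admission, and in-visit death
        death_at: Optional[int] = None
        for j in range(n_visits):
            if r_death.random() < cfg.death_probability_per_visit:
                death_at = j
                break
        if death_at is not None:
            arrivals = arrivals[: death_at + 1]
            n_visits = len(arrivals)

        discharges: list[_dt.date] = []
        for j, a in enumerate(arrivals):
            dies_here = death_at is not None and j == n_visits - 1
            if not dies_here and r_vis.random() < cfg.same_day_fraction:
                discharges.append(a)
            else:
                los = int(r_vis.geometric(0.25))  # mean 4-day stay
                discharges.append(a + _dt.timedelta(days=los))

        for j, (a, dch) in enumerate(zip(arrivals, discharges)):
            m = _month_index(a, start)
            record_p = 1.0 if a < shift_date else shift_mult
            row = {
                "Patient ID": pid,
                "Visit ID": f"V{visit_counter:07d}",
                "Age": _fmt(birth),
                "Sex": str(sex),
            }
            visit_counter += 1
            for cond in _CONDITIONS:
                onset = onsets[cond]
                has = onset is not None and j >= onset
                recorded = has and (record_p >= 1.0 or r_cond.random() < record_p)
                row[cond] = "1" if recorded else "0"
            for flag in _PER_VISIT_FLAGS:
                row[flag] = (
                    "1" if r_flag.random() < cfg.per_visit_flag_rates.get(flag, 0.0) else "0"
                )
            w = weight0 + r_meas.normal(0.0, 2.0)
            w = float(np.clip(w, 11.0 * (height / 100.0) ** 2, 68.0 * (height / 100.0) ** 2))
            w = min(w, height - 5.0)
            row["Height"] = str(height)
            row["Weight"] = str(int(round(w)))
            for med in _MEDICATIONS:
                pmed = cfg.medication_base.get(med, 0.0) + cfg.medication_trend.get(med, 0.0) * m
                row[med] = "1" if r_med.random() < min(max(pmed, 0.0), 0.95) else "0"
            # visits in the 365 days strictly before this arrival
            prior = [
                k for k in range(j) if 0 < (a - arrivals[k]).days <= 365
            ]
            row["Hospital admissions"] = str(
                sum(1 for k in prior if discharges[k] != arrivals[k])
            )
            row["Hospital appointments"] = str(
                sum(1 for k in prior if discharges[k] == arrivals[k])
            )
            row["Date of arrival"] = _fmt(a)
            row["Date of discharge"] = _fmt(dch)
            dies_here = death_at is not None and j == n_visits - 1
            row["Date of death"] = _fmt(dch) if dies_here else ""
            rows.append(row)

    dictionary = default_dictionary()
    raw = pd.DataFrame(rows, columns=dictionary.names)
    prov = Provenance(
        source=f"synthetic(seed={cfg.seed})",
        window_start=cfg.window[0],
        window_end=cfg.window[1],
    )
    return VisitTable(raw, dictionary, prov)


# ---------------------------------------------------------------------------
# error planting on the flat table
# ---------------------------------------------------------------------------

def _resolve_count(value: float | int, n: int, mode: str,
                   rng: np.random.Generator) -> int:
    """Turn a rate-or-count plan entry into a number of affected rows."""
    if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
        k, p = int(value), None
    elif 0.0 <= float(value) < 1.0:
        k, p = None, float(value)
    else:
        k, p = int(round(float(value))), None
    if mode == "exact_count":
        return k if k is not None else int(round(p * n))
    prob = p if p is not None else (k / n if n else 0.0)
    return int(rng.binomial(n, min(prob, 1.0)))


def _take(rng: np.random.Generator, pool: np.ndarray, k: int, cls: str,
          n: int) -> np.ndarray:
    """Select ``k`` rows from ``pool`` by per-row priority.

    A full-length priority vector is always drawn from the class's own
    substream, so the class's selection depends only on its own stream and
    the eligibility mask — disabling another class never perturbs the rows
    this class picks, beyond rows the two would have contended for.
    """
    priority = rng.random(n)
    if k > len(pool):
        raise ConfigError(
            f"error class {cls!r} requests {k} rows but only {len(pool)} are eligible"
        )
    order = np.argsort(priority[pool], kind="stable")
    return pool[order[:k]]


def plant_errors(
    table: VisitTable, config: GeneratorConfig
) -> tuple[VisitTable, GroundTruth]:
    """Plant the configured error classes into a clean flat table.

    Row count never changes: visit-ID collisions reassign an existing
    identifier and same-day clones overwrite one member of a sampled pair
    with the other's data.  Classes touching the same fields use disjoint
    row sets; the history-flip classes may share rows with the
    height/weight classes (different columns), which the ledger flags.
    Exact-count mode plants exactly the requested number per class; rate
    mode draws the affected number binomially.
    """
    cfg = config
    plan = cfg.errors
    rng = _streams(cfg.seed)
    raw = table.raw.copy()
    n = len(raw)
    truth = GroundTruth(overlapping_classes=("history_flip", "zero_height_weight"))

    frozen = np.zeros(n, dtype=bool)  # rows no later class may touch
    hw_used = np.zeros(n, dtype=bool)  # rows already claimed by a height/weight class
    other_cols = [c for c in raw.columns if c != "Visit ID"]

    def free_rows() -> np.ndarray:
        return np.flatnonzero(~frozen)

    def hw_pool() -> np.ndarray:
        return np.flatnonzero(~frozen & ~hw_used)

    # 1. same-day clones: overwrite B (and C) with A's data, keeping their IDs
    r = rng["plant_same_day"]
    k = _resolve_count(plan.same_day_duplicate, n, cfg.mode, r)
    if k == 1:
        raise ConfigError("same_day_duplicate needs at least 2 affected rows")
    if k:
        rows = _take(r, free_rows(), k, "same_day_duplicate", n)
        groups = _pair_up(rows)
        affected, originals = [], []
        for grp in groups:
            a, rest = grp[0], grp[1:]
            affected.append(a)
            originals.append(None)  # the template row keeps its own values
            for b in rest:
                affected.append(b)
                originals.append(dict(raw.loc[b]))
                keep_id = raw.at[b, "Visit ID"]
                raw.loc[b] = raw.loc[a]
                raw.at[b, "Visit ID"] = keep_id
        truth.add("same_day_duplicate", affected, true_value=originals)
        frozen[rows] = True

    # 2. visit-ID collisions: B adopts A's visit ID, other fields untouched
    r = rng["plant_duplicate_id"]
    k = _resolve_count(plan.duplicate_id, n, cfg.mode, r)
    if k == 1:
        raise ConfigError("duplicate_id needs at least 2 affected rows")
    if k:
        rows = _take(r, free_rows(), k, "duplicate_id", n)
        groups = _pair_up(rows)
        affected, olds = [], []
        for grp in groups:
            a = grp[0]
            affected.append(a)
            olds.append(None)  # the template row keeps its own ID
            for b in grp[1:]:
                affected.append(b)
                olds.append(raw.at[b, "Visit ID"])
                raw.at[b, "Visit ID"] = raw.at[a, "Visit ID"]
                # collision members must differ somewhere outside the ID
                if tuple(raw.loc[b, other_cols]) == tuple(raw.loc[a, other_cols]):
                    raw.at[b, "Weight"] = str(int(float(raw.at[b, "Weight"] or 0)) + 1)
        truth.add("duplicate_id", affected, variable="Visit ID", true_value=olds)
        frozen[rows] = True

    # 3. zero-coded height/weight (extraction artifact for missing measures)
    r = rng["plant_zero"]
    k = _resolve_count(plan.zero_height_weight, n, cfg.mode, r)
    if k:
        rows = np.sort(_take(r, hw_pool(), k, "zero_height_weight", n))
        truth.add("zero_height_weight", list(rows), variable="Height",
                  true_value=list(raw.loc[rows, "Height"]))
        truth.add("zero_height_weight", list(rows), variable="Weight",
                  true_value=list(raw.loc[rows, "Weight"]))
        raw.loc[rows, ["Height", "Weight"]] = "0"
        hw_used[rows] = True

    # 4. out-of-range heights (implausibly tall, BMI kept plausible)
    r = rng["plant_oor_height"]
    k = _resolve_count(plan.out_of_range_height, n, cfg.mode, r)
    if k:
        rows = np.sort(_take(r, hw_pool(), k, "out_of_range_height", n))
        truth.add("out_of_range_height", list(rows), variable="Height",
                  true_value=list(raw.loc[rows, "Height"]))
        for i in rows:
            h = int(r.integers(255, 301))
            raw.at[i, "Height"] = str(h)
            raw.at[i, "Weight"] = str(int(round(22.0 * (h / 100.0) ** 2)))
        hw_used[rows] = True

    # 5. out-of-range weights (implausibly light, BMI kept plausible)
    r = rng["plant_oor_weight"]
    k = _resolve_count(plan.out_of_range_weight, n, cfg.mode, r)
    if k:
        rows = np.sort(_take(r, hw_pool(), k, "out_of_range_weight", n))
        truth.add("out_of_range_weight", list(rows), variable="Weight",
                  true_value=list(raw.loc[rows, "Weight"]))
        for i in rows:
            h = int(r.integers(100, 121))
            wmin = int(np.ceil(10.5 * (h / 100.0) ** 2))
            w = int(r.integers(wmin, 19))
            raw.at[i, "Height"] = str(h)
            raw.at[i, "Weight"] = str(w)
        hw_used[rows] = True

    # 6. suspiciously low BMI (height and weight individually in range)
    r = rng["plant_low_bmi"]
    k = _resolve_count(plan.low_bmi, n, cfg.mode, r)
    if k:
        rows = np.sort(_take(r, hw_pool(), k, "low_bmi", n))
        for i in rows:
            h = int(r.integers(180, 211))
            t = r.uniform(7.0, 9.5)
            raw.at[i, "Height"] = str(h)
            raw.at[i, "Weight"] = str(int(round(t * (h / 100.0) ** 2)))
        truth.add("low_bmi", list(rows))
        hw_used[rows] = True

    # 7. implausibly high BMI (weight exceeds height: below-diagonal points)
    r = rng["plant_high_bmi"]
    k = _resolve_count(plan.high_bmi, n, cfg.mode, r)
    if k:
        rows = np.sort(_take(r, hw_pool(), k, "high_bmi", n))
        for i in rows:
            h = int(r.integers(150, 181))
            tmax = min(120.0, 345.0 / (h / 100.0) ** 2)
            t = r.uniform(75.0, tmax)
            raw.at[i, "Height"] = str(h)
            raw.at[i, "Weight"] = str(int(round(t * (h / 100.0) ** 2)))
        truth.add("high_bmi", list(rows))
        hw_used[rows] = True

    # 8. value inversion between height and weight
    r = rng["plant_inversion"]
    k = _resolve_count(plan.hw_inversion, n, cfg.mode, r)
    if k:
        rows = np.sort(_take(r, hw_pool(), k, "hw_inversion", n))
        for i in rows:
            h, w = raw.at[i, "Height"], raw.at[i, "Weight"]
            raw.at[i, "Height"], raw.at[i, "Weight"] = w, h
        truth.add("hw_inversion", list(rows))
        hw_used[rows] = True

    # 9. arrival dates before the extraction window
    r = rng["plant_early_dates"]
    k = _resolve_count(plan.early_arrival_dates, n, cfg.mode, r)
    if k:
        # moving a record to the front of a patient's timeline must not
        # fabricate temporal-order violations, so only rows without any
        # recorded condition history are eligible
        no_history = (raw[list(_CONDITIONS)] == "0").all(axis=1).to_numpy()
        rows = np.sort(_take(r, np.flatnonzero(~frozen & no_history), k,
                             "early_arrival_dates", n))
        truth.add("early_arrival_dates", list(rows), variable="Date of arrival",
                  true_value=list(raw.loc[rows, "Date of arrival"]))
        start = cfg.window[0]
        span = (start - _dt.date(1998, 1, 1)).days
        for i in rows:
            early = start - _dt.timedelta(days=int(r.integers(1, span)))
            raw.at[i, "Date of arrival"] = _fmt(early)
        frozen[rows] = True

    # 10. history-flag flips: a recorded history later reported as absent
    r = rng["plant_history_flip"]
    for cond in _CONDITIONS:
        # one fixed-size priority draw per condition keeps conditions on
        # independent slices of the substream whatever their rates are
        priority = r.random(n)
        rate = (plan.history_flip or {}).get(cond, 0.0)
        if not rate:
            continue
        # flip rates are relative to the flippable (eligible) records: rows
        # carrying a 1 that is not the patient's earliest recorded history
        eligible = _flip_eligible(raw, cond, frozen)
        k = _resolve_count(rate, len(eligible), cfg.mode, r)
        if not k:
            continue
        if k > len(eligible):
            raise ConfigError(
                f"error class 'history_flip[{cond}]' requests {k} rows but "
                f"only {len(eligible)} are eligible"
            )
        order = np.argsort(priority[eligible], kind="stable")
        rows = np.sort(eligible[order[:k]])
        truth.add(f"history_flip[{cond}]", list(rows), variable=cond, true_value="1")
        raw.loc[rows, cond] = "0"

    planted = table.with_raw(raw)
    return planted, truth


def _pair_up(rows: np.ndarray) -> list[list[int]]:
    """Split sampled rows into pairs (plus one triple when the count is odd)."""
    rows = [int(x) for x in rows]
    if len(rows) % 2 == 1:
        head, rows = rows[:3], rows[3:]
        groups = [head]
    else:
        groups = []
    groups.extend([rows[i:i + 2] for i in range(0, len(rows), 2)])
    return [g for g in groups if g]


def _flip_eligible(raw: pd.DataFrame, cond: str, frozen: np.ndarray) -> np.ndarray:
    """Rows whose flag may flip 1→0 and leave an earlier recorded 1 standing.

    Eligible rows carry a 1 that is not the patient's earliest 1 for the
    condition (ordered by arrival date, ties by visit ID), so the patient's
    first recorded history always survives and each flip yields exactly one
    temporal-order violation.
    """
    arrival = pd.to_datetime(raw["Date of arrival"], format="%d/%m/%Y", errors="coerce")
    iso = arrival.isna() & (raw["Date of arrival"] != "")
    if iso.any():
        arrival[iso] = pd.to_datetime(raw.loc[iso, "Date of arrival"],
                                      format="%Y-%m-%d", errors="coerce")
    df = pd.DataFrame(
        {
            "patient": raw["Patient ID"],
            "arrival": arrival,
            "vid": raw["Visit ID"],
            "one": (raw[cond] == "1").astype(int),
        }
    )
    sdf = df.sort_values(["patient", "arrival", "vid"], kind="mergesort")
    ones = sdf[sdf["one"] == 1]
    first_one = ones.groupby("patient", sort=False).head(1).index
    eligible_mask = df["one"].astype(bool)
    eligible_mask[first_one] = False
    eligible_mask &= ~frozen
    eligible_mask &= arrival.notna()
    return np.flatnonzero(eligible_mask.to_numpy())


# ---------------------------------------------------------------------------
# relational source generation
# ---------------------------------------------------------------------------

def generate_source(config: GeneratorConfig) -> tuple[RelationalSource, GroundTruth]:
    """Generate a small relational EHR source for the heart-failure cohort.

    Every patient carries at least one heart-failure ICD-9 diagnosis (the
    cohort criterion).  Dates are ISO strings.  A fraction of visits spawn
    a second same-day visit in another department sharing the same episode
    dates — the structure whose date-matching join produces same-day
    duplicate rows downstream — and a fraction of measured dates carry two
    differing weight measurements, the mechanism behind visit-ID collision
    duplicates.  Both structures are recorded in the ground-truth ledger
    (``same_day_visits`` and ``duplicate_measures``, keyed by visit ID and
    (patient ID, date) respectively).
    """
    cfg = config
    rng = _streams(cfg.seed)
    start, _end = cfg.window
    hf_codes = sorted(hf_icd9_codes().codes)

    r_dem = rng["demographics"]
    r_vis = rng["visits"]
    r_cond = rng["conditions"]
    r_flag = rng["flags"]
    r_med = rng["medications"]
    r_meas = rng["measures"]
    r_death = rng["death"]
    r_extra = rng["source_extra"]

    patients_rows = []
    visits_rows = []
    diag_rows = []
    drug_rows = []
    measure_rows = []
    truth = GroundTruth()
    same_day_pairs: list[str] = []
    dup_measures: list[str] = []

    visit_counter = 0
    p_geo = 1.0 / max(cfg.mean_visits_per_patient, 1.0)
    weights = _day_weights(cfg)

    for p in range(cfg.n_patients):
        pid = f"P{p:06d}"
        n_visits = int(r_vis.geometric(p_geo))
        day_offsets = _sample_arrival_days(r_vis, weights, n_visits)
        arrivals = [start + _dt.timedelta(int(d)) for d in day_offsets]
        n_visits = len(arrivals)

        sex = 1 if r_dem.random() < cfg.male_fraction else 2
        age0 = r_dem.uniform(*cfg.age_range_years)
        birth = arrivals[0] - _dt.timedelta(
            days=int(age0 * 365.25) + int(r_dem.integers(0, 365))
        )
        height = int(np.clip(r_meas.normal(168, 9), 145, 200))
        bmi0 = float(np.clip(r_meas.normal(28, 5), 16, 48))

        death_at = None
        for j in range(n_visits):
            if r_death.random() < cfg.death_probability_per_visit:
                death_at = j
                break
        if death_at is not None:
            arrivals = arrivals[: death_at + 1]
            n_visits = len(arrivals)

        onsets = {}
        for cond in _CONDITIONS:
            if r_cond.random() < cfg.condition_prevalence.get(cond, 0.0):
                onsets[cond] = int(r_cond.integers(0, n_visits))
            else:
                onsets[cond] = None
        hf_at = int(r_cond.integers(0, n_visits))

        death_date = None
        for j, a in enumerate(arrivals):
            vid = f"V{visit_counter:07d}"
            visit_counter += 1
            dies_here = death_at is not None and j == n_visits - 1
            if not dies_here and r_vis.random() < cfg.same_day_fraction:
                dch = a
            else:
                dch = a + _dt.timedelta(days=int(r_vis.geometric(0.25)))
            if dies_here:
                death_date = dch
            dept = _DEPARTMENTS[int(r_vis.integers(0, len(_DEPARTMENTS)))]
            visits_rows.append(
                dict(visit_id=vid, patient_id=pid, arrival_date=a.isoformat(),
                     discharge_date=dch.isoformat(), department=dept)
            )
            this_day_vids = [vid]
            if not dies_here and r_extra.random() < cfg.same_day_visit_rate:
                vid2 = f"V{visit_counter:07d}"
                visit_counter += 1
                dept2 = _DEPARTMENTS[
                    (_DEPARTMENTS.index(dept) + 1) % len(_DEPARTMENTS)
                ]
                visits_rows.append(
                    dict(visit_id=vid2, patient_id=pid, arrival_date=a.isoformat(),
                         discharge_date=dch.isoformat(), department=dept2)
                )
                same_day_pairs.extend([vid, vid2])
                this_day_vids.append(vid2)

            # diagnoses attach to the first visit of the day
            if j == hf_at or (j == n_visits - 1 and hf_at >= n_visits):
                diag_rows.append(
                    dict(visit_id=vid,
                         icd9_code=hf_codes[int(r_cond.integers(0, len(hf_codes)))],
                         history_flag=0)
                )
            for cond in _CONDITIONS:
                onset = onsets[cond]
                if onset is not None and j >= onset:
                    diag_rows.append(
                        dict(visit_id=vid, icd9_code=DEFAULT_CONDITION_CODES[cond],
                             history_flag=0 if j == onset else 1)
                    )
            for flag, code in DEFAULT_FLAG_CODES.items():
                if r_flag.random() < cfg.per_visit_flag_rates.get(flag, 0.0):
                    diag_rows.append(dict(visit_id=vid, icd9_code=code, history_flag=0))

            for med, atc in DEFAULT_ATC_CODES.items():
                if r_med.random() < cfg.medication_base.get(med, 0.0):
                    drug_rows.append(
                        dict(patient_id=pid, date=a.isoformat(), atc_code=atc)
                    )

            if r_meas.random() < cfg.measure_rate:
                w = bmi0 * (height / 100.0) ** 2 + r_meas.normal(0.0, 2.0)
                w = float(np.clip(w, 11.0 * (height / 100.0) ** 2,
                                  68.0 * (height / 100.0) ** 2))
                w = min(w, height - 5.0)
                measure_rows.append(
                    dict(patient_id=pid, date=a.isoformat(), measure="height",
                         value=float(height))
                )
                measure_rows.append(
                    dict(patient_id=pid, date=a.isoformat(), measure="weight",
                         value=float(int(round(w))))
                )
                if r_extra.random() < cfg.duplicate_measure_rate:
                    w2 = float(int(round(w))) + float(r_extra.integers(1, 4))
                    measure_rows.append(
                        dict(patient_id=pid, date=a.isoformat(), measure="weight",
                             value=w2)
                    )
                    dup_measures.append(f"{pid}@{a.isoformat()}")

        patients_rows.append(
            dict(patient_id=pid, birth_date=birth.isoformat(), sex=sex,
                 death_date=death_date.isoformat() if death_date else "")
        )

    source = RelationalSource(
        patients=pd.DataFrame(patients_rows),
        visits=pd.DataFrame(visits_rows),
        diagnoses=pd.DataFrame(diag_rows),
        drugs=pd.DataFrame(drug_rows),
        measures=pd.DataFrame(measure_rows),
    )
    if same_day_pairs:
        truth.add("same_day_visits", range(len(same_day_pairs)),
                  variable="visit_id", true_value=list(same_day_pairs))
    if dup_measures:
        truth.add("duplicate_measures", range(len(dup_measures)),
                  variable="patient_date", true_value=dup_measures)
    return source, truth


def inject_temporal_patterns(
    source: RelationalSource, config: GeneratorConfig
) -> RelationalSource:
    """Impose the documentation regime shift and medication trends on a source.

    History-of-condition diagnosis rows dated on or after the shift date
    are kept with probability equal to the configured multiplier (a
    multiplier of 1, or a shift date outside the window, leaves the source
    unchanged).  Per-drug recording probability follows the configured
    monthly slope: rows are added (positive slope) or thinned (negative)
    so the expected per-visit-date frequency tracks
    ``base + slope * months_elapsed``.
    """
    cfg = config
    rng = _streams(cfg.seed)
    r_hist = rng["inject_history"]
    r_drug = rng["inject_drugs"]
    start, end = cfg.window
    shift_date, mult = cfg.regime_shift

    diagnoses = source.diagnoses
    if mult < 1.0 and start <= shift_date <= end and len(diagnoses):
        arrival_by_vid = source.visits.set_index("visit_id")["arrival_date"]
        arr = diagnoses["visit_id"].map(arrival_by_vid)
        is_history = diagnoses["history_flag"] == 1
        after = arr >= shift_date.isoformat()
        candidates = (is_history & after).to_numpy()
        keep = ~candidates | (r_hist.random(len(diagnoses)) < mult)
        diagnoses = diagnoses.loc[keep].reset_index(drop=True)

    drugs = source.drugs
    trends = {m: s for m, s in (cfg.medication_trend or {}).items() if s}
    if trends and len(source.visits):
        visit_dates = (
            source.visits[["patient_id", "arrival_date"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )
        months = visit_dates["arrival_date"].map(
            lambda d: _month_index(_dt.date.fromisoformat(d), start)
        )
        new_rows = []
        keep_mask = np.ones(len(drugs), dtype=bool)
        for med, slope in trends.items():
            atc = DEFAULT_ATC_CODES[med]
            base = cfg.medication_base.get(med, 0.0)
            target = np.clip(base + slope * months.to_numpy(), 0.0, 0.95)
            have = set(
                zip(drugs.loc[drugs["atc_code"] == atc, "patient_id"],
                    drugs.loc[drugs["atc_code"] == atc, "date"])
            )
            has_row = np.array(
                [(p, d) in have for p, d in
                 zip(visit_dates["patient_id"], visit_dates["arrival_date"])]
            )
            if slope > 0:
                # add rows where the target exceeds the base rate
                p_add = np.where(~has_row & (base < 1.0),
                                 np.clip((target - base) / max(1.0 - base, 1e-12), 0, 1),
                                 0.0)
                add = r_drug.random(len(visit_dates)) < p_add
                for _, row in visit_dates[add].iterrows():
                    new_rows.append(
                        dict(patient_id=row["patient_id"], date=row["arrival_date"],
                             atc_code=atc)
                    )
            else:
                # thin rows where the target falls below the base rate
                p_keep = np.clip(np.where(base > 0, target / max(base, 1e-12), 0.0),
                                 0, 1)
                keymap = {
                    (p, d): pk for p, d, pk in
                    zip(visit_dates["patient_id"], visit_dates["arrival_date"],
                        p_keep)
                }
                is_med = (drugs["atc_code"] == atc).to_numpy()
                u = r_drug.random(len(drugs))
                for i in np.flatnonzero(is_med):
                    pk = keymap.get((drugs.iloc[i]["patient_id"], drugs.iloc[i]["date"]),
                                    1.0)
                    if u[i] >= pk:
                        keep_mask[i] = False
        drugs = drugs.loc[keep_mask]
        if new_rows:
            drugs = pd.concat([drugs, pd.DataFrame(new_rows)], ignore_index=True)
        drugs = drugs.sort_values(["patient_id", "date", "atc_code"],
                                  kind="mergesort").reset_index(drop=True)

    return RelationalSource(
        patients=source.patients,
        visits=source.visits,
        diagnoses=diagnoses,
        drugs=drugs,
        measures=source.measures,
    )
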