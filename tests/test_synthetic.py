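import dataclasses

import numpy as np
import pytest

from ichomdq import (
    ErrorPlan,
    GeneratorConfig,
    generate_flat,
    generate_source,
    inject_temporal_patterns,
    plant_errors,
)
from ichomdq.dictionary import hf_icd9_codes
from ichomdq.synthetic import ConfigError

import oracles


def cfg_small(**kw):
    base = dict(n_patients=120, mean_visits_per_patient=5.0, seed=42)
    base.update(kw)
    return GeneratorConfig(**base)


SMALL_PLAN = ErrorPlan(
    duplicate_id=12, same_day_duplicate=10, zero_height_weight=0.4,
    out_of_range_height=5, out_of_range_weight=4, early_arrival_dates=3,
    hw_inversion=2, low_bmi=3, high_bmi=6,
    history_flip={"Hypertension": 8, "Atrial fibrillation": 5},
)


class TestDeterminism:
    def test_same_config_same_flat_table(self):
        cfg = cfg_small(errors=SMALL_PLAN)
        t1, g1 = plant_errors(generate_flat(cfg), cfg)
        t2, g2 = plant_errors(generate_flat(cfg), cfg)
        assert t1.raw.equals(t2.raw)
        for cls in g1.classes:
            assert g1.classes[cls].equals(g2.classes[cls])

    def test_different_seed_differs(self):
        t1 = generate_flat(cfg_small(seed=1))
        t2 = generate_flat(cfg_small(seed=2))
        assert not t1.raw.equals(t2.raw)

    def test_disabling_one_class_leaves_others_untouched(self):
        """Class-local substreams: zeroing one class must not move the rest."""
        cfg_a = cfg_small(errors=SMALL_PLAN)
        cfg_b = cfg_small(errors=dataclasses.replace(SMALL_PLAN, low_bmi=0))
        _, ga = plant_errors(generate_flat(cfg_a), cfg_a)
        _, gb = plant_errors(generate_flat(cfg_b), cfg_b)
        for cls in gb.classes:
            assert ga.affected(cls) == gb.affected(cls)
        assert gb.count("low_bmi") == 0
        assert ga.count("low_bmi") == 3

    def test_same_config_same_source(self):
        cfg = cfg_small()
        s1, _ = generate_source(cfg)
        s2, _ = generate_source(cfg)
        for name in ("patients", "visits", "diagnoses", "drugs", "measures"):
            assert getattr(s1, name).equals(getattr(s2, name))


class TestCleanGeneration:
    def test_expected_scale(self):
        cfg = GeneratorConfig(n_patients=100, mean_visits_per_patient=3.0, seed=7)
        table = generate_flat(cfg.clean())
        # geometric visit counts, truncated by in-visit deaths
        assert 150 <= len(table) <= 450
        assert table.raw["Patient ID"].nunique() == 100

    def test_identifiers_unique_and_days_distinct(self):
        table = generate_flat(cfg_small().clean())
        assert table.raw["Visit ID"].is_unique
        assert not table.raw.duplicated(["Patient ID", "Date of arrival"]).any()

    def test_death_date_only_on_death_visit(self):
        table = generate_flat(cfg_small().clean())
        death = table.raw["Date of death"]
        recorded = death != ""
        assert recorded.any()
        assert (death[recorded] == table.raw.loc[recorded, "Date of discharge"]).all()

    def test_history_flags_monotone_when_clean(self):
        table = generate_flat(cfg_small().clean())
        for cond in ("Hypertension", "Diabetes mellitus"):
            assert oracles.brute_history_order(table.raw, cond) == []


class TestPlantErrors:
    def test_empty_plan_empty_ledger_identical_table(self):
        cfg = cfg_small(errors=ErrorPlan.none())
        clean = generate_flat(cfg)
        planted, truth = plant_errors(clean, cfg)
        assert truth.empty
        assert planted.raw.equals(clean.raw)

    def test_exact_counts_and_row_conservation(self):
        cfg = cfg_small(errors=SMALL_PLAN)
        clean = generate_flat(cfg)
        planted, truth = plant_errors(clean, cfg)
        assert len(planted) == len(clean)
        assert truth.count("duplicate_id") == 12
        assert truth.count("same_day_duplicate") == 10
        assert truth.count("out_of_range_height") == 5
        assert truth.count("out_of_range_weight") == 4
        assert truth.count("early_arrival_dates") == 3
        assert truth.count("zero_height_weight") == round(0.4 * len(clean))
        assert truth.count("history_flip[Hypertension]") == 8

    def test_inversion_swaps_fields(self):
        cfg = cfg_small(errors=ErrorPlan(0, 0, 0, 0, 0, 0, hw_inversion=4,
                                         low_bmi=0, high_bmi=0, history_flip={}))
        clean = generate_flat(cfg)
        planted, truth = plant_errors(clean, cfg)
        for i in truth.affected("hw_inversion"):
            assert planted.raw.at[i, "Height"] == clean.raw.at[i, "Weight"]
            assert planted.raw.at[i, "Weight"] == clean.raw.at[i, "Height"]

    def test_ledger_fidelity_brute_rescan(self):
        """An independent scan of the planted table recovers the ledger sets."""
        cfg = cfg_small(errors=SMALL_PLAN)
        clean = generate_flat(cfg)
        planted, truth = plant_errors(clean, cfg)
        raw, old = planted.raw, clean.raw
        zero = set(np.flatnonzero((raw["Height"] == "0") & (raw["Weight"] == "0")))
        assert zero == set(truth.affected("zero_height_weight"))
        changed_id = set(np.flatnonzero(raw["Visit ID"] != old["Visit ID"]))
        planted_id = set(truth.affected("duplicate_id"))
        assert changed_id <= planted_id  # templates keep their IDs
        assert oracles.brute_uniqueness1(raw) == len(planted_id)
        assert oracles.brute_uniqueness2(raw) == truth.count("same_day_duplicate")
        early = set(
            np.flatnonzero(raw["Date of arrival"].str[-4:].astype(int) < 2006)
        )
        assert early == set(truth.affected("early_arrival_dates"))
        # clone rows legitimately rewrite flag columns, so exclude them
        clones = set(truth.affected("same_day_duplicate"))
        flips = set(np.flatnonzero((raw["Hypertension"] == "0")
                                   & (old["Hypertension"] == "1"))) - clones
        assert flips == set(truth.affected("history_flip[Hypertension]"))

    def test_rate_mode_zero_fraction_within_binomial_error(self):
        cfg = GeneratorConfig(
            n_patients=1200, seed=9, mode="rate",
            errors=ErrorPlan(0, 0, zero_height_weight=0.85, out_of_range_height=0,
                             out_of_range_weight=0, early_arrival_dates=0,
                             hw_inversion=0, low_bmi=0, high_bmi=0, history_flip={}),
        )
        clean = generate_flat(cfg.clean() if False else cfg)
        planted, _ = plant_errors(clean, cfg)
        n = len(planted)
        frac = (planted.raw["Height"] == "0").mean()
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(frac - 0.85) < 3 * se

    def test_infeasible_exact_count_rejected(self):
        cfg = cfg_small(errors=ErrorPlan(0, 0, 0, out_of_range_height=10 ** 6,
                                         out_of_range_weight=0, early_arrival_dates=0,
                                         hw_inversion=0, low_bmi=0, high_bmi=0,
                                         history_flip={}))
        with pytest.raises(ConfigError):
            plant_errors(generate_flat(cfg), cfg)


class TestRelationalSource:
    def test_every_patient_hf_coded(self):
        source, _ = generate_source(cfg_small())
        source.check_integrity()
        hf = hf_icd9_codes()
        diag = source.diagnoses.merge(source.visits, on="visit_id")
        coded = set(diag.loc[diag["icd9_code"].map(hf.matches), "patient_id"])
        assert coded == set(source.patients["patient_id"])

    def test_visit_dates_inside_window(self):
        cfg = cfg_small()
        source, _ = generate_source(cfg)
        arr = source.visits["arrival_date"]
        assert (arr >= cfg.window[0].isoformat()).all()
        assert (arr <= cfg.window[1].isoformat()).all()

    def test_same_day_visits_recorded_in_ledger(self):
        cfg = cfg_small(same_day_visit_rate=0.2)
        source, truth = generate_source(cfg)
        pairs = truth.classes["same_day_visits"]["true_value"]
        vis = source.visits.set_index("visit_id")
        ids = list(pairs)
        for a, b in zip(ids[::2], ids[1::2]):
            assert vis.at[a, "patient_id"] == vis.at[b, "patient_id"]
            assert vis.at[a, "arrival_date"] == vis.at[b, "arrival_date"]
            assert vis.at[a, "department"] != vis.at[b, "department"]


class TestInjectTemporalPatterns:
    def test_history_regime_shift_ratio(self):
        """Post-shift history-row frequency falls to about the multiplier."""
        cfg = GeneratorConfig(
            n_patients=800, seed=13, regime_shift=(np.datetime64("2011-01-01").item(), 0.3),
            medication_trend={},
        )
        source, _ = generate_source(cfg)
        shifted = inject_temporal_patterns(source, cfg)

        def monthly_history_rate(src):
            diag = src.diagnoses.merge(src.visits, on="visit_id")
            hist = diag[diag["history_flag"] == 1]
            per_visit = hist.groupby("visit_id").size()
            vis = src.visits.set_index("visit_id")
            month = vis.loc[per_visit.index, "arrival_date"].str[:7]
            all_month = vis["arrival_date"].str[:7]
            num = per_visit.groupby(month.values).sum()
            den = all_month.value_counts()
            return (num / den).dropna()

        rate = monthly_history_rate(shifted)
        base = monthly_history_rate(source)
        pre = rate[rate.index < "2011-01"].mean() / base[base.index < "2011-01"].mean()
        post = rate[rate.index >= "2011-01"].mean() / base[base.index >= "2011-01"].mean()
        assert pre == pytest.approx(1.0, abs=0.02)
        assert post == pytest.approx(0.3, abs=0.06)

    def test_shift_outside_window_is_identity_for_history(self):
        cfg = cfg_small(regime_shift=(np.datetime64("2030-01-01").item(), 0.3),
                        medication_trend={})
        source, _ = generate_source(cfg)
        shifted = inject_temporal_patterns(source, cfg)
        assert shifted.diagnoses.equals(source.diagnoses)

    def test_zero_slopes_leave_drugs_unchanged(self):
        cfg = cfg_small(medication_trend={m: 0.0 for m in
                                          ("Beta blocker", "Diuretics")},
                        regime_shift=(np.datetime64("2011-01-01").item(), 1.0))
        source, _ = generate_source(cfg)
        shifted = inject_temporal_patterns(source, cfg)
        assert shifted.drugs.equals(source.drugs)

    def test_positive_slope_increases_late_drug_frequency(self):
        cfg = GeneratorConfig(
            n_patients=500, seed=21,
            medication_trend={"Beta blocker": 0.004},
            regime_shift=(np.datetime64("2011-01-01").item(), 1.0),
        )
        source, _ = generate_source(cfg)
        shifted = inject_temporal_patterns(source, cfg)
        bb = shifted.drugs[shifted.drugs["atc_code"].str.startswith("C07")]
        years = bb["date"].str[:4].astype(int)
        vis_years = shifted.visits["arrival_date"].str[:4].astype(int)
        early = (years <= 2008).sum() / max((vis_years <= 2008).sum(), 1)
        late = (years >= 2015).sum() / max((vis_years >= 2015).sum(), 1)
        assert late > 2 * early
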