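import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ichomdq import (
    ErrorPlan,
    GeneratorConfig,
    completeness,
    consistency_by_range,
    consistency_by_rules,
    consistency_by_type,
    consistency_overall,
    generate_flat,
    plant_errors,
    uniqueness_result1,
    uniqueness_result2,
)
from ichomdq.dictionary import default_dictionary
from ichomdq.result import round_half_up
from ichomdq.structural import Rule
from ichomdq.table import VisitTable

import oracles
from conftest import ROW_TEMPLATE, WINDOW, build_table


def random_messy_table(rng, n_rows):
    """A random small table with duplicates, junk, gaps and odd codes."""
    dictionary = default_dictionary()
    rows = []
    for i in range(n_rows):
        if rows and rng.random() < 0.15:
            # replay an earlier row, sometimes with a twist
            src = dict(rows[int(rng.integers(0, len(rows)))])
            if rng.random() < 0.5:
                src["Visit ID"] = f"V{int(rng.integers(0, n_rows)):03d}"
            if rng.random() < 0.5:
                src["Weight"] = str(int(rng.integers(40, 120)))
            rows.append(src)
            continue
        row = dict(ROW_TEMPLATE)
        row["Patient ID"] = f"P{int(rng.integers(0, max(2, n_rows // 4))):03d}"
        row["Visit ID"] = f"V{int(rng.integers(0, n_rows)):03d}"
        d = dt.date(2006, 1, 1) + dt.timedelta(days=int(rng.integers(-200, 4200)))
        row["Date of arrival"] = d.strftime("%d/%m/%Y")
        row["Date of discharge"] = (
            d + dt.timedelta(days=int(rng.integers(-2, 10)))
        ).strftime("%d/%m/%Y")
        for name, pool in {
            "Sex": ["1", "2", "3", ""],
            "Hypertension": ["0", "1", "999", "x", ""],
            "Atrial fibrillation": ["0", "1", "999"],
            "Height": ["0", "170", "abc", "", "300", "12.5"],
            "Weight": ["0", "65", "", "500", "oops"],
            "Hospital admissions": ["0", "3", "-1", "999", "2.5", ""],
            "Date of death": ["", "", "999", "31/12/2010", "junk"],
        }.items():
            row[name] = pool[int(rng.integers(0, len(pool)))]
        rows.append(row)
    raw = pd.DataFrame(rows, columns=dictionary.names)
    from ichomdq.table import Provenance

    return VisitTable(raw, dictionary,
                      Provenance("random", WINDOW[0], WINDOW[1]))


class TestUniqueness:
    def test_clean_table_scores_100(self, make_table):
        table = make_table([{}, {}, {}])
        assert uniqueness_result1(table).score == 100.0
        assert uniqueness_result2(table).score == 100.0

    def test_id_collision_counts_both_members(self, make_table):
        table = make_table([
            {"Visit ID": "V1", "Weight": "65"},
            {"Visit ID": "V1", "Weight": "70"},
            {"Visit ID": "V2"},
        ])
        res = uniqueness_result1(table)
        assert (res.numerator, res.denominator) == (2, 3)

    def test_exact_full_duplicates_excluded_from_result1(self, make_table):
        table = make_table([
            {"Visit ID": "V1", "Patient ID": "P1"},
            {"Visit ID": "V1", "Patient ID": "P1"},
        ])
        res = uniqueness_result1(table)
        assert res.numerator == 0
        assert res.extra["exact_duplicate_rows"] == 2

    def test_same_day_clone_counts_both_members(self, make_table):
        clone = {"Patient ID": "P9", "Date of arrival": "02/02/2010"}
        table = make_table([
            dict(clone, **{"Visit ID": "VA"}),
            dict(clone, **{"Visit ID": "VB"}),
            {"Visit ID": "VC"},
        ])
        res = uniqueness_result2(table)
        assert (res.numerator, res.denominator) == (2, 3)

    def test_same_day_pair_differing_clinically_not_counted(self, make_table):
        base = {"Patient ID": "P9", "Date of arrival": "02/02/2010"}
        table = make_table([
            dict(base, **{"Visit ID": "VA", "Smoking status": "0"}),
            dict(base, **{"Visit ID": "VB", "Smoking status": "1"}),
        ])
        assert uniqueness_result2(table).numerator == 0

    def test_planted_1000_row_example(self):
        cfg = GeneratorConfig(
            n_patients=170, mean_visits_per_patient=8.0, seed=3,
            errors=ErrorPlan(duplicate_id=12, same_day_duplicate=0,
                             zero_height_weight=0, out_of_range_height=0,
                             out_of_range_weight=0, early_arrival_dates=0,
                             hw_inversion=0, low_bmi=0, high_bmi=0,
                             history_flip={}),
        )
        clean = generate_flat(cfg.clean())
        table = clean.with_raw(clean.raw.head(1000))
        planted, _ = plant_errors(table, cfg)
        res = uniqueness_result1(planted)
        assert (res.numerator, res.denominator) == (12, 1000)
        assert res.score == 98.8
        assert oracles.brute_uniqueness1(planted.raw) == 12


class TestConsistency:
    def test_well_typed_table_scores_100(self, make_table):
        table = make_table([{}, {}])
        assert consistency_by_type(table).score == 100.0

    def test_single_type_failure_per_variable_scoring(self, make_table):
        rows = [{"Height": "abc"}] + [{} for _ in range(9)]
        res = consistency_by_type(build_table(rows))
        assert res.variable_score("Height").score == 90.0
        assert res.variable_score("Weight").score == 100.0

    def test_all_missing_column_vacuous_100(self, make_table):
        table = make_table([{"Date of death": ""}, {"Date of death": ""}])
        res = consistency_by_type(table)
        vs = res.variable_score("Date of death")
        assert vs.score == 100.0 and vs.vacuous
        assert any("Date of death" in w for w in res.warnings)

    @pytest.mark.parametrize(
        "override,variable",
        [
            ({"Height": "0"}, "Height"),  # zero-coded missing is a range error
            ({"Date of arrival": "31/12/2005"}, "Date of arrival"),
            ({"Sex": "3"}, "Sex"),
            ({"Hospital admissions": "-1"}, "Hospital admissions"),
        ],
    )
    def test_range_violations(self, override, variable):
        table = build_table([override, {}])
        res = consistency_by_range(table)
        assert res.variable_score(variable).numerator == 1
        assert any(f.variable == variable for f in res.findings)

    def test_999_is_not_a_range_violation(self, make_table):
        table = make_table([{"Hypertension": "999", "Hospital admissions": "999",
                             "Date of death": "999"}])
        assert consistency_by_range(table).numerator == 0

    def test_rules_violation_and_equality(self, make_table):
        table = make_table([
            {"Date of arrival": "05/03/2010", "Date of discharge": "01/03/2010"},
            {"Date of arrival": "05/03/2010", "Date of discharge": "05/03/2010"},
        ])
        res = consistency_by_rules(table)
        assert (res.numerator, res.denominator) == (1, 2)

    def test_rule_not_evaluable_when_field_missing(self, make_table):
        table = make_table([
            {"Date of discharge": ""},
            {"Date of arrival": "05/03/2010", "Date of discharge": "06/03/2010"},
        ])
        res = consistency_by_rules(table)
        assert res.denominator == 1 and res.numerator == 0

    def test_discharge_after_death_violates(self, make_table):
        table = make_table([
            {"Date of discharge": "08/03/2010", "Date of death": "07/03/2010"},
        ])
        assert consistency_by_rules(table).numerator == 1

    def test_custom_rule(self, make_table):
        table = make_table([{"Age": "01/01/2012", "Date of arrival": "05/03/2010"}])
        res = consistency_by_rules(table, [Rule("Age", "le", "Date of arrival")])
        assert res.numerator == 1

    def test_overall_mean(self):
        class Fake:
            def __init__(self, s):
                self.score = s

        assert consistency_overall(Fake(100), Fake(100), Fake(91.21)) == 97.07
        assert consistency_overall(Fake(100), Fake(100), Fake(100)) == 100.0
        assert consistency_overall(Fake(0), Fake(0), Fake(0)) == 0.0


class TestCompleteness:
    def test_fully_documented_with_in_visit_deaths_scores_100(self):
        rows = [{} for _ in range(8)]
        rows.append({"Date of arrival": "05/03/2010",
                     "Date of discharge": "08/03/2010",
                     "Date of death": "08/03/2010"})
        res = completeness(build_table(rows))
        assert res.score == 100.0
        assert not res.warnings

    def test_empty_cells_lower_the_variable_score(self):
        rows = [{"Smoking status": ""} for _ in range(3)] + [{} for _ in range(7)]
        res = completeness(build_table(rows))
        assert res.variable_score("Smoking status").score == 70.0

    def test_all_999_column_complete_with_unknown_rate_100(self):
        rows = [{"Diuretics": "999"} for _ in range(5)]
        res = completeness(build_table(rows))
        assert res.variable_score("Diuretics").score == 100.0
        assert res.extra["unknown_rate"]["Diuretics"] == 100.0

    def test_unconditional_death_rate_reported(self):
        rows = [{} for _ in range(3)]
        rows.append({"Date of death": "08/03/2010",
                     "Date of discharge": "08/03/2010"})
        res = completeness(build_table(rows))
        assert res.extra["unconditional_completeness"]["Date of death"] == 25.0

    def test_death_missing_on_death_visit_lowers_score(self):
        # a death visit identified by the death date must be non-empty, so
        # the conditional denominator only sees recorded deaths; absence of
        # any death yields the vacuous warning instead
        res = completeness(build_table([{} for _ in range(4)]))
        assert res.variable_score("Date of death").vacuous
        assert res.score == 100.0
        assert any("valid-incompleteness" in w for w in res.warnings)


class TestOracleEquivalenceAndProperties:
    def test_structural_numerators_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1234)
        dictionary = default_dictionary()
        for _ in range(25):
            table = random_messy_table(rng, int(rng.integers(10, 60)))
            raw = table.raw
            assert uniqueness_result1(table).numerator == oracles.brute_uniqueness1(raw)
            assert uniqueness_result2(table).numerator == oracles.brute_uniqueness2(raw)
            ct = consistency_by_type(table)
            expected = oracles.brute_type_counts(raw, dictionary)
            for v in ct.per_variable:
                assert (v.numerator, v.denominator) == expected[v.variable]
            cr = consistency_by_range(table)
            expected = oracles.brute_range_counts(raw, dictionary, WINDOW)
            for v in cr.per_variable:
                assert (v.numerator, v.denominator) == expected[v.variable]
            cl = consistency_by_rules(table)
            assert (cl.numerator, cl.denominator) == oracles.brute_rule_counts(raw)
            co = completeness(table)
            expected = oracles.brute_completeness_counts(raw, dictionary)
            for v in co.per_variable:
                if v.variable in expected:
                    assert (v.numerator, v.denominator) == expected[v.variable]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        table = random_messy_table(rng, 40)
        perm = table.with_raw(
            table.raw.sample(frac=1.0, random_state=11).reset_index(drop=True)
        )
        for check in (uniqueness_result1, uniqueness_result2, consistency_by_type,
                      consistency_by_range, consistency_by_rules, completeness):
            assert check(table).score == check(perm).score
            assert check(table).numerator == check(perm).numerator

    def test_adding_a_violation_never_increases_the_score(self, make_table):
        base_rows = [{} for _ in range(10)]
        clean = build_table(base_rows)
        worse = build_table(base_rows + [{"Visit ID": "V0000", "Weight": "99"}])
        assert uniqueness_result1(worse).score < uniqueness_result1(clean).score
        worse2 = build_table(base_rows + [{"Height": "0"}])
        assert (consistency_by_range(worse2).score
                < consistency_by_range(clean).score)

    def test_score_algebra(self):
        rng = np.random.default_rng(99)
        table = random_messy_table(rng, 50)
        for check in (uniqueness_result1, uniqueness_result2, consistency_by_rules):
            res = check(table)
            assert res.score == round_half_up(
                100.0 * (1.0 - res.numerator / res.denominator)
            )
        for check in (consistency_by_type, consistency_by_range, completeness):
            res = check(table)
            assert res.score == round_half_up(
                sum(v.score for v in res.per_variable) / len(res.per_variable)
            )
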