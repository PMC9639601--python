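"""Cohort construction: eligibility, follow-up, ethnicity, condition counts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gpcontinuity import (
    CohortSpec,
    build_cohort,
    compute_follow_up,
    count_ltc,
    filter_eligible_patients,
    harmonize_ethnicity,
)
from gpcontinuity.cohort import CodingError, SchemaError


class TestFollowUp:
    spec = CohortSpec()

    def test_full_window_is_exactly_four_years(self):
        assert compute_follow_up(None, self.spec) == pytest.approx(4.0)

    def test_exit_midway(self):
        got = compute_follow_up("2018-01-01", self.spec)
        assert got == pytest.approx(731 / 365.25)

    def test_exit_on_baseline_gives_zero(self):
        assert compute_follow_up("2016-01-01", self.spec) == 0.0

    def test_practice_closure_truncates(self):
        got = compute_follow_up(None, self.spec, practice_end_date="2017-01-01")
        assert got == pytest.approx(366 / 365.25)

    def test_exit_before_baseline_is_contract_violation(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_follow_up("2015-06-01", self.spec)


class TestHarmonizeEthnicity:
    def test_single_primary_source(self):
        assert harmonize_ethnicity([("2015-01-01", "Bangladeshi")], []) == "Bangladeshi"

    def test_hospital_fallback_when_primary_empty(self):
        got = harmonize_ethnicity([], [("2014-02-02", "Black African")])
        assert got == "Black African"

    def test_primary_precedence_over_richer_hospital_record(self):
        primary = [("2015-01-01", "Indian")]
        hospital = [("2014-01-01", "Chinese")] * 5
        assert harmonize_ethnicity(primary, hospital) == "Indian"

    def test_mode_wins_within_source(self):
        obs = [("2014-01-01", "White British"), ("2015-01-01", "Irish"),
               ("2016-01-01", "White British")]
        assert harmonize_ethnicity(obs, [], scheme="disaggregated") == "White British"

    def test_tie_broken_by_recency(self):
        obs = [("2014-01-01", "Irish"), ("2015-06-01", "Other White")]
        assert harmonize_ethnicity(obs, [], scheme="disaggregated") == "Other White"

    def test_remaining_tie_broken_by_fixed_order(self):
        obs = [("2015-06-01", "Other White"), ("2015-06-01", "Irish")]
        # same count, same date: scheme order puts Irish first
        assert harmonize_ethnicity(obs, [], scheme="disaggregated") == "Irish"

    def test_main_scheme_collapses_white_groups(self):
        obs = [("2015-01-01", "White British"), ("2016-01-01", "Other White")]
        assert harmonize_ethnicity(obs, [], scheme="main-11") == "White"

    def test_both_sources_empty_is_missing(self):
        assert harmonize_ethnicity([], []) is None

    def test_unknown_category_raises(self):
        with pytest.raises(CodingError, match="Martian"):
            harmonize_ethnicity([("2015-01-01", "Martian")], [])


class TestCountLtc:
    baseline = "2016-01-01"

    def test_physical_plus_mental(self):
        conds = [("asthma", "physical", "2010-01-01"),
                 ("depression", "mental", "2012-01-01")]
        assert count_ltc(conds, self.baseline) == (2, "physical+mental")

    def test_single_condition_below_threshold(self):
        assert count_ltc([("depression", "mental", "2012-01-01")],
                         self.baseline) == (1, "0-1")

    def test_mixed_takes_priority_over_both_pure_categories(self):
        conds = [("asthma", "physical", "2010-01-01"),
                 ("diabetes", "physical", "2011-01-01"),
                 ("depression", "mental", "2012-01-01"),
                 ("anxiety", "mental", "2013-01-01")]
        assert count_ltc(conds, self.baseline) == (4, "physical+mental")

    def test_onset_after_baseline_not_counted(self):
        conds = [("asthma", "physical", "2017-01-01"),
                 ("copd", "physical", "2010-01-01")]
        assert count_ltc(conds, self.baseline) == (1, "0-1")

    def test_duplicate_labels_count_once(self):
        conds = [("asthma", "physical", "2010-01-01"),
                 ("asthma", "physical", "2012-01-01")]
        assert count_ltc(conds, self.baseline)[0] == 1

    def test_missing_class_flag_is_schema_error(self):
        with pytest.raises(SchemaError):
            count_ltc([("asthma", None, "2010-01-01")], self.baseline)

    def test_all_flag_archetypes_match_brute_force(self):
        """All 2^4 presence patterns of {2 physical, 2 mental} conditions."""
        pool = [("c_p1", "physical"), ("c_p2", "physical"),
                ("c_m1", "mental"), ("c_m2", "mental")]
        for mask in itertools.product([0, 1], repeat=4):
            conds = [(label, clazz, "2010-01-01")
                     for (label, clazz), keep in zip(pool, mask) if keep]
            count, category = count_ltc(conds, self.baseline)
            # independent re-derivation from first principles
            n_p = sum(1 for (_, c, _) in conds if c == "physical")
            n_m = len(conds) - n_p
            assert count == n_p + n_m
            if count <= 1:
                expected = "0-1"
            elif n_p >= 1 and n_m >= 1:
                expected = "physical+mental"
            elif n_m == 0:
                expected = "2+ physical"
            else:
                expected = "2+ mental"
            assert category == expected


class TestEligibility:
    def test_hand_fixture_flow(self, hand_fixture):
        patients, events, _, spec = hand_fixture
        survivors, tallies = filter_eligible_patients(patients, events, spec)
        assert set(survivors["patient_id"]) == {"p1", "p2", "p5"}
        assert tallies["not_registered_at_baseline"] == 1   # p7
        assert tallies["below_minimum_age"] == 1            # p4
        assert tallies["fewer_than_minimum_consultations"] == 1  # p3
        assert tallies["missing_covariates"] == 1           # p6
        assert tallies["eligible"] == 3

    def test_tallies_sum_to_input_count(self, hand_fixture):
        patients, events, _, spec = hand_fixture
        _, tallies = filter_eligible_patients(patients, events, spec)
        assert sum(tallies.values()) == len(patients)

    def test_two_consultations_excluded_three_retained(self, hand_fixture):
        patients, events, _, spec = hand_fixture
        survivors, _ = filter_eligible_patients(patients, events, spec)
        assert "p3" not in set(survivors["patient_id"])
        # p5 has exactly 3 pre-exit events and survives
        assert "p5" in set(survivors["patient_id"])

    def test_quality_flag_column_respected(self, hand_fixture):
        patients, events, _, spec = hand_fixture
        patients = patients.assign(quality_flag=[True] * 6 + [True])
        patients.loc[patients["patient_id"] == "p1", "quality_flag"] = False
        _, tallies = filter_eligible_patients(patients, events, spec)
        assert tallies["failed_quality_or_linkage"] == 1
        assert tallies["eligible"] == 2

    def test_missing_columns_named_in_error(self, hand_fixture):
        patients, events, _, spec = hand_fixture
        with pytest.raises(SchemaError, match="mode"):
            filter_eligible_patients(patients, events.drop(columns=["mode"]), spec)


class TestBuildCohort:
    def test_hand_fixture_rows_match_hand_computation(self, hand_fixture):
        patients, events, conditions, spec = hand_fixture
        cohort, flow = build_cohort(patients, events, conditions, spec)
        assert list(cohort["patient_id"]) == ["p1", "p2", "p5"]
        by_id = cohort.set_index("patient_id")
        assert by_id.loc["p1", "upc"] == pytest.approx(0.5)
        assert by_id.loc["p1", "coc"] == pytest.approx(2 / 9)
        assert by_id.loc["p1", "n_consultations"] == 10
        assert by_id.loc["p1", "ltc_count"] == 2
        assert by_id.loc["p1", "ltc_category"] == "physical+mental"
        assert by_id.loc["p1", "follow_up_years"] == pytest.approx(4.0)
        assert by_id.loc["p2", "coc"] == pytest.approx(4 / 9)
        assert by_id.loc["p2", "ltc_category"] == "0-1"
        assert by_id.loc["p5", "upc"] == 1.0
        assert by_id.loc["p5", "coc"] == 1.0
        assert by_id.loc["p5", "n_consultations"] == 3  # post-exit events dropped
        assert by_id.loc["p5", "follow_up_years"] == pytest.approx(152 / 365.25)
        assert flow["eligible"] == 3

    def test_row_order_of_inputs_is_irrelevant(self, hand_fixture):
        patients, events, conditions, spec = hand_fixture
        cohort1, flow1 = build_cohort(patients, events, conditions, spec)
        rng = np.random.default_rng(0)
        cohort2, flow2 = build_cohort(
            patients.sample(frac=1, random_state=1),
            events.sample(frac=1, random_state=2),
            conditions.sample(frac=1, random_state=3),
            spec,
        )
        pd.testing.assert_frame_equal(cohort1, cohort2)
        assert flow1 == flow2

    def test_empty_consultations_tally_everyone_out(self, hand_fixture):
        patients, events, conditions, spec = hand_fixture
        cohort, flow = build_cohort(patients, events.iloc[:0], conditions, spec)
        assert cohort.empty
        # the two patients failing earlier rules keep their reasons
        assert flow["fewer_than_minimum_consultations"] == 5
        assert flow["eligible"] == 0

    def test_min_consultations_monotone_in_threshold(self, hand_fixture):
        patients, events, conditions, spec = hand_fixture
        sizes = [
            len(build_cohort(patients, events, conditions,
                             spec.replace(min_consultations=k))[0])
            for k in (3, 5, 11)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_two_source_observation_columns_are_harmonized(self, hand_fixture):
        patients, events, conditions, spec = hand_fixture
        patients = patients.drop(columns=["ethnicity"])
        patients["ethnicity_obs_primary"] = [
            [("2015-01-01", "White British")], [("2015-01-01", "Bangladeshi")],
            None, None, [], None, None,
        ]
        patients["ethnicity_obs_hospital"] = [
            None, None, None, None, [("2014-01-01", "Indian")], None, None,
        ]
        cohort, _ = build_cohort(patients, events, conditions, spec)
        by_id = cohort.set_index("patient_id")
        assert by_id.loc["p1", "ethnicity"] == "White"   # collapsed in main-11
        assert by_id.loc["p5", "ethnicity"] == "Indian"  # hospital fallback
        # p6 had no observations in either source: missing, so excluded
        assert "p6" not in by_id.index

    def test_disaggregated_scheme_preserves_detail(self, hand_fixture):
        patients, events, conditions, spec = hand_fixture
        patients = patients.drop(columns=["ethnicity"])
        patients["ethnicity_obs_primary"] = [
            [("2015-01-01", "White British")], [("2015-01-01", "Bangladeshi")],
            None, None, [("2015-01-01", "Irish")], [("2015-01-01", "Irish")], None,
        ]
        patients["ethnicity_obs_hospital"] = [None] * 7
        cohort, _ = build_cohort(patients, events, conditions, spec,
                                 scheme="disaggregated")
        by_id = cohort.set_index("patient_id")
        assert by_id.loc["p1", "ethnicity"] == "White British"
        assert by_id.loc["p5", "ethnicity"] == "Irish"
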