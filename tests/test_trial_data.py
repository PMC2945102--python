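"""Cohort fixtures, CSV round-trips, and descriptive statistics."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cortmeta.trial_data import (
    ArmCount,
    CSVParseError,
    DataError,
    EmptyDatasetError,
    Trial,
    classify_dose,
    dataset_from_trials,
    hydrocortisone_equivalent,
    load_dataset,
    load_trials_csv,
    observed_log_or,
    write_cohort_csv,
)


class TestArmCount:
    def test_rejects_impossible_counts(self):
        with pytest.raises(DataError):
            ArmCount(21, 20)
        with pytest.raises(DataError):
            ArmCount(-1, 20)
        with pytest.raises(DataError):
            ArmCount(0, 0)

    def test_accessors(self):
        arm = ArmCount(3, 10)
        assert arm.nonevents == 7 and arm.rate == 0.3


class TestBuiltinCohort:
    def test_cohort_size_and_strata(self, cohort):
        assert len(cohort) == 14
        mort_high = dataset_from_trials(cohort, "mortality", "high")
        mort_low = dataset_from_trials(cohort, "mortality", "low")
        assert len(mort_high) == 5
        assert len(mort_low) == 9

    @pytest.mark.parametrize(
        "trial_id, outcome, expected",
        [
            ("Annane 2002", "mortality", (95, 160, 103, 150)),
            ("Sprung 2008", "shock_reversal", (200, 251, 184, 248)),
            ("CSG 1963", "gi_bleed", (4, 96, 0, 98)),
            ("Schumer 1976", "mortality", (9, 86, 33, 86)),
        ],
    )
    def test_transcribed_counts(self, cohort, trial_id, outcome, expected):
        trial = next(t for t in cohort if t.trial_id == trial_id)
        s, c = trial.outcomes[outcome]
        assert (s.events, s.total, c.events, c.total) == expected

    def test_enrolment_totals(self, cohort):
        # published enrolment sums to 1,991 patients; the mortality-table arm
        # denominators differ for four trials and sum to 2,026
        assert sum(t.total_n for t in cohort) == 1991
        mort = dataset_from_trials(cohort, "mortality", "all")
        rt, nt, rc, nc = mort.counts()
        assert sum(nt) + sum(nc) == 2026

    def test_outcome_stratum_sizes_match_reported_analyses(self, cohort):
        sizes = {
            ("shock_reversal", "high"): 2,
            ("shock_reversal", "low"): 7,
            ("superinfection", "high"): 4,
            ("superinfection", "low"): 6,
            ("gi_bleed", "high"): 3,
            ("gi_bleed", "low"): 5,
            ("hyperglycemia", "high"): 3,
            ("hyperglycemia", "low"): 3,
            ("shock_reversal_responders", "all"): 3,
            ("shock_reversal_nonresponders", "all"): 3,
        }
        for (outcome, stratum), n in sizes.items():
            assert len(dataset_from_trials(cohort, outcome, stratum)) == n

    def test_age_covariate_availability(self, cohort):
        low = dataset_from_trials(cohort, "mortality", "low")
        high = dataset_from_trials(cohort, "mortality", "high")
        assert sum(v is not None for v in low.covariate_values("age")) == 6
        assert sum(v is not None for v in high.covariate_values("age")) == 4


class TestCSVRoundTrip:
    def test_cohort_roundtrip(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = load_trials_csv(path)
        assert [t.trial_id for t in back] == [t.trial_id for t in cohort]
        for orig, re in zip(cohort, back):
            assert re.outcomes == orig.outcomes
            assert re.age_steroid == orig.age_steroid
            assert re.age_placebo == orig.age_placebo
            assert re.hc_equiv_total_mg == orig.hc_equiv_total_mg
            assert re.steroid_days == orig.steroid_days

    def test_load_dataset_stratum(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        assert len(load_dataset(path, "mortality", "low")) == 9
        single = tmp_path / "one.csv"
        single.write_text(
            "trial_id,year,dose_group,outcome,steroid_events,steroid_total,"
            "control_events,control_total,age_steroid,age_placebo,"
            "hc_equiv_total_mg,steroid_days\n"
            "t1,2000,low,mortality,10,20,10,20,,,,\n"
        )
        assert len(load_dataset(single, "mortality", "all")) == 1

    def test_malformed_rows_name_the_line(self, tmp_path):
        header = (
            "trial_id,year,dose_group,outcome,steroid_events,steroid_total,"
            "control_events,control_total,age_steroid,age_placebo,"
            "hc_equiv_total_mg,steroid_days\n"
        )
        bad_counts = tmp_path / "bad.csv"
        bad_counts.write_text(header + "t1,2000,low,mortality,21,20,10,20,,,,\n")
        with pytest.raises(CSVParseError, match="line 2"):
            load_dataset(bad_counts, "mortality", "all")
        bad_field = tmp_path / "bad2.csv"
        bad_field.write_text(header + "t1,2000,low,mortality,xx,20,10,20,,,,\n")
        with pytest.raises(CSVParseError, match="line 2"):
            load_dataset(bad_field, "mortality", "all")

    def test_empty_selection_is_explicit(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        with pytest.raises(EmptyDatasetError):
            load_dataset(path, "hyperglycemia", ["Annane 2002"])


class TestObservedLogOR:
    def test_reference_values(self):
        lor, se = observed_log_or(ArmCount(95, 160), ArmCount(103, 150))
        assert lor == pytest.approx(math.log((95 / 65) / (103 / 47)), abs=1e-12)
        assert lor == pytest.approx(-0.406, abs=2e-3)
        assert se == pytest.approx(math.sqrt(1 / 95 + 1 / 65 + 1 / 103 + 1 / 47), abs=1e-12)

    def test_zero_cell_correction(self):
        lor, _ = observed_log_or(ArmCount(4, 96), ArmCount(0, 98), correction=0.5)
        assert lor == pytest.approx(math.log((4.5 / 92.5) / (0.5 / 98.5)), abs=1e-12)
        assert lor == pytest.approx(2.260, abs=1e-3)
        with pytest.raises(DataError):
            observed_log_or(ArmCount(4, 96), ArmCount(0, 98), correction=0.0)

    def test_identical_arms_give_null(self):
        lor, _ = observed_log_or(ArmCount(10, 20), ArmCount(10, 20))
        assert lor == 0.0

    def test_correction_untouched_without_zero_cells(self):
        # correction must not perturb tables with no zero cell
        a, b = observed_log_or(ArmCount(5, 10), ArmCount(3, 9), correction=0.5)
        c, d = observed_log_or(ArmCount(5, 10), ArmCount(3, 9), correction=0.0)
        assert (a, b) == (c, d)

    @given(
        st.tuples(st.integers(0, 30), st.integers(0, 30)),
        st.tuples(st.integers(0, 30), st.integers(0, 30)),
    )
    def test_antisymmetry_under_arm_swap(self, pair_a, pair_b):
        ea, xa = pair_a
        eb, xb = pair_b
        arm_a = ArmCount(ea, ea + xa + 1)
        arm_b = ArmCount(eb, eb + xb + 1)
        fwd, se_f = observed_log_or(arm_a, arm_b)
        rev, se_r = observed_log_or(arm_b, arm_a)
        assert fwd == pytest.approx(-rev, abs=1e-10)
        assert se_f == pytest.approx(se_r, abs=1e-10)


class TestDoseHandling:
    @pytest.mark.parametrize(
        "drug, dose, expected",
        [
            ("hydrocortisone", 100, 100),
            ("methylprednisolone", 100, 500),
            ("prednisolone", 0, 0),
            ("dexamethasone", 10, 267),
            ("betamethasone", 10, 267),
        ],
    )
    def test_hydrocortisone_equivalent(self, drug, dose, expected):
        assert hydrocortisone_equivalent(drug, dose) == pytest.approx(expected)

    def test_unknown_drug_raises(self):
        with pytest.raises(DataError):
            hydrocortisone_equivalent("cortisone", 100)

    def test_cohort_classification_matches_labels(self, cohort):
        for trial in cohort:
            assert classify_dose(trial) == trial.dose_group

    def test_boundary_is_strict(self):
        trial = Trial("syn", 2000, "high", hc_equiv_total_mg=1000.0, steroid_days=1.0,
                      taper_days=0.0)
        assert classify_dose(trial) == "low"

    def test_label_fallback_and_error(self):
        assert classify_dose(Trial("syn", 2000, "low")) == "low"
        bare = Trial("syn", 2000, "low")
        bare.dose_group = "unknown"  # bypass validation to hit the error path
        with pytest.raises(DataError):
            classify_dose(bare)
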