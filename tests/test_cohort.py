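"""Eligibility criteria, response labeling and cohort partition contracts."""

import pandas as pd
import pytest

import simrec
from simrec.cohort import EligibilityError, apply_eligibility, label_response
from tests.conftest import extracts_of


def _mini_extracts(ef_rows, dx_rows, pid="A"):
    patients = pd.DataFrame([{"patient_id": pid, **_complete_features()}])
    ef = pd.DataFrame(ef_rows, columns=["patient_id", "date", "ef"])
    dx = pd.DataFrame(dx_rows, columns=["patient_id", "date", "icd9_code"])
    return patients, ef, dx


def _complete_features():
    row = {
        "age": 70.0,
        "sex": "M",
        "race": "White",
        "ethnicity": "Non-Hispanic",
        "bmi": 28.0,
        "systolic_bp": 120.0,
        "hemoglobin": 13.0,
        "sodium": 140.0,
        "cholesterol": 150.0,
        "lymphocytes": 1.5,
    }
    row.update({c: 0 for c in simrec.COMORBIDITIES})
    return row


def test_high_ef_only_fails_criterion_2():
    patients, ef, dx = _mini_extracts(
        [("A", "2010-01-05", 55.0)], [("A", "2010-01-01", "428.0")]
    )
    results, report = apply_eligibility(patients, ef, dx)
    assert report.empty
    row = results.iloc[0]
    assert row["status"] == "ineligible"
    assert row["failed_criteria"] == "2"


def test_textbook_eligible_patient():
    patients, ef, dx = _mini_extracts(
        [("A", "2010-01-11", 45.0), ("A", "2010-09-28", 40.0)],
        [("A", "2010-01-01", "428.0")],
    )
    results, _ = apply_eligibility(patients, ef, dx)
    row = results.iloc[0]
    assert row["status"] == "eligible"
    assert row["index_ef"] == 45.0
    assert row["followup_ef"] == 40.0


def test_prior_exclusion_diagnosis_fails_criterion_4_but_same_day_does_not():
    ef_rows = [("A", "2010-01-11", 45.0), ("A", "2010-09-28", 40.0)]
    patients, ef, dx = _mini_extracts(
        ef_rows,
        [("A", "2010-01-01", "428.0"), ("A", "2009-06-01", "425.4")],
    )
    assert apply_eligibility(patients, ef, dx)[0].iloc[0]["failed_criteria"] == "4"
    patients, ef, dx = _mini_extracts(
        ef_rows,
        [("A", "2010-01-01", "428.0"), ("A", "2010-01-01", "425.4")],
    )
    assert apply_eligibility(patients, ef, dx)[0].iloc[0]["status"] == "eligible"


def test_malformed_date_goes_to_validation_report_not_silently_dropped():
    patients, ef, dx = _mini_extracts(
        [("A", "not-a-date", 45.0)], [("A", "2010-01-01", "428.0")]
    )
    results, report = apply_eligibility(patients, ef, dx)
    assert results.iloc[0]["status"] == "invalid"
    assert list(report["issue"]) == ["malformed date"]


def test_planted_eligibility_flags_recovered_exactly():
    """Eligibility decisions match the generator's planted pass/fail flags."""
    cfg = simrec.default_config(n_patients=200, seed=9, ineligible_fraction=0.3)
    syn = simrec.generate_cohort(cfg)
    results, _ = apply_eligibility(
        syn.patients, syn.ef_measurements, syn.diagnoses
    )
    merged = results.merge(syn.ground_truth, on="patient_id")
    assert ((merged["status"] == "eligible") == (merged["eligible"] == 1)).all()
    # each planted failure mode trips the matching criterion
    mode_to_crit = {
        "no_hf_dx": "1",
        "ef_above_50": "2",
        "no_followup": "3",
        "prior_exclusion": "4",
        "incomplete": "incomplete_data",
    }
    for mode, crit in mode_to_crit.items():
        sub = merged[merged["failure_mode"] == mode]
        assert len(sub) > 0
        assert (sub["failed_criteria"] == crit).all(), mode


def test_label_response_threshold_rule():
    base = {
        "patient_id": "A",
        "status": "eligible",
        "index_date": pd.Timestamp("2010-01-01"),
        "index_ef": 30.0,
        "followup_date": pd.Timestamp("2010-07-20"),
    }
    good = label_response({**base, "followup_ef": 41.0})
    assert good["label"] == "good" and good["ef_delta"] == pytest.approx(11.0)
    poor = label_response({**base, "followup_ef": 39.0})
    assert poor["label"] == "poor" and poor["ef_delta"] == pytest.approx(9.0)
    # relative interpretation: 9 points on EF 30 is a 30% relative gain
    assert label_response({**base, "followup_ef": 39.0}, relative=True)["label"] == "good"


def test_label_response_requires_eligibility():
    with pytest.raises(EligibilityError):
        label_response({"patient_id": "A", "status": "ineligible"})


def test_followup_beyond_response_window_is_poor():
    res = {
        "patient_id": "A",
        "status": "eligible",
        "index_date": pd.Timestamp("2010-01-01"),
        "index_ef": 30.0,
        "followup_date": pd.Timestamp("2011-02-01"),  # day 396 > 365
        "followup_ef": 45.0,
    }
    assert label_response(res)["label"] == "poor"


def test_partition_into_eligible_ineligible_invalid():
    cfg = simrec.default_config(n_patients=150, seed=4, ineligible_fraction=0.4)
    syn = simrec.generate_cohort(cfg)
    results, _ = apply_eligibility(syn.patients, syn.ef_measurements, syn.diagnoses)
    assert len(results) == 150
    counts = results["status"].value_counts()
    assert counts.sum() == 150
    empty_failed = results["failed_criteria"] == ""
    assert ((results["status"] == "eligible") == (
        empty_failed & (results["status"] != "invalid")
    )).all()


def test_cohort_labels_match_planted_ground_truth(default_synthetic, default_cohort):
    gt = default_synthetic.ground_truth.set_index("patient_id")
    got = default_cohort.set_index("patient_id")
    assert (got["response"] == gt.loc[got.index, "response"]).all()
    assert (got["plan"] == gt.loc[got.index, "assigned_plan"]).all()


def test_lowering_threshold_never_flips_good_to_poor(default_synthetic):
    ex = extracts_of(default_synthetic)
    strict, _, _ = simrec.build_cohort(ex, response_threshold=10)
    lax, _, _ = simrec.build_cohort(ex, response_threshold=5)
    good_strict = set(strict.loc[strict["response"] == "good", "patient_id"])
    good_lax = set(lax.loc[lax["response"] == "good", "patient_id"])
    assert good_strict <= good_lax


def test_rebuilding_on_the_built_cohort_changes_nothing(default_synthetic, default_cohort):
    ex = extracts_of(default_synthetic)
    keep = set(default_cohort["patient_id"])
    filtered = {name: df[df["patient_id"].isin(keep)].reset_index(drop=True)
                for name, df in ex.items()}
    again, exclusions, _ = simrec.build_cohort(filtered)
    assert exclusions.empty
    pd.testing.assert_frame_equal(
        again.sort_values("patient_id").reset_index(drop=True),
        default_cohort.sort_values("patient_id").reset_index(drop=True),
    )
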