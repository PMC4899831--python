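"""Cohort phenotyping: eligibility criteria and response-to-therapy labels.

Four eligibility criteria define the analysis cohort:

1. a heart-failure diagnosis (ICD-9-CM 428.x);
2. an EF measurement below 50% within 30 days of the earliest HF
   diagnosis (the *index* EF);
3. another EF measurement 180-450 days after the index EF (the earliest
   such is the *follow-up* EF);
4. no diagnosis from the exclusion set (coronary artery disease,
   myocarditis, cardiomyopathy, aortic/mitral stenosis) strictly before
   the HF diagnosis.

Patients missing any modelling feature are flagged ``incomplete_data``;
records with malformed dates or out-of-range EF values are collected into
a validation report and marked ``invalid`` (never silently dropped).
Criteria that cannot be assessed because an upstream anchor is missing
(e.g. no index EF) are not marked failed.

A patient responds *well* to therapy if the follow-up EF exceeds the
index EF by at least 10 percentage points (configurable, optionally
relative) within 365 days of treatment initiation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .simulate import COMORBIDITIES

__all__ = [
    "EligibilityWindows",
    "EligibilityError",
    "apply_eligibility",
    "label_response",
    "build_cohort",
    "DEFAULT_EXCLUSION_PREFIXES",
    "REQUIRED_FEATURES",
]

#: ICD-9-CM prefixes for the exclusion diagnoses (criterion 4).  The code
#: lists behind the named conditions are an editorial default: 414 coronary
#: artery disease, 422 acute myocarditis, 425 cardiomyopathy, 424.1 aortic
#: valve disorders, 394.0 / 396 mitral (and combined) stenosis.
DEFAULT_EXCLUSION_PREFIXES: tuple[str, ...] = (
    "414",
    "422",
    "425",
    "424.1",
    "394.0",
    "396",
)

_HF_CODE = re.compile(r"^428(\.|$)")

#: Features required for complete-case inclusion.
REQUIRED_FEATURES: tuple[str, ...] = (
    "age",
    "sex",
    "race",
    "ethnicity",
    "bmi",
    "systolic_bp",
    "hemoglobin",
    "sodium",
    "cholesterol",
    "lymphocytes",
    *COMORBIDITIES,
)


class EligibilityError(ValueError):
    """Raised when an operation's precondition on eligibility is violated."""


@dataclass(frozen=True)
class EligibilityWindows:
    """Day-count windows used by the eligibility criteria.

    Calendar-month arithmetic is avoided for determinism: "one month" is
    30 days, "6 to 15 months" is the closed interval [180, 450] days and
    "12 months" is 365 days.
    """

    index_window_days: int = 30
    followup_min_days: int = 180
    followup_max_days: int = 450
    response_max_days: int = 365


def _first_per_patient(df: pd.DataFrame, date_col: str, value_col: str) -> pd.DataFrame:
    """Earliest row per patient; date ties broken by ascending value."""
    ordered = df.reset_index(drop=True).sort_values(
        ["patient_id", date_col, value_col], kind="stable"
    )
    return ordered.groupby("patient_id", sort=False).first()


def apply_eligibility(
    patients: pd.DataFrame,
    ef_measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    windows: EligibilityWindows | None = None,
    exclusion_prefixes: Iterable[str] = DEFAULT_EXCLUSION_PREFIXES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four eligibility criteria to raw extracts.

    Returns ``(results, validation_report)``.  ``results`` has one row per
    patient with columns ``patient_id, status, failed_criteria,
    index_date, index_ef, followup_date, followup_ef``; ``status`` is one
    of ``eligible | ineligible | invalid`` and ``failed_criteria`` is a
    comma-joined subset of ``{1, 2, 3, 4, incomplete_data}``.
    ``validation_report`` lists every malformed record.
    """
    windows = windows or EligibilityWindows()
    exclusion_prefixes = tuple(exclusion_prefixes)

    ef = ef_measurements.copy()
    ef["patient_id"] = ef["patient_id"].astype(str)
    ef["date_parsed"] = pd.to_datetime(ef["date"], format="ISO8601", errors="coerce")
    ef["ef_value"] = pd.to_numeric(ef["ef"], errors="coerce")
    ef_bad_date = ef["date_parsed"].isna()
    ef_bad_value = ~ef_bad_date & (
        ef["ef_value"].isna() | (ef["ef_value"] <= 0) | (ef["ef_value"] > 100)
    )

    dx = diagnoses.copy()
    dx["patient_id"] = dx["patient_id"].astype(str)
    dx["date_parsed"] = pd.to_datetime(dx["date"], format="ISO8601", errors="coerce")
    dx_bad_date = dx["date_parsed"].isna()

    problems = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": ef.loc[ef_bad_date, "patient_id"],
                    "table": "ef_measurements",
                    "issue": "malformed date",
                }
            ),
            pd.DataFrame(
                {
                    "patient_id": ef.loc[ef_bad_value, "patient_id"],
                    "table": "ef_measurements",
                    "issue": "EF outside (0, 100]",
                }
            ),
            pd.DataFrame(
                {
                    "patient_id": dx.loc[dx_bad_date, "patient_id"],
                    "table": "diagnoses",
                    "issue": "malformed date",
                }
            ),
        ],
        ignore_index=True,
    )
    invalid_ids = set(problems["patient_id"])

    res = patients[["patient_id"]].copy()
    res["patient_id"] = res["patient_id"].astype(str)
    res = res.set_index("patient_id")

    # incomplete data: complete-case filtering on all modelling features
    pat = patients.copy()
    pat["patient_id"] = pat["patient_id"].astype(str)
    pat = pat.set_index("patient_id")
    missing_cols = [c for c in REQUIRED_FEATURES if c not in pat.columns]
    if missing_cols:
        incomplete = pd.Series(True, index=pat.index)
    else:
        incomplete = pat[list(REQUIRED_FEATURES)].isna().any(axis=1)

    # criterion 1: HF diagnosis 428.x
    dx_ok = dx[~dx_bad_date]
    is_hf = dx_ok["icd9_code"].astype(str).str.match(_HF_CODE)
    hf_date = dx_ok[is_hf].groupby("patient_id")["date_parsed"].min()
    res["hf_date"] = hf_date.reindex(res.index)

    # criterion 2: index EF < 50% within the index window of the HF diagnosis
    ef_ok = ef[~ef_bad_date & ~ef_bad_value].merge(
        hf_date.rename("hf_date"), left_on="patient_id", right_index=True
    )
    near = (ef_ok["date_parsed"] - ef_ok["hf_date"]).abs() <= pd.Timedelta(
        days=windows.index_window_days
    )
    index_rows = _first_per_patient(
        ef_ok[near & (ef_ok["ef_value"] < 50.0)], "date_parsed", "ef_value"
    )
    res["index_date"] = index_rows["date_parsed"].reindex(res.index)
    res["index_ef"] = index_rows["ef_value"].reindex(res.index)

    # criterion 3: follow-up EF inside [followup_min, followup_max] days
    ef_ok2 = ef[~ef_bad_date & ~ef_bad_value].merge(
        res["index_date"].dropna(), left_on="patient_id", right_index=True
    )
    lag = (ef_ok2["date_parsed"] - ef_ok2["index_date"]).dt.days
    fup_rows = _first_per_patient(
        ef_ok2[(lag >= windows.followup_min_days) & (lag <= windows.followup_max_days)],
        "date_parsed",
        "ef_value",
    )
    res["followup_date"] = fup_rows["date_parsed"].reindex(res.index)
    res["followup_ef"] = fup_rows["ef_value"].reindex(res.index)

    # criterion 4: exclusion diagnosis strictly before the HF diagnosis
    dx_excl = dx_ok[dx_ok["icd9_code"].astype(str).str.startswith(exclusion_prefixes)]
    dx_excl = dx_excl.merge(
        hf_date.rename("hf_date"), left_on="patient_id", right_index=True
    )
    prior_ids = set(
        dx_excl.loc[dx_excl["date_parsed"] < dx_excl["hf_date"], "patient_id"]
    )

    rows = []
    for pid, r in res.iterrows():
        if pid in invalid_ids:
            rows.append((pid, "invalid", "", None, None, None, None))
            continue
        failed = []
        if incomplete.get(pid, True):
            failed.append("incomplete_data")
        if pd.isna(r["hf_date"]):
            failed.append("1")
        else:
            if pd.isna(r["index_date"]):
                failed.append("2")
            elif pd.isna(r["followup_date"]):
                failed.append("3")
            if pid in prior_ids:
                failed.append("4")
        rows.append(
            (
                pid,
                "eligible" if not failed else "ineligible",
                ",".join(failed),
                r["index_date"] if pd.notna(r["index_date"]) else None,
                r["index_ef"] if pd.notna(r["index_ef"]) else None,
                r["followup_date"] if pd.notna(r["followup_date"]) else None,
                r["followup_ef"] if pd.notna(r["followup_ef"]) else None,
            )
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "status",
            "failed_criteria",
            "index_date",
            "index_ef",
            "followup_date",
            "followup_ef",
        ],
    )
    return results, problems.reset_index(drop=True)


def label_response(
    result: pd.Series | dict,
    threshold: float = 10.0,
    relative: bool = False,
    initiation_date: pd.Timestamp | None = None,
    response_max_days: int = 365,
) -> dict:
    """Label one eligible patient's response to therapy.

    ``ef_delta`` is follow-up EF minus index EF in absolute percentage
    points (or percent of the index EF when ``relative``).  The label is
    ``good`` iff ``ef_delta >= threshold`` and the follow-up measurement
    falls within ``response_max_days`` of treatment initiation (default
    initiation: the index EF date).

    Raises :class:`EligibilityError` if called on an ineligible result.
    """
    status = result.get("status", "eligible")
    if status != "eligible":
        raise EligibilityError(
            f"label_response requires an eligible patient, got status={status!r}"
        )
    index_ef = float(result["index_ef"])
    followup_ef = float(result["followup_ef"])
    delta = followup_ef - index_ef
    if relative:
        delta = 100.0 * delta / index_ef
    init = initiation_date if initiation_date is not None else result["index_date"]
    in_window = (result["followup_date"] - init).days <= response_max_days
    label = "good" if (delta >= threshold and in_window) else "poor"
    return {"patient_id": result["patient_id"], "label": label, "ef_delta": delta}


def _plans_in_window(
    medications: pd.DataFrame, index_dates: pd.Series, window_days: int
) -> pd.Series:
    """Canonical plan per patient id from medication starts in the
    treatment window (empty string when untreated)."""
    meds = medications.copy()
    meds["patient_id"] = meds["patient_id"].astype(str)
    meds["start_parsed"] = pd.to_datetime(
        meds["start_date"], format="ISO8601", errors="coerce"
    )
    meds = meds.merge(
        index_dates.rename("index_date"), left_on="patient_id", right_index=True
    )
    lag = (meds["start_parsed"] - meds["index_date"]).dt.days
    in_win = meds[(lag >= 0) & (lag <= window_days)]
    plans = in_win.groupby("patient_id")["drug_class"].agg(
        lambda cls: "+".join(sorted(set(cls)))
    )
    return plans.reindex(index_dates.index, fill_value="")


def build_cohort(
    extracts: dict[str, pd.DataFrame],
    windows: EligibilityWindows | None = None,
    response_threshold: float = 10.0,
    relative_response: bool = False,
    initiation: str = "index",
    treatment_window_days: int = 365,
    exclusion_prefixes: Iterable[str] = DEFAULT_EXCLUSION_PREFIXES,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build the labeled analysis cohort from raw extracts.

    Returns ``(cohort, exclusions, validation_report)``.  ``cohort`` has
    one row per eligible patient: demographics, vitals, labs, comorbidity
    flags, index/follow-up EF, ``ef_delta``, ``response`` and the
    medication ``plan`` (empty string for untreated patients, who are
    excluded from recommendation training downstream).

    ``initiation`` selects the treatment-initiation date for the response
    window: ``"index"`` (the index EF date) or ``"first_med"`` (earliest
    medication start).
    """
    windows = windows or EligibilityWindows()
    results, report = apply_eligibility(
        extracts["patients"],
        extracts["ef_measurements"],
        extracts["diagnoses"],
        windows,
        exclusion_prefixes,
    )
    eligible = results[results["status"] == "eligible"].set_index("patient_id")

    meds = extracts["medications"].copy()
    meds["patient_id"] = meds["patient_id"].astype(str)
    meds["start_parsed"] = pd.to_datetime(
        meds["start_date"], format="ISO8601", errors="coerce"
    )
    if initiation == "first_med":
        first_med = meds.groupby("patient_id")["start_parsed"].min()
        init_dates = first_med.reindex(eligible.index).fillna(eligible["index_date"])
    elif initiation == "index":
        init_dates = eligible["index_date"]
    else:
        raise ValueError("initiation must be 'index' or 'first_med'")

    delta = eligible["followup_ef"] - eligible["index_ef"]
    if relative_response:
        delta = 100.0 * delta / eligible["index_ef"]
    in_window = (
        eligible["followup_date"] - init_dates
    ).dt.days <= windows.response_max_days
    response = ((delta >= response_threshold) & in_window).map(
        {True: "good", False: "poor"}
    )
    plans = _plans_in_window(
        extracts["medications"], eligible["index_date"], treatment_window_days
    )

    pat = extracts["patients"].copy()
    pat["patient_id"] = pat["patient_id"].astype(str)
    pat = pat.set_index("patient_id")
    cohort = pat.loc[eligible.index, list(REQUIRED_FEATURES)].copy()
    cohort.insert(0, "patient_id", eligible.index)
    cohort["index_date"] = eligible["index_date"].dt.date.astype(str)
    cohort["index_ef"] = eligible["index_ef"]
    cohort["followup_date"] = eligible["followup_date"].dt.date.astype(str)
    cohort["followup_ef"] = eligible["followup_ef"]
    cohort["ef_delta"] = delta
    cohort["response"] = response
    cohort["plan"] = plans
    cohort = cohort.reset_index(drop=True)

    exclusions = results[results["status"] != "eligible"][
        ["patient_id", "status", "failed_criteria"]
    ].reset_index(drop=True)
    return cohort, exclusions, report
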