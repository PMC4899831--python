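"""Shared fixtures: synthetic cohorts at the study's default conditions."""

import pandas as pd
import pytest

import simrec


def extracts_of(syn: simrec.SyntheticCohort) -> dict[str, pd.DataFrame]:
    return {
        name: getattr(syn, name)
        for name in ("patients", "ef_measurements", "diagnoses", "medications")
    }


@pytest.fixture(scope="session")
def default_synthetic() -> simrec.SyntheticCohort:
    """Study-sized cohort (n=1386) at the default generator conditions."""
    return simrec.generate_cohort(simrec.default_config(seed=7))


@pytest.fixture(scope="session")
def default_cohort(default_synthetic) -> pd.DataFrame:
    cohort, exclusions, report = simrec.build_cohort(extracts_of(default_synthetic))
    assert exclusions.empty and report.empty
    return cohort


@pytest.fixture(scope="session")
def calibration_synthetic() -> simrec.SyntheticCohort:
    """Large cohort (n=5000) for law-of-large-numbers calibration checks."""
    return simrec.generate_cohort(simrec.default_config(n_patients=5000, seed=2))


@pytest.fixture(scope="session")
def planted_synthetic() -> simrec.SyntheticCohort:
    """Strongly planted cohort: 4 groups, separation 8 SD, effect 0.5."""
    cfg = simrec.default_config(
        n_patients=2000, seed=11, group_separation=8.0, plan_match_effect=0.5
    )
    return simrec.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort(planted_synthetic) -> pd.DataFrame:
    cohort, _, _ = simrec.build_cohort(extracts_of(planted_synthetic))
    return cohort
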