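"""Numeric encoding of patient records and medication-plan labels.

Continuous variables are z-scored with constants fitted on training
patients only; categoricals are one-hot encoded against the reference
(first) level; the 26 comorbidity flags pass through as {0, 1}.  Drug
classes define the label (the medication plan) and are excluded from the
feature vector by default to avoid label leakage; ``include_plan=True``
adds the five class indicators for replication experiments.

Canonical feature order: continuous block (age, bmi, systolic_bp,
index_ef, hemoglobin, sodium, cholesterol, lymphocytes), one-hot block
(sex, race, ethnicity; levels sorted, first dropped), comorbidity block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .plans import DRUG_CLASSES, canonical_plan
from .simulate import COMORBIDITIES

__all__ = [
    "CONTINUOUS_FEATURES",
    "CATEGORICAL_FEATURES",
    "CohortEncoder",
    "EncodingSchema",
    "SchemaError",
    "EncodingError",
    "UntreatedPatientError",
    "fit_schema",
    "encode",
    "plan_of_patient",
]

CONTINUOUS_FEATURES: tuple[str, ...] = (
    "age",
    "bmi",
    "systolic_bp",
    "index_ef",
    "hemoglobin",
    "sodium",
    "cholesterol",
    "lymphocytes",
)

CATEGORICAL_FEATURES: tuple[str, ...] = ("sex", "race", "ethnicity")


class SchemaError(ValueError):
    """Raised when a schema cannot be fitted (e.g. zero-variance feature)."""


class EncodingError(ValueError):
    """Raised on rows that do not conform to the fitted schema."""


class UntreatedPatientError(ValueError):
    """Raised when a patient has no medication start in the treatment window."""


@dataclass
class EncodingSchema:
    """Fitted encoding constants; standardization uses training data only."""

    continuous_stats: dict[str, tuple[float, float]]
    categorical_levels: dict[str, list[str]]
    flag_names: list[str]
    include_plan: bool = False

    @property
    def feature_names(self) -> list[str]:
        names = list(self.continuous_stats)
        for col, levels in self.categorical_levels.items():
            names.extend(f"{col}={lvl}" for lvl in levels[1:])
        names.extend(self.flag_names)
        if self.include_plan:
            names.extend(f"plan_has_{c}" for c in DRUG_CLASSES)
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "continuous_stats": self.continuous_stats,
                    "categorical_levels": self.categorical_levels,
                    "flag_names": self.flag_names,
                    "include_plan": self.include_plan,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EncodingSchema":
        d = json.loads(Path(path).read_text())
        d["continuous_stats"] = {
            k: (float(v[0]), float(v[1])) for k, v in d["continuous_stats"].items()
        }
        return cls(**d)


class CohortEncoder(BaseEstimator, TransformerMixin):
    """Transformer from cohort rows to the numeric feature matrix X.

    Parameters
    ----------
    include_plan
        Add the five drug-class indicators of the patient's plan to the
        feature vector (off by default to keep the label out of X).
    """

    def __init__(self, include_plan: bool = False):
        self.include_plan = include_plan

    def fit(self, X: pd.DataFrame, y=None) -> "CohortEncoder":
        if len(X) < 2:
            raise SchemaError("at least 2 training rows are required")
        stats: dict[str, tuple[float, float]] = {}
        for col in CONTINUOUS_FEATURES:
            vals = pd.to_numeric(X[col], errors="raise").to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise SchemaError(f"continuous feature {col!r} has missing values")
            mean, sd = float(vals.mean()), float(vals.std())
            if sd == 0.0:
                raise SchemaError(f"continuous feature {col!r} has zero variance")
            stats[col] = (mean, sd)
        levels = {
            col: sorted(X[col].astype(str).unique()) for col in CATEGORICAL_FEATURES
        }
        self.schema_ = EncodingSchema(
            continuous_stats=stats,
            categorical_levels=levels,
            flag_names=list(COMORBIDITIES),
            include_plan=self.include_plan,
        )
        self.feature_names_ = self.schema_.feature_names
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        schema = self.schema_
        blocks = []
        for col, (mean, sd) in schema.continuous_stats.items():
            vals = pd.to_numeric(X[col], errors="raise").to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise EncodingError(f"missing value in continuous feature {col!r}")
            blocks.append((vals - mean) / sd)
        for col, levels in schema.categorical_levels.items():
            vals = X[col].astype(str)
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                raise EncodingError(
                    f"unseen level(s) {sorted(unseen)} in categorical {col!r}"
                )
            for lvl in levels[1:]:
                blocks.append((vals == lvl).to_numpy(dtype=float))
        for col in schema.flag_names:
            vals = pd.to_numeric(X[col], errors="raise").to_numpy(dtype=float)
            if np.isnan(vals).any() or not np.isin(vals, (0.0, 1.0)).all():
                raise EncodingError(f"comorbidity flag {col!r} must be 0/1")
            blocks.append(vals)
        if schema.include_plan:
            plans = X["plan"].map(canonical_plan)
            for cls in DRUG_CLASSES:
                blocks.append(
                    plans.map(lambda p: float(cls in p.split("+"))).to_numpy()
                )
        out = np.column_stack(blocks)
        assert not np.isnan(out).any()
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_, dtype=object)


def fit_schema(training: pd.DataFrame, include_plan: bool = False) -> EncodingSchema:
    """Fit z-score constants and one-hot maps on training rows."""
    return CohortEncoder(include_plan=include_plan).fit(training).schema_


def encode(rows: pd.DataFrame, schema: EncodingSchema) -> np.ndarray:
    """Encode cohort rows against a fitted schema."""
    enc = CohortEncoder(include_plan=schema.include_plan)
    enc.schema_ = schema
    enc.feature_names_ = schema.feature_names
    return enc.transform(rows)


def plan_of_patient(
    medications: pd.DataFrame,
    index_date: pd.Timestamp | str,
    window_days: int = 365,
) -> str:
    """Canonical medication plan: distinct drug classes started in the
    treatment window (index date to index + ``window_days``).

    Raises :class:`UntreatedPatientError` when no medication falls in the
    window; such patients are excluded from recommendation training.
    """
    index_date = pd.Timestamp(index_date)
    if "start_parsed" in medications.columns:
        starts = medications["start_parsed"]
    else:
        starts = pd.to_datetime(medications["start_date"], format="ISO8601")
    delta = (starts - index_date).dt.days
    in_window = medications[(delta >= 0) & (delta <= window_days)]
    if in_window.empty:
        raise UntreatedPatientError(
            "no medication start within the treatment window"
        )
    return canonical_plan(in_window["drug_class"])
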