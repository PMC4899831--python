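"""Seeded synthetic heart-failure cohort generator.

Emits the four EHR-style extracts (patients, EF measurements, diagnoses,
medication starts) plus a ground-truth table, with:

* marginal calibration — continuous variables are truncated-normal draws
  with configurable (mean, sd, bounds); comorbidities are Bernoulli flags
  with configurable prevalences;
* a planted latent-group structure — group centroids form a regular
  simplex in the standardized continuous-feature space with pairwise
  distance ``group_separation`` (in within-group-SD units), renormalized
  so the configured marginal moments are preserved exactly;
* a feature -> plan -> response linkage controlled by
  ``plan_match_effect`` (see :class:`GeneratorConfig`), so downstream
  clustering and recommendation have a recoverable ground truth;
* EF trajectories that encode the planted good/poor response label as an
  absolute EF change of >= / < 10 percentage points at a follow-up
  measurement inside the eligibility window.

Identical seeds produce byte-identical extracts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .plans import all_plans, canonical_plan

__all__ = [
    "ContinuousSpec",
    "GeneratorConfig",
    "GeneratorConfigError",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "implied_marginal_moments",
    "read_extracts",
    "COMORBIDITIES",
    "SEPARATED_VARIABLES",
]


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class ContinuousSpec:
    """Truncated-normal specification of one continuous variable."""

    mean: float
    sd: float
    lower: float
    upper: float


#: The 26 CMS Chronic Conditions Data Warehouse comorbidity flags.
COMORBIDITIES: tuple[str, ...] = (
    "acquired_hypothyroidism",
    "alzheimers_disease",
    "alzheimers_related_dementia",
    "anemia",
    "asthma",
    "atrial_fibrillation",
    "benign_prostatic_hyperplasia",
    "breast_cancer",
    "cataract",
    "chronic_kidney_disease",
    "chronic_obstructive_pulmonary_disease",
    "colorectal_cancer",
    "depression",
    "diabetes",
    "endometrial_cancer",
    "glaucoma",
    "hip_pelvic_fracture",
    "hyperlipidemia",
    "hypertension",
    "ischemic_heart_disease",
    "lung_cancer",
    "myocardial_infarction",
    "osteoporosis",
    "prostate_cancer",
    "rheumatoid_arthritis_osteoarthritis",
    "stroke_tia",
)

#: Continuous variables that carry the planted latent-group separation.
#: EF is deliberately excluded: it carries the response trajectory.
SEPARATED_VARIABLES: tuple[str, ...] = (
    "age",
    "bmi",
    "systolic_bp",
    "hemoglobin",
    "sodium",
    "cholesterol",
    "lymphocytes",
)

_INELIGIBLE_MODES = (
    "no_hf_dx",
    "ef_above_50",
    "no_followup",
    "prior_exclusion",
    "incomplete",
)

_BASE_DATE = date(2005, 1, 1)


def _default_continuous_specs() -> dict[str, ContinuousSpec]:
    return {
        "age": ContinuousSpec(77.0, 13.0, 18.0, 110.0),
        "bmi": ContinuousSpec(28.4, 10.8, 12.0, 70.0),
        "systolic_bp": ContinuousSpec(121.0, 23.0, 60.0, 240.0),
        "ef": ContinuousSpec(37.0, 9.8, 5.0, 49.9),
        "hemoglobin": ContinuousSpec(13.0, 1.9, 4.0, 22.0),
        "sodium": ContinuousSpec(140.0, 6.9, 110.0, 170.0),
        "cholesterol": ContinuousSpec(155.0, 42.0, 40.0, 400.0),
        "lymphocytes": ContinuousSpec(1.53, 0.78, 0.05, 6.0),
    }


def _default_prevalences() -> dict[str, float]:
    return {
        "acquired_hypothyroidism": 0.159,
        "alzheimers_disease": 0.499,
        "alzheimers_related_dementia": 0.30,
        "anemia": 0.50,
        "asthma": 0.09,
        "atrial_fibrillation": 0.508,
        "benign_prostatic_hyperplasia": 0.103,
        "breast_cancer": 0.012,
        "cataract": 0.282,
        "chronic_kidney_disease": 0.532,
        "chronic_obstructive_pulmonary_disease": 0.249,
        "colorectal_cancer": 0.009,
        "depression": 0.22,
        "diabetes": 0.406,
        "endometrial_cancer": 0.01,
        "glaucoma": 0.086,
        "hip_pelvic_fracture": 0.05,
        "hyperlipidemia": 0.789,
        "hypertension": 0.828,
        "ischemic_heart_disease": 0.712,
        "lung_cancer": 0.02,
        "myocardial_infarction": 0.281,
        "osteoporosis": 0.127,
        "prostate_cancer": 0.06,
        "rheumatoid_arthritis_osteoarthritis": 0.386,
        "stroke_tia": 0.114,
    }


def _default_plan_frequencies() -> dict[str, float]:
    freqs = {"ACEI+BB+Statin": 0.17, "ACEI+BB": 0.12}
    rest = [p for p in all_plans() if p not in freqs]
    residual = (1.0 - sum(freqs.values())) / len(rest)
    for p in rest:
        freqs[p] = residual
    return freqs


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_patients, seed
        Cohort size and RNG seed (equal seeds give byte-identical output).
    continuous_specs
        Truncated-normal (mean, sd, lower, upper) per continuous variable.
    comorbidity_prevalences
        Bernoulli prevalence per CCW comorbidity flag (26 entries).
    plan_frequencies
        Marginal probability of each canonical medication plan; sums to 1.
    responder_rate
        Marginal probability of a good response (EF gain >= 10 points).
    n_latent_groups, group_separation
        Number of planted phenotype groups and the pairwise distance of
        their centroids in within-group-SD units.
    plan_match_effect
        Uplift of P(good response) when a patient's assigned plan equals
        their group's preferred plan, i.e. P(good|match)-P(good|mismatch).
        It also gates how strongly plan assignment follows the phenotype:
        with probability min(1, effect/linkage_saturation) assignment is
        phenotype-driven — the most feature-typical ``protocol_pool_fraction``
        of each group receive the group's preferred plan and the remainder
        draw a different plan — otherwise plans are drawn from the marginal
        frequencies independent of features.  At effect = 0 plans, features
        and responses are completely unlinked.
    sex_male, race_white, ethnicity_non_hispanic
        Demographic proportions.
    ineligible_fraction
        Fraction of patients constructed to fail eligibility, cycling
        through one violated criterion each (known flag in ground truth).
    """

    n_patients: int = 1386
    seed: int = 0
    continuous_specs: dict[str, ContinuousSpec] = field(
        default_factory=_default_continuous_specs
    )
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=_default_prevalences
    )
    plan_frequencies: dict[str, float] = field(
        default_factory=_default_plan_frequencies
    )
    responder_rate: float = 0.57
    n_latent_groups: int = 4
    group_separation: float = 6.0
    plan_match_effect: float = 0.4
    protocol_pool_fraction: float = 0.2
    linkage_saturation: float = 0.4
    sex_male: float = 0.65
    race_white: float = 0.96
    ethnicity_non_hispanic: float = 0.90
    ineligible_fraction: float = 0.0
    response_threshold: float = 10.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise GeneratorConfigError("n_patients must be a positive integer")
        for name, spec in self.continuous_specs.items():
            if spec.sd <= 0:
                raise GeneratorConfigError(
                    f"continuous_specs[{name!r}].sd must be > 0"
                )
            if spec.lower >= spec.upper:
                raise GeneratorConfigError(
                    f"continuous_specs[{name!r}] bounds must satisfy lower < upper"
                )
        missing = set(SEPARATED_VARIABLES) | {"ef"}
        missing -= set(self.continuous_specs)
        if missing:
            raise GeneratorConfigError(
                f"continuous_specs missing variables: {sorted(missing)}"
            )
        if set(self.comorbidity_prevalences) != set(COMORBIDITIES):
            raise GeneratorConfigError(
                "comorbidity_prevalences must cover exactly the 26 CCW conditions"
            )
        for name, p in self.comorbidity_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(
                    f"comorbidity_prevalences[{name!r}] must be in [0, 1]"
                )
        total = 0.0
        for plan, p in self.plan_frequencies.items():
            canonical_plan(plan)  # raises PlanError on malformed plans
            if p < 0:
                raise GeneratorConfigError(
                    f"plan_frequencies[{plan!r}] must be >= 0"
                )
            total += p
        if abs(total - 1.0) > 1e-9:
            raise GeneratorConfigError("plan_frequencies must sum to 1")
        for name in (
            "responder_rate",
            "plan_match_effect",
            "protocol_pool_fraction",
            "sex_male",
            "race_white",
            "ethnicity_non_hispanic",
            "ineligible_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1]")
        if self.group_separation < 0:
            raise GeneratorConfigError("group_separation must be >= 0")
        if not 1 <= self.n_latent_groups <= len(SEPARATED_VARIABLES):
            raise GeneratorConfigError(
                "n_latent_groups must be between 1 and "
                f"{len(SEPARATED_VARIABLES)} (the separated feature count)"
            )
        if self.linkage_saturation <= 0:
            raise GeneratorConfigError("linkage_saturation must be > 0")

    # -- convenience ----------------------------------------------------
    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def preferred_plans(self) -> list[str]:
        """Preferred plan per latent group: the top-G plans by frequency
        (ties broken by canonical string)."""
        ranked = sorted(self.plan_frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        return [plan for plan, _ in ranked[: self.n_latent_groups]]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["continuous_specs"] = {
            k: [v.mean, v.sd, v.lower, v.upper]
            for k, v in self.continuous_specs.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "continuous_specs" in d:
            d["continuous_specs"] = {
                k: ContinuousSpec(*v) for k, v in d["continuous_specs"].items()
            }
        return cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    """Cohort defaults: published HF-cohort marginals (age 77±13,
    EF 37±9.8, sodium 140±6.9, ...), 57% responder rate, plan frequencies
    skewed to ACEI+BB+Statin (17%) and ACEI+BB (12%)."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# latent-group geometry


def _group_centroids(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Centered latent-group centroids (G x d_sep) with pairwise distance
    ``group_separation``, randomly rotated into the separated-variable space."""
    G = config.n_latent_groups
    d = len(SEPARATED_VARIABLES)
    if G == 1 or config.group_separation == 0:
        rng.standard_normal((d, G))  # keep the RNG stream aligned
        return np.zeros((G, d))
    s = config.group_separation
    verts = (s / np.sqrt(2.0)) * np.eye(G)
    verts -= verts.mean(axis=0)
    q, _ = np.linalg.qr(rng.standard_normal((d, G)))
    return verts @ q[:, :G].T


def _component_params(
    config: GeneratorConfig, centroids: np.ndarray
) -> dict[str, tuple[np.ndarray, float]]:
    """Per-variable (group locations, within-group scale) in original units.

    The between-group variance is folded into the configured marginal
    variance: z = (c_g + eps) / sqrt(1 + b_j) keeps marginal mean/SD at the
    configured values for any separation.
    """
    G = config.n_latent_groups
    between = (centroids**2).sum(axis=0) / G  # per-dimension between-var
    shrink = 1.0 / np.sqrt(1.0 + between)
    params: dict[str, tuple[np.ndarray, float]] = {}
    for j, name in enumerate(SEPARATED_VARIABLES):
        spec = config.continuous_specs[name]
        locs = spec.mean + spec.sd * shrink[j] * centroids[:, j]
        params[name] = (locs, spec.sd * shrink[j])
    ef = config.continuous_specs["ef"]
    params["ef"] = (np.full(G, ef.mean), ef.sd)
    return params


def implied_marginal_moments(config: GeneratorConfig) -> dict[str, tuple[float, float]]:
    """Exact marginal (mean, sd) each continuous variable is drawn with.

    Draws are truncated normals mixed over latent groups, so the implied
    marginal moments differ slightly from the raw configured (mean, sd)
    where the bounds bite (e.g. lymphocytes near 0).  This is the oracle
    the calibration checks compare sample moments against.
    """
    rng = np.random.default_rng(config.seed)
    centroids = _group_centroids(config, rng)
    params = _component_params(config, centroids)
    out: dict[str, tuple[float, float]] = {}
    for name, (locs, scale) in params.items():
        spec = config.continuous_specs[name]
        a = (spec.lower - locs) / scale
        b = (spec.upper - locs) / scale
        m, v = stats.truncnorm.stats(a, b, loc=locs, scale=scale, moments="mv")
        m, v = np.atleast_1d(m), np.atleast_1d(v)
        mix_mean = m.mean()
        mix_var = (v + m**2).mean() - mix_mean**2
        out[name] = (float(mix_mean), float(np.sqrt(mix_var)))
    return out


# ---------------------------------------------------------------------------
# generation


@dataclass
class SyntheticCohort:
    """The four extracts plus ground truth, all plain DataFrames."""

    patients: pd.DataFrame
    ef_measurements: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    ground_truth: pd.DataFrame
    config: GeneratorConfig

    _FILES = (
        "patients",
        "ef_measurements",
        "diagnoses",
        "medications",
        "ground_truth",
    )

    def write(self, outdir: str | Path) -> None:
        """Write the extracts as RFC-4180 CSV with ISO-8601 dates."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._FILES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)


def read_extracts(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Re-read extracts written by :meth:`SyntheticCohort.write`."""
    indir = Path(indir)
    string_cols = ("patient_id", "icd9_code", "drug_class", "date", "start_date")
    out = {}
    for name in SyntheticCohort._FILES:
        path = indir / f"{name}.csv"
        if path.exists():
            out[name] = pd.read_csv(path, dtype={c: str for c in string_cols})
    return out


def _draw_plans(
    config: GeneratorConfig,
    rng: np.random.Generator,
    groups: np.ndarray,
    typicality_rank: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign plans; returns (plan, matched, q) per patient.

    q is each patient's a-priori match probability, used to center the
    response uplift so the marginal responder rate is preserved.
    """
    n = len(groups)
    plans = sorted(config.plan_frequencies)
    freqs = np.array([config.plan_frequencies[p] for p in plans])
    freqs = freqs / freqs.sum()
    preferred = config.preferred_plans()
    pi = min(1.0, config.plan_match_effect / config.linkage_saturation)
    m_star = config.protocol_pool_fraction

    protocol = rng.random(n) < pi
    # feature-typical pool: the m* fraction of each group with the smallest
    # true-metric distance to the group centroid
    pool = np.zeros(n, dtype=bool)
    for g in range(config.n_latent_groups):
        idx = np.flatnonzero(groups == g)
        k = int(round(m_star * len(idx)))
        order = idx[np.argsort(typicality_rank[idx], kind="stable")]
        pool[order[:k]] = True

    assigned = rng.choice(len(plans), size=n, p=freqs)
    plan = np.array(plans, dtype=object)[assigned]
    for g in range(config.n_latent_groups):
        pref = preferred[g]
        in_g = groups == g
        plan[in_g & protocol & pool] = pref
        # phenotype-driven but not in the pool: anything except the
        # preferred plan
        redraw = in_g & protocol & ~pool
        if redraw.any():
            keep = [i for i, p in enumerate(plans) if p != pref]
            f = freqs[keep] / freqs[keep].sum()
            alt = rng.choice(len(keep), size=int(redraw.sum()), p=f)
            plan[redraw] = np.array(plans, dtype=object)[np.array(keep)[alt]]

    pref_of = np.array(preferred, dtype=object)[groups]
    matched = plan == pref_of
    f_pref = np.array([config.plan_frequencies[p] for p in preferred])[groups]
    q = pi * m_star + (1.0 - pi) * f_pref
    return plan, matched, q


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate one synthetic cohort.

    Raises :class:`GeneratorConfigError` on an invalid configuration.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, G = config.n_patients, config.n_latent_groups

    centroids = _group_centroids(config, rng)
    params = _component_params(config, centroids)
    groups = rng.integers(0, G, size=n)

    # continuous variables: truncated normals per latent group
    values: dict[str, np.ndarray] = {}
    for name in (*SEPARATED_VARIABLES, "ef"):
        spec = config.continuous_specs[name]
        locs, scale = params[name]
        col = np.empty(n)
        for g in range(G):
            idx = groups == g
            a = (spec.lower - locs[g]) / scale
            b = (spec.upper - locs[g]) / scale
            col[idx] = stats.truncnorm.rvs(
                a, b, loc=locs[g], scale=scale, size=int(idx.sum()), random_state=rng
            )
        values[name] = col

    flag_names = list(COMORBIDITIES)
    prev = np.array([config.comorbidity_prevalences[c] for c in flag_names])
    flags = rng.random((n, len(flag_names))) < prev

    sex = np.where(rng.random(n) < config.sex_male, "M", "F")
    race_draw = rng.random(n)
    other = (1.0 - config.race_white) / 3.0
    race = np.select(
        [
            race_draw < config.race_white,
            race_draw < config.race_white + other,
            race_draw < config.race_white + 2 * other,
        ],
        ["White", "Black", "Asian"],
        default="Other",
    )
    ethnicity = np.where(
        rng.random(n) < config.ethnicity_non_hispanic, "Non-Hispanic", "Hispanic"
    )

    # true-metric (diagonal Mahalanobis) typicality within each group
    d2 = np.zeros(n)
    for name in SEPARATED_VARIABLES:
        locs, scale = params[name]
        d2 += ((values[name] - locs[groups]) / scale) ** 2
    ef_spec = config.continuous_specs["ef"]
    d2 += ((values["ef"] - ef_spec.mean) / ef_spec.sd) ** 2
    var = np.clip(prev * (1.0 - prev), 1e-6, None)
    d2 += (((flags.astype(float) - prev) ** 2) / var).sum(axis=1)

    plan, matched, q = _draw_plans(config, rng, groups, d2)
    # response uplift of plan_match_effect for matched patients, centered so
    # the marginal responder rate is preserved exactly; degenerate rates
    # (0 or 1) collapse the uplift to keep probabilities feasible
    rr, e = config.responder_rate, config.plan_match_effect
    p_match = np.minimum(1.0, rr + e * (1.0 - q))
    p_mismatch = np.clip((rr - q * p_match) / np.maximum(1.0 - q, 1e-12), 0.0, 1.0)
    p_good = np.where(matched, p_match, p_mismatch)
    response = rng.random(n) < p_good

    # eligibility planting
    failure = np.full(n, "", dtype=object)
    n_bad = int(round(config.ineligible_fraction * n))
    if n_bad:
        bad = rng.choice(n, size=n_bad, replace=False)
        for i, idx in enumerate(np.sort(bad)):
            failure[idx] = _INELIGIBLE_MODES[i % len(_INELIGIBLE_MODES)]
    eligible = failure == ""

    # dates and EF trajectory
    dx_offset = rng.integers(0, 3650, size=n)
    index_lag = rng.integers(0, 21, size=n)
    follow_lag = rng.integers(180, 361, size=n)
    delta = np.where(
        response, 10.5 + rng.exponential(4.0, size=n), rng.uniform(-8.0, 8.5, size=n)
    )
    ef_index = values["ef"].copy()
    high_ef = failure == "ef_above_50"
    ef_index[high_ef] = rng.uniform(52.0, 70.0, size=int(high_ef.sum()))
    ef_follow = np.clip(ef_index + delta, 1.0, 95.0)
    med_lags = rng.integers(0, 181, size=(n, 5))

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    dx_date = np.array([_BASE_DATE + timedelta(days=int(o)) for o in dx_offset])

    patients = pd.DataFrame({"patient_id": ids})
    patients["age"] = np.round(values["age"], 2)
    patients["sex"] = sex
    patients["race"] = race
    patients["ethnicity"] = ethnicity
    patients["bmi"] = np.round(values["bmi"], 2)
    patients["systolic_bp"] = np.round(values["systolic_bp"], 2)
    patients["hemoglobin"] = np.round(values["hemoglobin"], 2)
    patients["sodium"] = np.round(values["sodium"], 2)
    patients["cholesterol"] = np.round(values["cholesterol"], 2)
    patients["lymphocytes"] = np.round(values["lymphocytes"], 3)
    for j, c in enumerate(flag_names):
        patients[c] = flags[:, j].astype(int)
    patients.loc[failure == "incomplete", "sodium"] = np.nan

    ef_rows, dx_rows, med_rows = [], [], []
    for i in range(n):
        pid, mode = ids[i], failure[i]
        t0 = dx_date[i]
        idx_date = t0 + timedelta(days=int(index_lag[i]))
        hf_code = "401.9" if mode == "no_hf_dx" else "428.0"
        dx_rows.append((pid, t0.isoformat(), hf_code))
        if mode == "prior_exclusion":
            dx_rows.append((pid, (t0 - timedelta(days=100)).isoformat(), "425.4"))
        ef_rows.append((pid, idx_date.isoformat(), round(float(ef_index[i]), 1)))
        if mode != "no_followup":
            f_date = idx_date + timedelta(days=int(follow_lag[i]))
            ef_rows.append((pid, f_date.isoformat(), round(float(ef_follow[i]), 1)))
        for k, cls in enumerate(plan[i].split("+")):
            start = idx_date + timedelta(days=int(med_lags[i, k]))
            med_rows.append((pid, cls, start.isoformat()))

    ef_measurements = pd.DataFrame(ef_rows, columns=["patient_id", "date", "ef"])
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "date", "icd9_code"])
    medications = pd.DataFrame(
        med_rows, columns=["patient_id", "drug_class", "start_date"]
    )
    preferred = config.preferred_plans()
    ground_truth = pd.DataFrame(
        {
            "patient_id": ids,
            "latent_group": groups,
            "group_preferred_plan": [preferred[g] for g in groups],
            "assigned_plan": plan,
            "matched": matched.astype(int),
            "response": np.where(response, "good", "poor"),
            "eligible": eligible.astype(int),
            "failure_mode": failure,
        }
    )
    return SyntheticCohort(
        patients, ef_measurements, diagnoses, medications, ground_truth, config
    )
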