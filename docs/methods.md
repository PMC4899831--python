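# Methods

## Scope and model

`simrec` studies similarity-based therapy recommendation in systolic
heart failure (HF).  The object of interest is the map from a patient's
multidimensional record — labs (hemoglobin, sodium, cholesterol,
lymphocytes), vitals (BMI, systolic blood pressure), demographics (age,
sex, race, ethnicity), 26 CMS Chronic-Conditions-Data-Warehouse
comorbidity flags, and ejection fraction (EF) — to the medication plan
(a nonempty subset of {ACEI, ARB, BB, CCB, Statin}) most associated
with a good response, defined as an EF gain of at least 10 percentage
points within 12 months of treatment initiation.

The recommender clusters training *good responders*, labels each cluster
with a plan, and recommends to a new patient the plan of the cluster
minimizing the generalized Mahalanobis distance
d_S(x, C) = sqrt((x − μ_C)ᵀ S (x − μ_C)), S symmetric positive
semi-definite (SPSD).  Poor responders inform evaluation only; a
configuration switch allows clustering all patients for sensitivity
analysis.

## Decisions where the design was genuinely open

* **Response threshold.** "A 10% EF increase" is read as 10 *absolute*
  percentage points (the clinically common convention for EF deltas);
  `relative_response=True` switches to a 10% relative gain.  The
  threshold is a named parameter.
* **Windows.** Day-count arithmetic throughout, for determinism: index
  window ±30 days around the first HF diagnosis, follow-up window
  [180, 450] days after the index EF (closed), response window 365 days.
  Treatment initiation defaults to the index-EF date; the earliest
  medication start is available as an alternative.
* **Exclusion diagnoses.** The ICD-9 code lists behind the named
  exclusion conditions are an editorial default (prefixes 414, 422, 425,
  424.1, 394.0, 396), exposed as a parameter.  Same-day exclusion
  diagnoses do not count as "prior".
* **Medications as labels, not features.** Drug classes define the label
  y_i and are excluded from X_i to avoid label leakage;
  `include_plan=True` re-adds them for replication experiments.  Dosage
  is out of scope: plans are drug-class sets.
* **Construction of S.** Unspecified by the problem statement; the
  default is the pseudo-inverse of the pooled within-cluster covariance
  shrunk toward its diagonal, (1 − λ)Σ̂ + λ·diag(Σ̂), λ = 0.1.  Shrinkage
  stabilizes the inverse at d = 39 with a few hundred training points;
  the pseudo-inverse covers residual rank deficiency.  `identity` gives
  the scale-free Euclidean special case (features are z-scored, so this
  degrades gracefully); per-cluster inverses are offered but flagged —
  distances to different clusters are then not a single metric.
* **The radical.** d_S applies the square root.  Since sqrt is monotone,
  rankings — and therefore every recommendation — are identical with or
  without it (property-tested).
* **Tie-breaks**, all deterministic: equal recommendation distances
  prefer the larger cluster, then the lexicographically smaller plan;
  modal-plan labeling breaks ties by global plan frequency, then
  lexicographically; merging absorbs the smallest cluster first and
  prefers maximal Jaccard, then strict superset plans, then the larger
  target.  If no cluster reaches the 5% floor, the smallest pair is
  merged (fallback; merging never fails and strictly reduces the cluster
  count, so it terminates).
* **Evaluation protocol.** "Repeated cross-validation at 70/30" is
  realized as 10 seeded stratified 70/30 splits (stratified on response),
  averaged.  With n = 1386 this gives exactly 970 train / 416 test.
* **Positive class and ROC.** The outcome is *plan match among good
  responders*: outcome 1 iff the patient responded well AND the
  recommended plan equals the observed plan.  This retrospective
  plan-match reading (rather than a counterfactual "response to the
  recommended therapy", which the data cannot identify) determines all
  reported metrics and is therefore stated prominently.  The confidence
  score is the negative winning distance.  Operating-point metrics are
  taken at the first cut point (the 50th score percentile); the AUC is
  the trapezoidal area over the ROC traced at every distinct score,
  asserted equal (to 1e-9) to the Mann–Whitney statistic at run time.

## The synthetic cohort generator

The generator emulates the study conditions so every stage has a
testable ground truth.

* **Marginals.**  Continuous variables are truncated normals with the
  cohort-characteristic moments (age 77±13 y, BMI 28.4±10.8 kg/m²,
  systolic BP 121±23 mmHg, EF 37±9.8%, hemoglobin 13±1.9 g/dL, sodium
  140±6.9 mEq/L, cholesterol 155±42 mg/dL, lymphocytes 1.53±0.78 ×10⁹/L)
  and physiological bounds; comorbidities are Bernoulli flags at the
  published prevalences.  Where the source table is garbled the defaults
  are editorial and overridable: sex 65% male, ethnicity 90%
  non-Hispanic, anemia prevalence 0.5; the four CCW conditions the table
  omits (Alzheimer-related dementia, endometrial cancer, lung cancer,
  hip/pelvic fracture) default to 0.30/0.01/0.02/0.05.
* **Calibration oracle.**  Because draws are truncated, sample moments
  are compared against the *implied* truncated-mixture moments
  (`implied_marginal_moments`), computed exactly with
  `scipy.stats.truncnorm`.  For wide-bounded variables these coincide
  with the configured values (age: 76.93/12.87 vs 77/13); for variables
  with a binding bound (lymphocytes at 0; EF capped below 50) the
  implied moments are the honest target.
* **Latent groups.**  `n_latent_groups` phenotype centroids form a
  regular simplex with pairwise distance `group_separation` in units of
  the within-group SD, randomly rotated into the 7 non-EF continuous
  dimensions.  The between-group variance is folded back so the marginal
  mean/SD of every variable is preserved *exactly*, independent of the
  separation.  EF carries the response trajectory instead and is
  group-independent.
* **Plans, response, and the linkage.**  Each group's *preferred plan*
  is one of the top plans by configured frequency (`ACEI+BB+Statin`
  ≈ 17%, `ACEI+BB` ≈ 12%, the remainder uniform over the other nonempty
  subsets — only the top of the plan distribution is published).
  `plan_match_effect` (e) controls the feature→plan→response linkage:
  with probability min(1, e/0.4) a patient's plan assignment is
  *phenotype-driven* — the 20% of each group most typical of their
  phenotype (smallest true-metric Mahalanobis distance to the group
  centroid) receive the preferred plan, the rest draw a different plan —
  otherwise plans follow the marginal frequencies.  Matched patients'
  response probability is uplifted by exactly e over mismatched ones,
  centered so the marginal responder rate stays at 57% (degenerate rates
  0/1 collapse the uplift to stay feasible).  At e = 0, plans, features
  and responses are mutually independent, which is what makes the null
  calibration of the evaluation meaningful; at e ≥ 0.4 the structure is
  recoverable end to end.  The saturation at 0.4 ties "fully
  phenotype-driven prescribing" to the regime where recovery is
  expected.  This confounding-by-indication construction is what gives
  the distance score predictive power over the plan-match outcome: a
  constant response uplift alone would leave the score independent of
  the outcome.
* **Trajectories and events.**  Index EF is drawn below 50; good
  responders get a follow-up EF at +10.5 + Exp(4) points, poor
  responders at +U(−8, 8.5), 180–360 days after the index measurement,
  so labels survive rounding and the 365-day response window.
  Diagnosis, EF and medication-start dates are uniform within the
  eligibility windows; `ineligible_fraction` plants patients violating
  one criterion each (missing HF code, index EF ≥ 50, no follow-up,
  prior exclusion diagnosis, missing lab) with known flags.
* **Determinism.** One `numpy` Generator seeds everything; equal seeds
  give byte-identical CSV extracts.

What the generator does **not** emulate: longitudinal coding noise,
censoring, visit irregularity, inter-variable clinical correlations
(a correlation hook ships as identity), dosages, and ICD-10.  Passing
tests therefore demonstrate correctness of the pipeline's logic and its
behavior under known structure — not clinical performance on real EHR
data, where the feature–treatment–response linkage is far weaker and
confounded.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at n = 1386 (the study
size), n = 2000 for planted-recovery checks (4 groups, separation 8,
e = 0.5), n = 4000 × 20 seeds for the null calibration (the larger
cohort shrinks the finite-sample bias of estimated centroids and labels,
which is O(1/n) and positive), and n = 5000 for marginal-calibration
checks at 3-standard-error tolerance.  Quadratic forms are clamped to
zero when within −1e-10 of it; SPSD validation requires symmetry to
1e-10 and eigenvalues ≥ −1e-8.  Zero-variance features, unseen
categorical levels, untreated patients, single-class outcome vectors and
malformed records all raise typed errors (malformed records additionally
land in a validation report; they are never silently dropped).

## Known limitations

* Supervised clustering scores *below* the unsupervised methods on
  planted cohorts: after 28 plan-pure clusters are merged down, cluster
  membership no longer tracks phenotype, while k-means/Ward clusters do.
  On real data with many plan-specific subpopulations the ordering may
  differ; the package reports all three.
* The plan-match outcome undercounts clinically equivalent plans
  (a recommended superset of the observed plan counts as a mismatch).
* The null end-to-end AUC has a small positive finite-sample bias
  (≈ +0.01 at n = 2000, ≈ +0.007 at n = 4000) because cluster labels and
  centroids are estimated from the same training data; it vanishes as n
  grows and is absent from the AUC computation itself (verified on
  synthetic scores).
* Eligibility uses ICD-9 prefix matching only; no hierarchy traversal or
  code-system translation.
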