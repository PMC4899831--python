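# simrec — patient-similarity analytics for heart-failure therapy recommendation

`simrec` implements a multidimensional patient-similarity framework for
recommending heart-failure (HF) medication plans from EHR-style tabular
extracts.  It is aimed at clinical-informatics researchers who want to
study similarity-based treatment recommendation end to end — cohort
phenotyping, clustering of treatment responders, metric-based
recommendation, and cross-validated evaluation — without access to
protected patient data: a calibrated synthetic cohort generator with a
planted, recoverable ground truth stands in for the EHR.

## The method

**Cohort.** From four extracts (patients, EF measurements, diagnoses,
medication starts), the analysis cohort is the set of patients with
(1) an HF diagnosis (ICD-9-CM 428.x), (2) an ejection fraction (EF)
below 50% within 30 days of it (the *index* EF), (3) another EF
measurement 180–450 days later, and (4) no prior coronary artery
disease, myocarditis, cardiomyopathy or aortic/mitral stenosis.  A
patient is a **good responder** if the follow-up EF exceeds the index EF
by ≥ 10 percentage points within 12 months of treatment initiation.

**Features and labels.** Each patient i is encoded as a vector
X_i ∈ R^d (z-scored labs/vitals/EF/age, one-hot demographics, 26
CMS-CCW comorbidity flags; d = 39).  The label y_i is the **medication
plan**: the set of drug classes started in the treatment window, a
nonempty subset of {ACEI, ARB, BB, CCB, Statin} written canonically,
e.g. `ACEI+BB+Statin`.

**Clusters.** Training good responders are clustered three ways:
k-means (k-means++ init), Ward hierarchical clustering (both at k = 7 by
default, labeled with each cluster's most frequent plan), or
*supervised* clustering — one cluster per distinct plan.  Clusters
holding < 5% of the training population are absorbed, smallest first,
into the large cluster whose label plan is most similar (Jaccard
similarity of drug-class sets, supersets preferred): a small
{ACEI, CCB, Statin} cluster merges into {ACEI, BB, CCB, Statin}.

**Recommendation.** For a new patient x, the similarity to each cluster
C with centroid μ is the generalized Mahalanobis distance

    d_S(x, C) = sqrt( (x − μ)ᵀ S (x − μ) ),

with S symmetric positive semi-definite — by default the pseudo-inverse
of the shrunk pooled within-cluster covariance (identity available, in
which case d_S is the Euclidean distance).  Clusters are ranked by
distance and the nearest cluster's plan is recommended.

**Evaluation.** Ten seeded stratified 70/30 splits; for every test
patient the binary outcome is *plan match among good responders*
(outcome 1 iff the patient responded well and the recommendation equals
the observed plan) and the confidence score is the negative winning
distance.  Specificity, sensitivity, F1 and accuracy are reported at the
50th score percentile; the AUC integrates the full ROC and is
cross-checked against the Mann–Whitney formulation.

## Worked example

```python
import simrec

cfg = simrec.default_config(seed=1)          # n = 1386 patients
syn = simrec.generate_cohort(cfg)
cohort, exclusions, _ = simrec.build_cohort({
    "patients": syn.patients,
    "ef_measurements": syn.ef_measurements,
    "diagnoses": syn.diagnoses,
    "medications": syn.medications,
})
print(f"cohort: {len(cohort)} eligible, "
      f"{(cohort.response == 'good').mean():.1%} good responders")
print(f"most frequent plan: {cohort['plan'].value_counts().idxmax()}")

report = simrec.evaluate_methods(cohort, simrec.EvaluationConfig(seed=1))
cols = ["method", "specificity_mean", "sensitivity_mean", "f1_mean",
        "accuracy_mean", "auc_mean"]
print(report.summary[cols].round(2).to_string(index=False))
```

prints

```
cohort: 1386 eligible, 54.2% good responders
most frequent plan: ACEI+BB+Statin
      method  specificity_mean  sensitivity_mean  f1_mean  accuracy_mean  auc_mean
  supervised              0.57              0.87     0.42           0.62      0.84
hierarchical              0.59              0.93     0.48           0.65      0.90
      kmeans              0.59              0.94     0.49           0.65      0.91
```

The cohort's responder share and plan mix track the generator's
configured marginals (57% responders; `ACEI+BB+Statin` the modal plan at
≈ 17%).  The AUCs quantify how well the negative winning distance
separates plan-matched good responders from everyone else; on synthetic
cohorts with a planted feature→plan→response linkage the unsupervised
pipelines recover the structure almost perfectly, while supervised
plan-clusters conflate phenotype groups after merging and score lower.

The same pipeline is scriptable from the shell:

```bash
simrec simulate --seed 3 --n 800 --out extracts
simrec build-cohort --in extracts --out cohortdir
simrec train --cohort cohortdir/cohort.csv --method supervised --seed 1 --out model
simrec recommend --model model --patients cohortdir/cohort.csv --out recs.csv
simrec evaluate --cohort cohortdir/cohort.csv --seed 2 --out report
```

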