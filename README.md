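# survscale

Outcome-supervised feature scaling and consensus k-medians clustering for
right-censored survival cohorts, with a cross-validated Cox model-comparison
harness.

## The problem

Clustering groups patients by feature similarity, but plain (unsupervised)
clusters need not relate to the outcome a clinician cares about. When the
outcome is a right-censored time-to-event — overall or relapse-free survival
in an oncology cohort where ~80% of patients never experience the event
during follow-up — supervising the grouping is awkward: most subjects have
no observed event time to regress on.

`survscale` implements a simple, effective resolution. Every subject — also
a censored one — has a **null-model martingale residual**

&nbsp;&nbsp;&nbsp;&nbsp; M&#7522; = δ&#7522; − Λ̂(t&#7522;),

the observed event count minus the Nelson–Aalen cumulative hazard at their
follow-up time (values in (−∞, +1], summing to zero). These residuals are a
censoring-aware continuous proxy for "excess risk". The pipeline is:

1. min–max standardize each feature to [0, 1] (training ranges reused on
   held-out rows, then clipped);
2. fit an ordinary least-squares regression of the martingale residuals on
   the standardized features;
3. multiply each feature column by the magnitude of its fitted coefficient —
   features unrelated to the outcome shrink out of the geometry;
4. cluster the scaled space with **consensus k-medians** (k-means++-style
   seeding, Manhattan distance, coordinate-wise median updates; many
   subsampled runs accumulated into a consensus matrix, final clusters
   extracted by average-linkage hierarchical clustering on 1 − consensus);
5. assign held-out subjects to the nearest cluster median and evaluate the
   labels in Cox proportional-hazards models against clinical baselines
   (AIC/AICc, likelihood-ratio tests, hazard-ratio intervals, C-index,
   IPCW Brier score, time-dependent AUC, Nam–D'Agostino calibration,
   Kaplan–Meier curves with log-rank tests, adjusted Rand index).

Supporting stages match common practice for this kind of cohort: chained
predictive-mean-matching imputation (validation rows imputed individually
against the completed training matrix), zero-variance/correlation redundancy
filters, and RReliefF feature weighting against the residuals.

A synthetic-cohort generator with two latent risk groups (configurable
hazard ratio, feature separation, censoring fraction, missingness) provides
ground truth for every stage.

## Worked example

Generate a 600-subject cohort (two latent groups, hazard ratio 3, ~80%
censoring, 13% missingness on the continuous features), run the 10-fold
cross-validated pipeline, and score the held-out cluster labels:

```bash
cat > cohort.yaml <<EOF
n_subjects: 600
group_separation: 2.0
latent_hazard_ratio: 3.0
EOF
cat > pipeline.yaml <<EOF
k_folds: 10
consensus_runs: 100
rrelieff_top_m: null
EOF

survscale generate --out cohort.csv --config cohort.yaml --seed 1
# wrote 600 subjects (80.5% censored) to cohort.csv
survscale run --cohort cohort.csv --config pipeline.yaml --seed 1 --out-dir out
survscale metrics --cohort cohort.csv --labels out/labels.csv --out-dir out
```

```json
{
  "cluster_sc":    { "logrank_chi2": 23.37, "logrank_p": 1.34e-06, "ari_vs_latent": 0.623 },
  "cluster_stand": { "logrank_chi2": 11.49, "logrank_p": 7.01e-04, "ari_vs_latent": 0.298 }
}
```

The supervised-scaled labels (`cluster_sc`) separate survival far more
sharply than the standardization-only ablation (`cluster_stand`) and track
the latent truth twice as well (adjusted Rand index 0.62 vs 0.30). The model
comparison (`survscale compare`) makes the same point through Cox fits on
the full cohort with the fold-assigned labels as a covariate:

| model                      | −ΔAIC vs clinical | LRT p  | cluster HR 95% CI | AUC    | Brier  | C-index |
|----------------------------|-------------------|--------|-------------------|--------|--------|---------|
| Clin. & Rad.               | +10.54            | 8.0e-4 | —                 | 0.6802 | 0.0977 | 0.6743  |
| Clin. & [Sc.] Cluster      | +13.58            | 1.0e-4 | [0.22, 0.61]      | 0.6388 | 0.0980 | 0.6374  |
| Clin. & [Stand.] Cluster   | −0.10             | 0.17   | [0.32, 1.23]      | 0.6216 | 0.0985 | 0.6204  |

Adding the scaled-cluster label to the clinical model improves AIC by well
over the conventional meaningful margin of 3 and carries a significant
hazard ratio, while the standardization-only label adds nothing — the
pattern the method is designed to produce. (Cluster numbering is arbitrary,
so the hazard ratio may land on either side of 1.)

The same functionality is available as a library:

```python
from survscale import CohortConfig, PipelineConfig, generate_cohort, run_cv

cohort = generate_cohort(CohortConfig(n_subjects=600, group_separation=2.0, seed=1))
cv = run_cv(cohort, PipelineConfig(k_folds=10, consensus_runs=100,
                                   rrelieff_top_m=None, seed=1))
cv.scaled_labels       # one held-out cluster label per subject
```

All transform stages (`RangeScaler`, `PMMImputer`, `VarianceCorrelationFilter`,
`RReliefF`, `SupervisedScaler`, `KMedians`, `ConsensusKMedians`) are
scikit-learn-style estimators with `fit`/`transform`/`predict` and fitted
attributes, and compose with sklearn pipelines.

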