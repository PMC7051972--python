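# Methods

## Model and procedure

The package targets cohorts with right-censored time-to-event outcomes: for
subject *i* we observe a follow-up time *t&#7522;* and an event indicator
*δ&#7522;* ∈ {0, 1}. The goal is a two-group stratification of the feature
space that is prognostic for the outcome despite heavy (~80%) censoring.

**Martingale residual proxy.** For a Cox model with cumulative baseline
hazard Λ₀ and linear predictor β′Z, the martingale residual is
N&#7522;(t) − ∫ Y&#7522;(s) e^{β′Z&#7522;(s)} dΛ₀(s). With no covariates
(β = 0) the model's cumulative hazard is estimated by Nelson–Aalen, so the
residual reduces to the closed form **M&#7522; = δ&#7522; − Λ̂(t&#7522;)**
with Λ̂(t) = Σ_{s ≤ t} d_s / n_s (d_s events among n_s at risk, ties
aggregated; the at-risk set at time s is {i : t&#7522; ≥ s}). Residuals lie
in (−∞, +1] and sum to zero exactly — both properties are asserted in the
test suite on arbitrary inputs. A subject censored early has a residual near
0 (no information), a subject with an early event a residual near +1
(excess risk), a long-surviving censored subject a negative residual.

**Supervised scaling.** The residuals are regressed on the min–max
standardized features by ordinary least squares with an intercept. Column
*j* of the standardized matrix is then multiplied by |β̂&#11388;|. The
magnitude is used because Manhattan distances satisfy |w|·|x − y|
regardless of sign — a signed weight could only flip a coordinate, never
change a distance — and the intercept is never applied because it shifts
all points equally. A rank-deficient design is refused (coefficients not
identified) with the collinear columns named. No regularization is applied.

**Consensus k-medians.** The scaled space is clustered with k-medians:
k-means++-style seeding (squared-Manhattan-distance sampling), assignment
to the nearest median under the Manhattan metric (ties to the lowest
cluster index), coordinate-wise median updates (even-sized sets: mean of
the two middle values), iterated until the labels stabilize. An emptied
cluster is reseeded with the point farthest from its current median. To
remove seeding sensitivity, the production path runs many k-medians
passes over random 80% subsamples of the subjects and accumulates

&nbsp;&nbsp;&nbsp;&nbsp; consensus(i, j) = Σ_h M⁽ʰ⁾(i, j) / Σ_h I⁽ʰ⁾(i, j),

where I⁽ʰ⁾ marks pairs co-sampled in run *h* and M⁽ʰ⁾ pairs additionally
co-clustered. The matrix is symmetric with unit diagonal and entries in
[0, 1]; a pair never co-sampled is an error (raise the run count). Final
clusters are extracted by average-linkage agglomerative clustering on
1 − consensus cut at k (default k = 2), and the cluster medians are
recomputed from the extracted member sets. Held-out subjects take the
label of the nearest median.

**Cross-validation protocol.** Subjects are partitioned into k folds (10 by
default) uniformly at random under the master seed. Per fold, every stage —
PMM imputation, standardization ranges, residuals, optional RReliefF
selection, scaling weights, consensus clustering — is fit on the training
subjects only; each validation row is imputed *individually* against the
completed training matrix, standardized with training ranges (clipped to
[0, 1]), scaled with training weights and assigned to the nearest training
median. Because two-cluster numbering is arbitrary, each fold's labeling is
aligned to fold 1 by majority agreement on the shared training subjects
(below one-half agreement the labels are inverted; an exact tie keeps
them), with validation labels inverted in lockstep. A parallel
standardization-only route (identical, minus the scaling step) provides the
ablation. Every subject ends up with exactly one held-out label per route.

**Model comparison.** A roster of Cox models (Efron tie handling, via
lifelines) is fit on the full cohort — clinical covariates only, clinical
plus the continuous-feature signature, clinical plus either cluster label,
cluster labels alone, plus staging-variable variants when such a column is
supplied. AIC = 2p − 2lnL̂ and AICc = AIC + (2p² + 2p)/(n − p − 1) are
reported relative to the clinical and to the null baseline as the negated
difference (positive = better; differences ≥ 3 treated as meaningful), with
likelihood-ratio tests where the baseline is nested. Predictive metrics use
each model's full-data linear predictor; event-by-horizon probabilities
come from the Breslow baseline hazard, 1 − exp(−Λ̂₀(τ) e^{lp}). AUC, Brier
and C-index are computed per cross-validation fold on that fold's held-out
subjects and aggregated as mean ± standard error; calibration is a single
pooled statistic.

## Evaluation metrics

* **C-index** enumerates ordered pairs: a pair is evaluable when both
  subjects have events (and distinct times), or when exactly one is
  censored at a time no earlier than the other's event (at a tie the event
  is taken to occur first). Risk ties count 1/2. The implementation is the
  direct O(n²) enumeration (vectorized) and is tested for exact agreement
  with scikit-survival's estimator.
* **IPCW weights** use the Kaplan–Meier estimate Ĝ of the censoring
  distribution (event/censoring roles swapped), evaluated left-continuously:
  subjects with an event by the horizon weigh 1/Ĝ(t&#7522;⁻), subjects at
  risk past it weigh 1/Ĝ(τ), subjects censored earlier weigh 0. The Brier
  score is the weighted mean of (status − prediction)²; with no censoring
  it reduces to the plain mean squared error (0 for a perfect model, 0.25
  for a constant 1/2). The cumulative/dynamic AUC weights cases by
  1/Ĝ(t&#7522;⁻) (the shared control weight cancels) and reduces to the
  Mann–Whitney statistic without censoring.
* **Nam–D'Agostino calibration** bins subjects by deciles of predicted
  risk; per bin, observed = 1 − KM(τ) within the bin, expected = mean
  prediction; the statistic Σ n_d (O_d − E_d)²/(E_d(1 − E_d)) is referred
  to χ² with (bins − 2) degrees of freedom (10 bins → 8 df).
* **Adjusted Rand index** is the Hubert–Arabie chance-corrected pair
  agreement (via scikit-learn, brute-force pair counting as the test
  oracle).

## Synthetic cohorts

The generator emulates the statistical shape of a retrospective oncology
cohort: ~640 subjects; two equiprobable latent risk groups with exponential
event times whose hazards differ by a configurable ratio (default 3, the
2–4 range typical of strong prognostic splits); independent exponential
censoring whose rate is solved numerically (Brent) so the realized
censoring fraction matches the target (default 79.4%); ~8 binary clinical
covariates, 4 informative continuous "radiomic-like" features, 4 pure-noise
continuous features; 13.1% MCAR missingness on the continuous features.
The default low-risk hazard (0.0011/month) puts the median observed
follow-up near 65 months so that a 5-year (60-month) evaluation horizon is
informative.

Group 2 shifts the informative continuous features by `group_separation`
(in within-group standard deviations) and the binary prevalences by half
that amount on the logit scale: in the cohorts this emulates, clinical
covariates are distinctly weaker correlates of the latent risk grouping
than the engineered continuous features (the strongest clinical contrast
between observed risk groups is roughly a one-unit logit shift, most far
smaller), and full-strength binary shifts would make the unsupervised
geometry unrealistically informative, erasing the scaled-vs-standardized
contrast the method exists to demonstrate.

What the generator does **not** emulate: correlated radiomic feature blocks
(real radiomic panels are massively redundant; the correlation filters are
therefore tested on purpose-built fixtures), covariate-dependent (MAR/MNAR)
missingness, competing risks, non-proportional hazards, and administrative
(fixed-date) censoring. Passing tests on these cohorts show the pipeline
recovers latent proportional-hazards group structure under heavy random
censoring; they do not certify behaviour under informative censoring or
non-proportional effects.

## Numerical choices and edge cases

* Constant columns standardize to 0; validation values outside the training
  range are clipped to [0, 1] to keep distances bounded.
* PMM: 5 chained cycles, initial fill = column median, k = 5 donors, donor
  drawn uniformly among the k nearest predictions; imputed values always
  belong to the column's observed support. Validation rows use per-row
  random streams keyed by the row label, so imputation is independent of
  presentation order.
* Duplicate-correlation filtering keeps the earlier column in input order;
  Pearson correlation throughout.
* RReliefF: 1000 iterations, k = 10 neighbours, exponential distance-rank
  influence with σ = 20; weights W[A] = P(diff A | diff target, near) −
  P(diff A | same target, near) lie in [−1, 1], constants get exactly 0.
  Being a local method, it detects features that drive *nearby* target
  variation; a global mean shift between two well-separated blobs is
  invisible to it, which is why the cross-validation pipeline makes the
  selection step optional (`rrelieff_top_m=None`) and the synthetic study
  runs — whose continuous pool is already small — skip it.
* k-medians cost is non-increasing across assignment/update iterations
  (asserted); `init="exhaustive"` (k = 2) restarts from every bipartition's
  medians and provably attains the global-optimum cost on tiny instances,
  which the oracle-equivalence tests exploit.
* Log-rank p-values come from the χ² upper tail with (groups − 1) df; no
  continuity corrections. Cox fits use Efron tie handling; non-convergence
  reports monotone likelihood as the likely cause.
* Subjects with t = 0 and an event are kept; the at-risk convention is
  left-closed (t&#7522; ≥ s).
* All stage seeds derive from the master seed through `SeedSequence`
  (fold- and stage-tagged), making the pipeline bit-reproducible.

## Problem sizes used in the test suite

Unit tests run on purpose-built fixtures of 3–400 subjects. The end-to-end
recovery study uses 20 cohorts of n = 600 at hazard ratio 3, separation 2
and ~80% censoring with 10 folds and 100 consensus runs per fold — 100 runs
(rather than the production default of 1000) is the package's chosen
desk-scale setting; measured agreement between consensus and single-run
k-medians labels on these cohorts shows no quality loss. Null-behaviour
calibration uses 100 structure-free cohorts of n = 240. The acceptance
script simulates 100 cohorts of n = 500.

## Known limitations

* The supervised scaler is plain OLS: with heavy censoring the residual
  signal is weak, so noise features can draw coefficient magnitudes
  comparable to the diluted per-feature signal of several correlated
  informative features. This attenuates cluster accuracy on unlucky draws;
  a shrinkage variant would trade faithfulness for stability and is
  deliberately not implemented.
* Fold-label matching is defined for two clusters only, as is the
  production default; k > 2 clustering works but cross-fold alignment must
  then be handled by the caller.
* AICc requires n > p + 1; the comparison table reports per-model values
  only where defined.
* The two-sided 95% hazard-ratio intervals use the normal approximation
  exp(β̂ ± 1.96·se).
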