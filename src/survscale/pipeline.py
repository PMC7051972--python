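"""Cross-validated supervised-scaled clustering and Cox model comparison.

:func:`run_cv` executes the full per-fold pipeline — train-only PMM
imputation, min-max standardization on training ranges, null-model
martingale residuals, optional RReliefF selection of the continuous
feature signature, supervised scaling, consensus k-medians, fold-label
alignment and nearest-median assignment of validation subjects — and
returns one cluster label per subject, assigned while that subject was
held out.  A parallel "standardization-only" route (identical but with
the supervised scaling step skipped) provides the ablation the method is
judged against.

:func:`compare_models` then fits a roster of Cox models on the full
cohort, with the fold-assigned cluster labels as an extra covariate where
named, and reports information criteria relative to the clinical and null
baselines, likelihood-ratio tests, cluster hazard-ratio intervals, and
fold-wise predictive metrics (AUC, Brier, C-index) plus a pooled
calibration statistic at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as ev
from .cluster import ConsensusKMedians, match_fold_labels
from .preprocessing import PMMImputer, RangeScaler, RReliefF
from .scaling import SupervisedScaler
from .survival import breslow_cumhaz, cox_fit, null_martingale_residuals
from .synthetic import SurvivalCohort

__all__ = ["PipelineConfig", "CVResult", "run_cv", "run_fold", "compare_models",
           "default_roster"]


@dataclass
class PipelineConfig:
    """Knobs of the cross-validated experiment.

    ``clinical_features`` / ``radiomic_features`` name the column roles; if
    left ``None`` they are inferred from the ``clin_`` prefix (clinical)
    with every other column treated as part of the continuous feature pool.
    ``rrelieff_top_m = None`` disables feature selection (sensible when the
    continuous pool is already small); the study-scale default keeps the
    top 4 of the pool.
    """

    outcome: str = "os"
    k_folds: int = 10
    n_clusters: int = 2
    consensus_runs: int = 1000
    subsample_fraction: float = 0.8
    rrelieff_top_m: int | None = 4
    rrelieff_iterations: int = 1000
    rrelieff_k_neighbors: int = 10
    pmm_k: int = 5
    horizon: float = 60.0
    seed: int = 0
    clinical_features: list[str] | None = None
    radiomic_features: list[str] | None = None

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")

    def roles(self, columns) -> tuple[list[str], list[str]]:
        columns = list(columns)
        clinical = (self.clinical_features if self.clinical_features is not None
                    else [c for c in columns if c.startswith("clin_")])
        radiomic = (self.radiomic_features if self.radiomic_features is not None
                    else [c for c in columns if c not in clinical])
        missing = [c for c in clinical + radiomic if c not in columns]
        if missing:
            raise ValueError(f"configured features absent from cohort: {missing}")
        return clinical, radiomic

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class FoldArtifacts:
    fold: int
    train_index: pd.Index
    selected_features: list[str]
    scaling_weights: pd.Series
    train_labels_scaled: pd.Series
    train_labels_standardized: pd.Series
    val_labels_scaled: pd.Series
    val_labels_standardized: pd.Series


@dataclass
class CVResult:
    scaled_labels: pd.Series
    standardized_labels: pd.Series
    fold_assignments: pd.Series
    folds: list[FoldArtifacts] = field(default_factory=list)


def _stage_seed(base: int, *tags: int) -> int:
    ss = np.random.SeedSequence([base, *tags])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_fold(cohort: SurvivalCohort, train_index, val_index,
             config: PipelineConfig, fold: int) -> FoldArtifacts:
    """Train every stage on the training subjects only, then place the
    held-out subjects.  Validation rows are imputed individually against the
    completed training matrix and standardized with training ranges, so no
    information flows out of the held-out set."""
    clinical, radiomic = config.roles(cohort.features.columns)
    pool = clinical + radiomic
    train_X = cohort.features.loc[train_index, pool]
    val_X = cohort.features.loc[val_index, pool]
    t_tr = cohort.time.loc[train_index].to_numpy()
    e_tr = cohort.event.loc[train_index].to_numpy()

    imputer = PMMImputer(k_donors=config.pmm_k,
                         random_state=_stage_seed(config.seed, fold, 1))
    train_complete = imputer.fit_transform(train_X)
    val_complete = imputer.transform(val_X) if len(val_X) else val_X

    scaler = RangeScaler().fit(train_complete)
    train_std = scaler.transform(train_complete)
    val_std = scaler.transform(val_complete) if len(val_complete) else val_complete

    residuals = null_martingale_residuals(t_tr, e_tr)

    selected = pool
    if config.rrelieff_top_m is not None and len(radiomic) > config.rrelieff_top_m:
        relief = RReliefF(
            n_iterations=config.rrelieff_iterations,
            k_neighbors=config.rrelieff_k_neighbors,
            random_state=_stage_seed(config.seed, fold, 2),
        ).fit(train_std[radiomic], residuals)
        selected = clinical + relief.top_features(config.rrelieff_top_m)
    train_sel, val_sel = train_std[selected], (val_std[selected] if len(val_std) else val_std)

    sup = SupervisedScaler().fit(train_sel, residuals)
    train_scaled = sup.transform(train_sel)

    def _cluster(train_pts, val_pts, tag):
        model = ConsensusKMedians(
            n_clusters=config.n_clusters,
            n_runs=config.consensus_runs,
            subsample_fraction=config.subsample_fraction,
            random_state=_stage_seed(config.seed, fold, tag),
        ).fit(train_pts)
        tr = pd.Series(model.labels_, index=train_pts.index)
        va = (pd.Series(model.predict(val_pts), index=val_pts.index)
              if len(val_pts) else pd.Series(dtype=int))
        return tr, va

    tr_sc, va_sc = _cluster(train_scaled, sup.transform(val_sel) if len(val_sel) else val_sel, 3)
    tr_st, va_st = _cluster(train_sel, val_sel, 4)

    return FoldArtifacts(
        fold=fold,
        train_index=pd.Index(train_index),
        selected_features=list(selected),
        scaling_weights=sup.weights_.coefficients.copy(),
        train_labels_scaled=tr_sc,
        train_labels_standardized=tr_st,
        val_labels_scaled=va_sc,
        val_labels_standardized=va_st,
    )


def _align(art: FoldArtifacts, ref_scaled: pd.Series, ref_std: pd.Series) -> None:
    """Match this fold's labelings (train + validation jointly) to fold 1."""
    for attr_tr, attr_va, ref in (
        ("train_labels_scaled", "val_labels_scaled", ref_scaled),
        ("train_labels_standardized", "val_labels_standardized", ref_std),
    ):
        tr = getattr(art, attr_tr)
        aligned = match_fold_labels(tr, ref)
        if not aligned.equals(tr):
            setattr(art, attr_tr, aligned)
            va = getattr(art, attr_va)
            setattr(art, attr_va, va.map({1: 2, 2: 1}))


def run_cv(cohort: SurvivalCohort, config: PipelineConfig) -> CVResult:
    """10-fold (by default) cross-validated clustering of a cohort."""
    n = cohort.n_subjects
    if n < config.k_folds * config.n_clusters:
        raise ValueError("cohort too small for the requested folds/clusters")
    rng = np.random.default_rng(_stage_seed(config.seed, 0, 0))
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, config.k_folds)):
        fold_of[chunk] = f
    index = cohort.features.index
    fold_assignments = pd.Series(fold_of, index=index, name="fold")

    artifacts: list[FoldArtifacts] = []
    for f in range(config.k_folds):
        train_index = index[fold_of != f]
        val_index = index[fold_of == f]
        art = run_fold(cohort, train_index, val_index, config, fold=f)
        if f > 0:
            _align(art, artifacts[0].train_labels_scaled,
                   artifacts[0].train_labels_standardized)
        artifacts.append(art)

    scaled = pd.concat([a.val_labels_scaled for a in artifacts]).loc[index]
    standardized = pd.concat([a.val_labels_standardized for a in artifacts]).loc[index]
    return CVResult(
        scaled_labels=scaled.rename("cluster_sc"),
        standardized_labels=standardized.rename("cluster_stand"),
        fold_assignments=fold_assignments,
        folds=artifacts,
    )


def default_roster(has_ajcc: bool = False) -> dict[str, list[str]]:
    """Named covariate-group sets for the model-comparison table.

    Group names: ``clinical``, ``radiomic``, ``cluster_sc``,
    ``cluster_stand``, ``ajcc``.
    """
    roster = {
        "Clin. Only": ["clinical"],
        "Clin. & Rad.": ["clinical", "radiomic"],
        "Clin. & [Sc.] Cluster": ["clinical", "cluster_sc"],
        "Clin. & [Stand.] Cluster": ["clinical", "cluster_stand"],
        "[Sc.] Cluster Only": ["cluster_sc"],
        "[Stand.] Cluster Only": ["cluster_stand"],
    }
    if has_ajcc:
        roster.update({
            "AJCC Only": ["ajcc"],
            "Clin. & AJCC": ["clinical", "ajcc"],
            "Clin. & AJCC & [Sc.] Cluster": ["clinical", "ajcc", "cluster_sc"],
            "Only AJCC & [Sc.] Cluster": ["ajcc", "cluster_sc"],
        })
    return roster


@dataclass
class ModelComparisonReport:
    table: pd.DataFrame          # one row per roster model
    fold_metrics: pd.DataFrame   # per model x fold AUC / Brier / C-index
    fits: dict = field(default_factory=dict)


def _full_data_matrix(cohort: SurvivalCohort, config: PipelineConfig) -> pd.DataFrame:
    """Complete + standardize the full cohort once for whole-data Cox fits."""
    clinical, radiomic = config.roles(cohort.features.columns)
    X = cohort.features[clinical + radiomic]
    if X.isna().any().any():
        X = PMMImputer(k_donors=config.pmm_k,
                       random_state=_stage_seed(config.seed, 9999, 1)).fit_transform(X)
    return RangeScaler().fit_transform(X)


def compare_models(cohort: SurvivalCohort, cv: CVResult, config: PipelineConfig,
                   roster: dict[str, list[str]] | None = None,
                   ajcc: pd.Series | None = None,
                   radiomic_signature: list[str] | None = None) -> ModelComparisonReport:
    """Fit the model roster on the full cohort and build the comparison table.

    AIC/AICc are reported relative to the clinical and to the null baseline
    as the *negated* difference, so positive values mean the model improves
    on the baseline.  LRT p-values are computed only against a nested
    baseline.  Predictive metrics are evaluated per cross-validation fold on
    that fold's held-out subjects, using each model's full-data linear
    predictor and Breslow horizon survival, and aggregated as mean +/- se.
    """
    clinical, radiomic = config.roles(cohort.features.columns)
    X = _full_data_matrix(cohort, config)
    time = cohort.time.to_numpy()
    event = cohort.event.to_numpy()

    groups: dict[str, pd.DataFrame] = {
        "clinical": X[clinical],
        "radiomic": X[radiomic_signature if radiomic_signature is not None
                      else radiomic],
        "cluster_sc": (cv.scaled_labels == 2).astype(float).rename("cluster_sc").to_frame(),
        "cluster_stand": (cv.standardized_labels == 2).astype(float)
        .rename("cluster_stand").to_frame(),
    }
    if ajcc is not None:
        groups["ajcc"] = pd.get_dummies(ajcc, prefix="ajcc", drop_first=True).astype(float)
    if roster is None:
        roster = default_roster(has_ajcc=ajcc is not None)

    fits = {"Null": cox_fit(None, time, event)}
    model_groups = {"Null": []}
    for name, gs in roster.items():
        missing = [g for g in gs if g not in groups]
        if missing:
            raise ValueError(f"model {name!r} needs unavailable groups: {missing}")
        Xm = pd.concat([groups[g] for g in gs], axis=1)
        fits[name] = cox_fit(Xm, time, event)
        model_groups[name] = gs

    def _relative(name, baseline):
        fit, base = fits[name], fits[baseline]
        aic, aicc = ev.aic_aicc(fit.log_likelihood, fit.n_params, fit.n_subjects)
        b_aic, b_aicc = ev.aic_aicc(base.log_likelihood, base.n_params, base.n_subjects)
        out = {"dAIC": b_aic - aic, "dAICc": b_aicc - aicc, "LRT_p": np.nan}
        nested = set(model_groups[baseline]) <= set(model_groups[name])
        df = fit.n_params - base.n_params
        if nested and df >= 1:
            _, p = ev.likelihood_ratio_test(base.log_likelihood, fit.log_likelihood, df)
            out["LRT_p"] = p
        return out

    rows = []
    fold_rows = []
    for name, fit in fits.items():
        aic, aicc = ev.aic_aicc(fit.log_likelihood, fit.n_params, fit.n_subjects)
        row = {"model": name, "n_params": fit.n_params, "lnL": fit.log_likelihood,
               "AIC": aic, "AICc": aicc}
        if name != "Null":
            for key, val in _relative(name, "Null").items():
                row[f"{key}_vs_null"] = val
        if name not in ("Null", "Clin. Only") and "Clin. Only" in fits:
            for key, val in _relative(name, "Clin. Only").items():
                row[f"{key}_vs_clinical"] = val
        for tag in ("cluster_sc", "cluster_stand"):
            if tag in fit.summary.index:
                row["cluster_hr"] = fit.summary.loc[tag, "hr"]
                row["cluster_hr_lower"] = fit.summary.loc[tag, "hr_lower"]
                row["cluster_hr_upper"] = fit.summary.loc[tag, "hr_upper"]

        if fit.n_params > 0:
            Xm = pd.concat([groups[g] for g in model_groups[name]], axis=1)
            lp = fit.linear_predictor(Xm)
            chaz = breslow_cumhaz(time, event, lp)
            prob = 1.0 - np.exp(-float(chaz(config.horizon)) * np.exp(lp))
            pred = pd.Series(prob, index=cohort.features.index)
            risk = pd.Series(lp, index=cohort.features.index)
            per_fold = _fold_metrics(name, pred, risk, cohort, cv, config)
            fold_rows.extend(per_fold)
            if per_fold:
                pf = pd.DataFrame(per_fold)
                for m in ("auc", "brier", "cindex"):
                    vals = pf[m].dropna()
                    row[m] = vals.mean()
                    row[f"{m}_se"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            try:
                cal, _ = ev.nam_dagostino(pred.to_numpy(), time, event,
                                          horizon=config.horizon)
                row["calibration"] = cal
            except ValueError:
                row["calibration"] = np.nan
        rows.append(row)

    table = pd.DataFrame(rows).set_index("model")
    return ModelComparisonReport(table=table,
                                 fold_metrics=pd.DataFrame(fold_rows),
                                 fits=fits)


def _fold_metrics(name, pred, risk, cohort, cv, config):
    out = []
    for f in sorted(cv.fold_assignments.unique()):
        idx = cv.fold_assignments.index[cv.fold_assignments == f]
        t = cohort.time.loc[idx].to_numpy()
        e = cohort.event.loc[idx].to_numpy()
        row = {"model": name, "fold": int(f)}
        for key, fn, arg in (
            ("auc", ev.auc_at_horizon, risk.loc[idx].to_numpy()),
            ("brier", ev.brier_ipcw, pred.loc[idx].to_numpy()),
        ):
            try:
                row[key] = fn(arg, t, e, horizon=config.horizon)
            except ValueError:
                row[key] = np.nan
        try:
            row["cindex"] = ev.concordance_index(risk.loc[idx].to_numpy(), t, e)
        except ValueError:
            row["cindex"] = np.nan
        out.append(row)
    return out
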