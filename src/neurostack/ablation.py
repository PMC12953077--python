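"""Feature-set ablation with leakage-safe nested cross-validation.

Four tasks — three binary stage classifications (CN-ADD, CN-MCI,
MCI-ADD) and one regression (LCDP: annualized MMSE change) — are each
run over seven feature-set combinations (MO, MS, GT, MO+MS, MO+GT,
MS+GT, MO+MS+GT; amyloid status always appended), giving the 28-run
ablation grid.  Each run applies a stratified 80/20 hold-out, then
5-outer / 3-inner nested CV with per-fold grid search over a
heterogeneous learner roster, and finally the diversity-aware stacking
ensemble.  Covariate adjustment (residualization + standardization) is
fitted inside each outer training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, AdaBoostRegressor,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from xgboost import XGBClassifier, XGBRegressor

from . import ensemble as ens
from .adjust import CovariatePipeline, delta_mmse_targets, etiv_normalize
from .cohort import SubjectRecord, cohort_demographics
from .tables import FeatureTable

CLASSIFICATION_METRICS = ["ACC", "BACC", "SEN", "SPE", "rocAUC"]
REGRESSION_METRICS = ["MAE", "MSE", "RMSE", "R2"]

#: The seven feature-set combinations; amyloid status is always appended.
FEATURE_SET_COMBOS = ["MO", "MS", "GT", "MO+MS", "MO+GT", "MS+GT", "MO+MS+GT"]
_COMBO_TAGS = {"MO": {"MO-SV", "MO-CT", "MO-other"},
               "MS": {"MS"},
               "GT": {"GT-local", "GT-global"}}

#: task_id -> (kind, class pair or None, positive/impaired class)
TASKS: dict[str, tuple[str, tuple[str, str] | None, str | None]] = {
    "CN-ADD": ("classification", ("CN", "ADD"), "ADD"),
    "CN-MCI": ("classification", ("CN", "MCI"), "MCI"),
    "MCI-ADD": ("classification", ("MCI", "ADD"), "ADD"),
    "LCDP": ("regression", None, None),
}


class AblationError(ValueError):
    pass


@dataclass
class FoldPlan:
    outer_folds: int = 5
    inner_folds: int = 3
    holdout_fraction: float = 0.2
    seed: int = 0


# ---------------------------------------------------------------------------
# Learner registry.  The registry (ids, default grids) is the contract;
# estimators come from scikit-learn / xgboost.
# ---------------------------------------------------------------------------

def classifier_registry(seed: int = 0, small: bool = False) -> dict:
    """id -> (estimator, hyperparameter grid).  ``small`` shrinks grids
    for desk-scale runs; both are config-overridable."""
    reg = {
        "LogR": (LogisticRegression(max_iter=2000, random_state=seed),
                 {"C": [0.01, 0.1, 1.0, 10.0]}),
        "LDA": (LinearDiscriminantAnalysis(),
                [{"solver": ["svd"]},
                 {"solver": ["lsqr"], "shrinkage": ["auto"]}]),
        "DT": (DecisionTreeClassifier(random_state=seed),
               {"max_depth": [3, 5, 10, None]}),
        "RF": (RandomForestClassifier(random_state=seed, n_jobs=1),
               {"n_estimators": [100], "max_depth": [None, 10],
                "max_features": ["sqrt"]}),
        "AdaBoost": (AdaBoostClassifier(random_state=seed),
                     {"n_estimators": [50, 100],
                      "learning_rate": [0.1, 1.0]}),
        "XGB": (XGBClassifier(random_state=seed, n_jobs=1,
                              eval_metric="logloss", verbosity=0),
                {"n_estimators": [100], "max_depth": [3, 5],
                 "learning_rate": [0.1]}),
        "SVM": (SVC(probability=True, random_state=seed),
                {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]}),
    }
    if small:
        reg["LogR"] = (reg["LogR"][0], {"C": [0.1, 1.0]})
        reg["DT"] = (reg["DT"][0], {"max_depth": [3, None]})
        reg["RF"] = (RandomForestClassifier(random_state=seed, n_jobs=1),
                     {"n_estimators": [50], "max_depth": [None]})
        reg["AdaBoost"] = (reg["AdaBoost"][0],
                           {"n_estimators": [50], "learning_rate": [1.0]})
        reg["XGB"] = (reg["XGB"][0], {"n_estimators": [50], "max_depth": [3],
                                      "learning_rate": [0.1]})
        reg["SVM"] = (reg["SVM"][0], {"C": [1.0], "kernel": ["linear"]})
    return reg


def regressor_registry(seed: int = 0, small: bool = False) -> dict:
    reg = {
        "Ridge": (Ridge(random_state=seed),
                  {"alpha": [0.1, 1.0, 10.0]}),
        "DT": (DecisionTreeRegressor(random_state=seed),
               {"max_depth": [3, 5, 10, None]}),
        "RF": (RandomForestRegressor(random_state=seed, n_jobs=1),
               {"n_estimators": [100], "max_depth": [None, 10],
                "max_features": ["sqrt"]}),
        "AdaBoost": (AdaBoostRegressor(random_state=seed),
                     {"n_estimators": [50, 100],
                      "learning_rate": [0.1, 1.0]}),
        "XGB": (XGBRegressor(random_state=seed, n_jobs=1, verbosity=0),
                {"n_estimators": [100], "max_depth": [3, 5],
                 "learning_rate": [0.1]}),
        "GPR": (GaussianProcessRegressor(random_state=seed,
                                         normalize_y=True),
                {"alpha": [1e-2, 1e-1, 1.0]}),
        "SVR": (SVR(), {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]}),
    }
    if small:
        reg["Ridge"] = (reg["Ridge"][0], {"alpha": [1.0, 10.0]})
        reg["DT"] = (reg["DT"][0], {"max_depth": [3, None]})
        reg["RF"] = (RandomForestRegressor(random_state=seed, n_jobs=1),
                     {"n_estimators": [50], "max_depth": [None]})
        reg["AdaBoost"] = (reg["AdaBoost"][0],
                           {"n_estimators": [50], "learning_rate": [1.0]})
        reg["XGB"] = (reg["XGB"][0], {"n_estimators": [50], "max_depth": [3],
                                      "learning_rate": [0.1]})
        reg["GPR"] = (reg["GPR"][0], {"alpha": [1e-1]})
        reg["SVR"] = (reg["SVR"][0], {"C": [1.0], "kernel": ["linear"]})
    return reg


# ---------------------------------------------------------------------------
# Splitting and metrics.
# ---------------------------------------------------------------------------

def holdout_split(diagnosis: pd.Series, fraction: float = 0.2,
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified hold-out: per-class test count rounds half-up to the
    nearest integer.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    test: set[str] = set()
    for cls in sorted(diagnosis.unique()):
        ids = list(diagnosis.index[diagnosis == cls])
        if len(ids) < 2:
            raise AblationError(f"class {cls!r} has < 2 members; cannot "
                                "stratify")
        n_test = int(np.floor(len(ids) * fraction + 0.5))
        picked = rng.permutation(len(ids))[:n_test]
        test.update(ids[i] for i in picked)
    train_ids = [s for s in diagnosis.index if s not in test]
    test_ids = [s for s in diagnosis.index if s in test]
    return train_ids, test_ids


def assemble_feature_set(full_table: FeatureTable,
                         combo: str) -> FeatureTable:
    """Select the requested sets' columns plus the amyloid column, in the
    source table's frozen order."""
    if combo not in FEATURE_SET_COMBOS:
        raise AblationError(f"unknown feature-set combination {combo!r}")
    tags: set[str] = set().union(*(_COMBO_TAGS[p] for p in combo.split("+")))
    tags.add("ABETA")
    return full_table.select_tags(tags)


def classification_metrics(y_true, p_pred,
                           threshold: float = 0.5) -> dict[str, float]:
    """ACC, BACC, SEN, SPE, rocAUC with the impaired class coded 1."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(p_pred, dtype=float)
    if len(np.unique(y)) < 2:
        raise AblationError("both classes must be present in y_true")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    return {"ACC": (tp + tn) / len(y), "BACC": (sen + spe) / 2.0,
            "SEN": sen, "SPE": spe,
            "rocAUC": float(roc_auc_score(y, p))}


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) < 2 or np.var(y) == 0:
        raise AblationError("R^2 undefined for constant or singleton y_true")
    err = p - y
    mse = float(np.mean(err ** 2))
    return {"MAE": float(np.mean(np.abs(err))), "MSE": mse,
            "RMSE": float(np.sqrt(mse)),
            "R2": float(1.0 - mse * len(y) / np.sum((y - y.mean()) ** 2))}


def summarize_folds(fold_metrics: pd.DataFrame) -> dict[str, str]:
    """mean +/- sd (over folds) per metric, formatted for reporting."""
    return {m: f"{fold_metrics[m].mean():.3f} +/- {fold_metrics[m].std():.3f}"
            for m in fold_metrics.columns}


# ---------------------------------------------------------------------------
# Nested cross-validation.
# ---------------------------------------------------------------------------

@dataclass
class NestedCVResult:
    oof: pd.DataFrame                    # subject-indexed: fold, y_true, pred
    fold_metrics: pd.DataFrame           # one row per outer fold
    best_params: list[dict]              # per outer fold


def nested_cv_run(task_kind: str, features: FeatureTable,
                  demographics: pd.DataFrame, y: pd.Series,
                  estimator, grid, plan: FoldPlan) -> NestedCVResult:
    """5-outer / 3-inner nested CV with grid search.

    Residualizer and standardizer are fitted on each outer training fold
    and applied to its held-out fold before any model sees the data; the
    inner grid search (selection metric: BACC for classification,
    negative MAE for regression) runs on the transformed outer-train.
    """
    if not grid:
        raise AblationError("empty hyperparameter grid")
    ids = np.array(features.subjects)
    y = y.loc[ids]
    yv = y.to_numpy()
    if task_kind == "classification":
        classes, counts = np.unique(yv, return_counts=True)
        if len(classes) < 2 or counts.min() < plan.outer_folds:
            raise AblationError("too few members of a class for stratified "
                                f"{plan.outer_folds}-fold CV")
        outer = StratifiedKFold(plan.outer_folds, shuffle=True,
                                random_state=plan.seed)
        inner = StratifiedKFold(plan.inner_folds, shuffle=True,
                                random_state=plan.seed)
        scoring = "balanced_accuracy"
    else:
        outer = KFold(plan.outer_folds, shuffle=True, random_state=plan.seed)
        inner = KFold(plan.inner_folds, shuffle=True, random_state=plan.seed)
        scoring = "neg_mean_absolute_error"

    oof_rows, fold_rows, best_params = [], [], []
    for fold, (tr, te) in enumerate(outer.split(ids, yv if task_kind ==
                                                "classification" else None)):
        tr_ids, te_ids = ids[tr], ids[te]
        pipe = CovariatePipeline(fold_id=fold)
        x_tr = pipe.fit_transform(features.subset(tr_ids),
                                  demographics).data.to_numpy(dtype=float)
        x_te = pipe.transform(features.subset(te_ids),
                              demographics).data.to_numpy(dtype=float)
        search = GridSearchCV(estimator, grid, scoring=scoring, cv=inner,
                              n_jobs=1, refit=True)
        search.fit(x_tr, yv[tr])
        best_params.append(dict(search.best_params_))
        if task_kind == "classification":
            pred = search.predict_proba(x_te)[:, 1]
            fold_rows.append(classification_metrics(yv[te], pred))
        else:
            pred = search.predict(x_te)
            fold_rows.append(regression_metrics(yv[te], pred))
        for sid, yt, p in zip(te_ids, yv[te], pred):
            oof_rows.append({"subject_id": sid, "fold": fold,
                             "y_true": yt, "pred": float(p)})
    oof = pd.DataFrame(oof_rows).set_index("subject_id").loc[ids]
    return NestedCVResult(oof=oof, fold_metrics=pd.DataFrame(fold_rows),
                          best_params=best_params)


def _modal_params(best_params: list[dict]) -> dict:
    """Most frequently selected hyperparameters (lexicographic tie-break)."""
    keyed = [tuple(sorted(p.items())) for p in best_params]
    uniq = sorted(set(keyed), key=lambda k: (-keyed.count(k), repr(k)))
    return dict(uniq[0])


# ---------------------------------------------------------------------------
# Full experiment.
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    tasks: list[str] = field(default_factory=lambda: list(TASKS))
    feature_sets: list[str] = field(
        default_factory=lambda: list(FEATURE_SET_COMBOS))
    models: list[str] | None = None      # default: full roster per kind
    plan: FoldPlan = field(default_factory=FoldPlan)
    tau: float = 0.85
    small_grids: bool = False
    normalize_bpv: bool = True


def enumerate_runs(config: ExperimentConfig) -> list[tuple[str, str]]:
    """The (task, feature set) grid — 28 runs for the default config."""
    for t in config.tasks:
        if t not in TASKS:
            raise AblationError(f"unknown task {t!r}")
    return [(t, f) for t in config.tasks for f in config.feature_sets]


@dataclass
class RunResult:
    task: str
    feature_set: str
    kind: str
    train_ids: list[str]
    test_ids: list[str]
    fold_metrics: dict[str, pd.DataFrame]
    oof: dict[str, pd.DataFrame]
    best_params: dict[str, list[dict]]
    ensemble: ens.EnsembleModel
    holdout_metrics: dict[str, dict[str, float]]


def task_targets(task: str, cohort: list[SubjectRecord]) -> pd.Series:
    """Per-subject target for a task: impaired-class indicator for the
    stage classifications, annualized MMSE change for LCDP."""
    kind, pair, positive = TASKS[task]
    if kind == "classification":
        return pd.Series({s.subject_id: int(s.diagnosis == positive)
                          for s in cohort if s.diagnosis in pair})
    return delta_mmse_targets(cohort)


def run_single(task: str, combo: str, full_table: FeatureTable,
               cohort: list[SubjectRecord],
               config: ExperimentConfig) -> RunResult:
    """One (task, feature set) cell: hold-out split, nested CV for every
    base learner, diversity pruning, stacking, and hold-out evaluation."""
    kind, _, _ = TASKS[task]
    demo = cohort_demographics(cohort)
    y = task_targets(task, cohort)
    y = y.loc[[s for s in full_table.subjects if s in y.index]]
    table = assemble_feature_set(full_table, combo).subset(list(y.index))
    plan = config.plan
    train_ids, test_ids = holdout_split(demo.loc[y.index, "diagnosis"],
                                        plan.holdout_fraction, plan.seed)
    train_tab = table.subset(train_ids)
    y_train = y.loc[train_ids]

    registry = (classifier_registry(plan.seed, config.small_grids)
                if kind == "classification"
                else regressor_registry(plan.seed, config.small_grids))
    model_ids = config.models or list(registry)
    fold_metrics, oof, best_params = {}, {}, {}
    for mid in model_ids:
        est, grid = registry[mid]
        res = nested_cv_run(kind, train_tab, demo, y_train, est, grid, plan)
        fold_metrics[mid] = res.fold_metrics
        oof[mid] = res.oof
        best_params[mid] = res.best_params

    # Cross-validated performance for pruning: mean BACC / negated MAE.
    perf_metric = "BACC" if kind == "classification" else "MAE"
    sign = 1.0 if kind == "classification" else -1.0
    performance = {m: sign * float(fold_metrics[m][perf_metric].mean())
                   for m in model_ids}
    oof_vectors = {m: oof[m]["pred"].to_numpy() for m in model_ids}
    report = ens.prune_models(oof_vectors, performance, tau=config.tau)
    meta = ens.build_meta_features(oof_vectors, report.retained,
                                   subject_ids=train_ids)
    stack = ens.fit_stacking(meta, y_train.to_numpy(), kind, report,
                             seed=plan.seed)

    # Ensemble fold-wise metrics on the same outer folds.
    folds = oof[model_ids[0]]["fold"]
    ens_pred = pd.Series(stack.predict(meta), index=meta.index)
    rows = []
    for fold in sorted(folds.unique()):
        sids = folds.index[folds == fold]
        yt = y_train.loc[sids].to_numpy()
        pv = ens_pred.loc[sids].to_numpy()
        rows.append(classification_metrics(yt, pv) if kind ==
                    "classification" else regression_metrics(yt, pv))
    fold_metrics["Ensemble"] = pd.DataFrame(rows)
    oof["Ensemble"] = pd.DataFrame({"fold": folds, "y_true":
                                    y_train.loc[folds.index],
                                    "pred": ens_pred.loc[folds.index]})

    holdout = _holdout_eval(kind, table, demo, y, train_ids, test_ids,
                            registry, best_params, stack)
    return RunResult(task=task, feature_set=combo, kind=kind,
                     train_ids=train_ids, test_ids=test_ids,
                     fold_metrics=fold_metrics, oof=oof,
                     best_params=best_params, ensemble=stack,
                     holdout_metrics=holdout)


def _holdout_eval(kind, table, demo, y, train_ids, test_ids, registry,
                  best_params, stack) -> dict[str, dict[str, float]]:
    """Refit retained base models on the full training portion (modal
    fold hyperparameters) and evaluate models + ensemble on the 20%
    hold-out.  Reported separately from the NestedCV fold metrics."""
    from sklearn.base import clone

    pipe = CovariatePipeline(fold_id="holdout")
    x_tr = pipe.fit_transform(table.subset(train_ids),
                              demo).data.to_numpy(dtype=float)
    x_te = pipe.transform(table.subset(test_ids),
                          demo).data.to_numpy(dtype=float)
    y_tr = y.loc[train_ids].to_numpy()
    y_te = y.loc[test_ids].to_numpy()
    out: dict[str, dict[str, float]] = {}
    test_meta = {}
    attributions: dict[str, np.ndarray | None] = {}
    for mid in stack.retained:
        est = clone(registry[mid][0]).set_params(**_modal_params(
            best_params[mid]))
        est.fit(x_tr, y_tr)
        pred = (est.predict_proba(x_te)[:, 1] if kind == "classification"
                else est.predict(x_te))
        test_meta[mid] = pred
        attributions[mid] = ens.base_attribution(est)
        out[mid] = (classification_metrics(y_te, pred) if kind ==
                    "classification" else regression_metrics(y_te, pred))
    meta_te = ens.build_meta_features(test_meta, stack.retained,
                                      subject_ids=test_ids)
    pred = stack.predict(meta_te)
    out["Ensemble"] = (classification_metrics(y_te, pred) if kind ==
                       "classification" else regression_metrics(y_te, pred))
    ens.propagate_importance(stack, attributions, table.features)
    return out


def run_ablation(full_table: FeatureTable, cohort: list[SubjectRecord],
                 config: ExperimentConfig | None = None,
                 ) -> tuple[pd.DataFrame, dict[tuple[str, str], RunResult]]:
    """Run the full (task x feature set) grid.

    ``full_table`` must already be eTIV-normalized (a per-subject
    operation; see :func:`prepare_feature_table`).  Returns one summary
    row per run plus the detailed per-run results keyed by
    (task, feature_set).
    """
    config = config or ExperimentConfig()
    results: dict[tuple[str, str], RunResult] = {}
    rows = []
    for task, combo in enumerate_runs(config):
        run = run_single(task, combo, full_table, cohort, config)
        results[(task, combo)] = run
        primary = "BACC" if run.kind == "classification" else "MAE"
        for model, fm in run.fold_metrics.items():
            rows.append({"task": task, "feature_set": combo, "model": model,
                         "n_train": len(run.train_ids),
                         "n_test": len(run.test_ids),
                         f"{primary}_mean": fm[primary].mean(),
                         f"{primary}_sd": fm[primary].std(),
                         **{f"{m}_mean": fm[m].mean() for m in fm.columns},
                         **{f"holdout_{k}": v for k, v in
                            run.holdout_metrics.get(model, {}).items()}})
    return pd.DataFrame(rows), results


def prepare_feature_table(mo_ms: FeatureTable, gt: pd.DataFrame,
                          abeta: FeatureTable,
                          cohort: list[SubjectRecord],
                          normalize_bpv: bool = True) -> FeatureTable:
    """Assemble the 688-column master table (91 MO + 5 MS + 591 GT +
    amyloid status) and apply the per-subject eTIV normalization."""
    from .tables import concat_tables

    gt_table = FeatureTable(gt)
    full = concat_tables([mo_ms, gt_table, abeta])
    return etiv_normalize(full, cohort, normalize_bpv=normalize_bpv)
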