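"""Performance- and diversity-aware stacking.

Base models trained under identical nested-CV splits produce aligned
out-of-fold (OOF) predictions.  The pool is pruned by pairwise Pearson
correlation of those predictions (threshold tau = 0.85): among a highly
correlated pair, the model with worse cross-validated performance is
discarded, greedily in descending correlation order.  Retained models'
OOF predictions become meta-features for a logistic (classification) or
ridge (regression) meta-model, trained exclusively on pooled OOF
predictions.  Ensemble-level importance for each original feature j is
the stacking-weighted sum of base-model attribution magnitudes,
I_j = sum_m |w_m| |beta_j^(m)|, normalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge


class EnsembleError(ValueError):
    pass


def prediction_correlation(oof_a: np.ndarray, oof_b: np.ndarray) -> float:
    """Pearson correlation of two aligned OOF prediction vectors.

    A constant vector has undefined correlation; it is treated as
    maximally redundant (rho = 1) so degenerate models are pruned first.
    """
    a = np.asarray(oof_a, dtype=float)
    b = np.asarray(oof_b, dtype=float)
    if a.shape != b.shape:
        raise EnsembleError("OOF vectors are not aligned")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant OOF prediction vector; correlation set to 1 "
                      "(maximally redundant)", stacklevel=2)
        return 1.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class DiversityReport:
    correlation: pd.DataFrame            # model x model rho_pred
    tau: float
    retained: list[str]
    pruned: list[dict]                   # model, kept_partner, performances


def prune_models(oof: dict[str, np.ndarray],
                 performance: dict[str, float],
                 tau: float = 0.85) -> DiversityReport:
    """Greedy correlation pruning.

    Pairs are processed in descending correlation; while any retained
    pair exceeds ``tau`` the worse performer (higher is better; ties
    broken by lexicographic model id) is discarded.  At least one model
    is always retained.
    """
    models = sorted(oof)
    if not models:
        raise EnsembleError("empty model pool")
    rho = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            r = prediction_correlation(oof[a], oof[b])
            rho.loc[a, b] = rho.loc[b, a] = r
    retained = set(models)
    pruned: list[dict] = []
    pairs = sorted(((rho.loc[a, b], a, b)
                    for i, a in enumerate(models) for b in models[i + 1:]),
                   key=lambda t: (-t[0], t[1], t[2]))
    for r, a, b in pairs:
        if r <= tau or a not in retained or b not in retained:
            continue
        if len(retained) == 1:
            break
        # discard the worse performer (ties: later lexicographic id)
        if (performance[a], b) > (performance[b], a):
            worse, kept = b, a
        else:
            worse, kept = a, b
        retained.discard(worse)
        pruned.append({"model": worse, "kept_partner": kept,
                       "rho": float(r),
                       "performance": performance[worse],
                       "partner_performance": performance[kept]})
    return DiversityReport(correlation=rho, tau=tau,
                           retained=[m for m in models if m in retained],
                           pruned=pruned)


def build_meta_features(oof: dict[str, np.ndarray],
                        retained: list[str],
                        subject_ids=None) -> pd.DataFrame:
    """Meta-feature matrix: one column per retained model's OOF
    prediction (class-1 probability or predicted value)."""
    lengths = {len(np.asarray(oof[m])) for m in retained}
    if len(lengths) != 1:
        raise EnsembleError("misaligned OOF predictions across models")
    z = pd.DataFrame({m: np.asarray(oof[m], dtype=float) for m in retained})
    if subject_ids is not None:
        z.index = pd.Index(list(subject_ids), name="subject_id")
    return z


@dataclass
class EnsembleModel:
    task_kind: str                       # classification / regression
    retained: list[str]
    meta_model: object
    meta_weights: pd.Series              # w_m per retained model
    diversity: DiversityReport
    importance: pd.Series | None = None  # normalized I_j, descending
    attribution_models: list[str] = field(default_factory=list)

    def predict(self, meta: pd.DataFrame) -> np.ndarray:
        """Ensemble prediction from base-model prediction columns."""
        x = meta[self.retained].to_numpy(dtype=float)
        if self.task_kind == "classification":
            return self.meta_model.predict_proba(x)[:, 1]
        return self.meta_model.predict(x)


def fit_stacking(meta: pd.DataFrame, targets: np.ndarray, task_kind: str,
                 diversity: DiversityReport,
                 regularization: float = 1.0,
                 seed: int = 0) -> EnsembleModel:
    """Fit the meta-model on pooled OOF predictions only."""
    y = np.asarray(targets)
    if len(y) != len(meta):
        raise EnsembleError("meta-features and targets are misaligned")
    x = meta.to_numpy(dtype=float)
    if task_kind == "classification":
        if len(np.unique(y)) < 2:
            raise EnsembleError("single-class targets")
        model = LogisticRegression(C=regularization, max_iter=5000,
                                   random_state=seed)
        model.fit(x, y)
        weights = pd.Series(model.coef_[0], index=meta.columns)
    elif task_kind == "regression":
        model = Ridge(alpha=regularization, random_state=seed)
        model.fit(x, y)
        weights = pd.Series(model.coef_, index=meta.columns)
    else:
        raise EnsembleError(f"unknown task kind {task_kind!r}")
    return EnsembleModel(task_kind=task_kind, retained=list(meta.columns),
                         meta_model=model, meta_weights=weights,
                         diversity=diversity)


def base_attribution(estimator) -> np.ndarray | None:
    """Per-feature attribution magnitudes of a fitted base model:
    |coefficients| for linear models, native normalized importances for
    tree ensembles; None when the model exposes neither (e.g. an RBF
    kernel machine)."""
    coef = getattr(estimator, "coef_", None)
    if coef is not None:
        coef = np.asarray(coef, dtype=float)
        return np.abs(coef[0] if coef.ndim == 2 else coef)
    imp = getattr(estimator, "feature_importances_", None)
    if imp is not None:
        return np.abs(np.asarray(imp, dtype=float))
    return None


def propagate_importance(ensemble: EnsembleModel,
                         attributions: dict[str, np.ndarray | None],
                         feature_names: list[str]) -> pd.Series:
    """I_j = sum over retained models of |w_m| * |beta_j^(m)|, normalized
    to sum to 1 and sorted descending.  Models without any attribution
    vector are excluded from the sum with a warning."""
    total = np.zeros(len(feature_names))
    used: list[str] = []
    for m in ensemble.retained:
        beta = attributions.get(m)
        if beta is None:
            warnings.warn(f"model {m} has no feature attribution; excluded "
                          "from importance propagation", stacklevel=2)
            continue
        beta = np.abs(np.asarray(beta, dtype=float))
        if beta.shape[0] != len(feature_names):
            raise EnsembleError(f"attribution length mismatch for {m}")
        total += abs(float(ensemble.meta_weights[m])) * beta
        used.append(m)
    s = total.sum()
    if s > 0:
        total = total / s
    imp = pd.Series(total, index=feature_names).sort_values(ascending=False)
    ensemble.importance = imp
    ensemble.attribution_models = used
    return imp
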