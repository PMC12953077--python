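"""Paired fold-wise statistics, bootstrap uncertainty, and reporting.

The a-priori feature-set comparisons (does adding MS to MO help? does
adding GT to MO+MS help?) are tested with paired one-sided Wilcoxon
signed-rank tests across cross-validation folds: W is the sum of ranks
of positive oriented differences, with zero differences dropped and ties
given average ranks.  For n <= 12 usable folds the one-sided p-value is
exact, by enumeration of all 2^n sign assignments; above that a normal
approximation is used.  With 5 folds the smallest attainable exact p is
1/32 = 0.03125, a documented limitation of fold-level testing.

Bootstrap (percentile, B = 1000 by default) provides 95% confidence
intervals on OOF metrics and pointwise ROC confidence bands.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve


class ReportError(ValueError):
    pass


@dataclass
class PairedComparison:
    label: str
    differences: np.ndarray              # oriented: positive = improvement
    w: float
    p_value: float
    n_used: int
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


def wilcoxon_one_sided(x, y, higher_is_better: bool = True,
                       label: str = "", alpha: float = 0.05,
                       ) -> PairedComparison:
    """One-sided paired Wilcoxon signed-rank test that arm ``x`` improves
    on arm ``y`` over folds.

    Differences are oriented so that positive means improvement
    (negated when lower is better, e.g. MAE).  Zero differences are
    dropped; tied |d| get average ranks.  Exact enumeration for
    n <= 12, normal approximation above.  All-zero differences give the
    degenerate signal (W = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ReportError("fold metric vectors have unequal length")
    d = (x - y) if higher_is_better else (y - x)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return PairedComparison(label=label, differences=d, w=0.0,
                                p_value=1.0, n_used=0, alpha=alpha,
                                degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 12:
        null_w = np.zeros(1 << n)
        for mask in range(1 << n):
            s = 0.0
            for i in range(n):
                if mask >> i & 1:
                    s += ranks[i]
            null_w[mask] = s
        p = float(np.mean(null_w >= w - 1e-12))
    else:
        _, p = sps.wilcoxon(d, alternative="greater", correction=True,
                            method="approx")
        p = float(p)
    return PairedComparison(label=label, differences=d, w=w, p_value=p,
                            n_used=n, alpha=alpha)


#: A-priori comparison plan: (base arm, augmented arm) per task.
DEFAULT_COMPARISON_PLAN = [("MO", "MO+MS"), ("MO+MS", "MO+MS+GT")]


def compare_feature_sets(results, tasks=None, plan=None,
                         alpha: float = 0.05) -> list[PairedComparison]:
    """Evaluate the planned comparisons on ensemble fold metrics.

    ``results`` maps (task, feature_set) to a RunResult (or any object
    with ``kind`` and ``fold_metrics['Ensemble']``).  Classification
    arms compare BACC (higher better), regression arms MAE (lower
    better).
    """
    plan = plan or DEFAULT_COMPARISON_PLAN
    if tasks is None:
        tasks = sorted({t for t, _ in results})
    out = []
    for task in tasks:
        for base, augmented in plan:
            try:
                run_a = results[(task, augmented)]
                run_b = results[(task, base)]
            except KeyError as e:
                raise ReportError(f"missing arm for {task}: {e}") from e
            metric, higher = (("BACC", True) if run_a.kind ==
                              "classification" else ("MAE", False))
            out.append(wilcoxon_one_sided(
                run_a.fold_metrics["Ensemble"][metric].to_numpy(),
                run_b.fold_metrics["Ensemble"][metric].to_numpy(),
                higher_is_better=higher, alpha=alpha,
                label=f"{task}: {base} vs. {augmented}"))
    return out


@dataclass
class BootstrapCI:
    metric: str
    estimate: float
    lower: float
    upper: float
    iterations: int
    seed: int


def bootstrap_ci(oof: pd.DataFrame, metric_fn, metric_name: str = "metric",
                 B: int = 1000, seed: int = 0,
                 classification: bool = False) -> BootstrapCI:
    """Percentile 95% CI over B subject-level resamples of pooled OOF
    predictions.  Classification resamples must contain both classes
    (resample until valid, 100-retry cap)."""
    y = oof["y_true"].to_numpy()
    p = oof["pred"].to_numpy()
    if len(y) < 2:
        raise ReportError("need >= 2 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    estimate = float(metric_fn(y, p))
    vals = np.empty(B)
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, len(y), size=len(y))
            if not classification or len(np.unique(y[idx])) > 1:
                break
        else:
            raise ReportError("could not draw a valid resample")
        vals[b] = metric_fn(y[idx], p[idx])
    if np.isnan(vals).all():
        raise ReportError("metric undefined on all resamples")
    lo, hi = np.nanpercentile(vals, [2.5, 97.5])
    # percentile interval anchored to contain the point estimate
    return BootstrapCI(metric=metric_name, estimate=estimate,
                       lower=float(min(lo, estimate)),
                       upper=float(max(hi, estimate)),
                       iterations=B, seed=seed)


def roc_with_bands(oof: pd.DataFrame, B: int = 1000,
                   seed: int = 0, grid_size: int = 101) -> pd.DataFrame:
    """ROC curve on pooled OOF predictions with a pointwise percentile
    bootstrap band (columns fpr, tpr, band_lo, band_hi)."""
    y = oof["y_true"].to_numpy().astype(int)
    p = oof["pred"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ReportError("ROC undefined with one class")
    fpr_grid = np.linspace(0.0, 1.0, grid_size)

    def curve(yy, pp):
        fpr, tpr, _ = roc_curve(yy, pp)
        return np.interp(fpr_grid, fpr, tpr)

    point = curve(y, p)
    rng = np.random.default_rng(seed)
    curves = np.empty((B, grid_size))
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, len(y), size=len(y))
            if len(np.unique(y[idx])) > 1:
                break
        curves[b] = curve(y[idx], p[idx])
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame({"fpr": fpr_grid, "tpr": point,
                         "band_lo": np.minimum(lo, point),
                         "band_hi": np.maximum(hi, point)})


def permutation_importance(model, x: pd.DataFrame, y, metric_fn,
                           repeats: int = 5, seed: int = 0,
                           higher_is_better: bool = True,
                           predict=None) -> pd.Series:
    """Model-agnostic importance: mean metric drop when one feature
    column is shuffled, over ``repeats`` shuffles; ranked descending."""
    if repeats < 1:
        raise ReportError("repeats must be >= 1")
    predict = predict or (lambda m, xv: m.predict(xv))
    y = np.asarray(y)
    xv = x.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    baseline = float(metric_fn(y, predict(model, xv)))
    sign = 1.0 if higher_is_better else -1.0
    drops = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        vals = np.empty(repeats)
        for r in range(repeats):
            xp = xv.copy()
            xp[:, j] = xp[rng.permutation(len(y)), j]
            vals[r] = metric_fn(y, predict(model, xp))
        drops[j] = sign * (baseline - vals.mean())
    return pd.Series(drops, index=x.columns).sort_values(ascending=False)


def render_report(results_table: pd.DataFrame, results: dict,
                  comparisons: list[PairedComparison],
                  out_dir: str, roc_bootstrap: int = 200,
                  seed: int = 0) -> dict:
    """Write the report bundle: best-per-task summary, the comparison
    table (W, p), top-20 importance tables, and ROC band data."""
    if results_table.empty:
        raise ReportError("empty results")
    os.makedirs(out_dir, exist_ok=True)

    best_rows = []
    for task in results_table["task"].unique():
        sub = results_table[results_table["task"] == task]
        if "BACC_mean" in sub.columns and sub["BACC_mean"].notna().any():
            row = sub.loc[sub["BACC_mean"].idxmax()]
            best_rows.append({"task": task, "feature_set": row["feature_set"],
                              "model": row["model"],
                              "BACC": f"{row['BACC_mean']:.3f} +/- "
                                      f"{row['BACC_sd']:.3f}"})
        else:
            row = sub.loc[sub["MSE_mean"].idxmin()]
            best_rows.append({"task": task, "feature_set": row["feature_set"],
                              "model": row["model"],
                              "MSE": f"{row['MSE_mean']:.3f} +/- "
                                     f"{row['MAE_sd']:.3f}"})
    pd.DataFrame(best_rows).to_csv(os.path.join(out_dir, "best_per_task.csv"),
                                   index=False)

    pd.DataFrame([{"comparison": c.label, "W": c.w, "p_value": c.p_value,
                   "n_folds_used": c.n_used,
                   "significant_at_0.05": c.significant,
                   "degenerate": c.degenerate}
                  for c in comparisons]).to_csv(
        os.path.join(out_dir, "comparisons.csv"), index=False)

    for (task, fs), run in results.items():
        imp = run.ensemble.importance
        if imp is not None:
            imp.head(20).rename("importance").to_csv(
                os.path.join(out_dir, f"importance_top20_{task}_{fs}.csv"),
                index_label="feature")
        if run.kind == "classification":
            roc = roc_with_bands(run.oof["Ensemble"], B=roc_bootstrap,
                                 seed=seed)
            roc.to_csv(os.path.join(out_dir, f"roc_{task}_{fs}.csv"),
                       index=False)

    summary = {
        "n_runs": len(results),
        "n_comparisons": len(comparisons),
        "note": ("Wilcoxon p-values for 5 folds are exact; the smallest "
                 "attainable one-sided p is 1/32 = 0.03125."),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    results_table.to_csv(os.path.join(out_dir, "results.csv"), index=False)
    return summary


def ensemble_metric_cis(run, B: int = 1000, seed: int = 0) -> list[BootstrapCI]:
    """Bootstrap CIs for the ensemble's pooled-OOF metric suite."""
    from .ablation import classification_metrics, regression_metrics

    oof = run.oof["Ensemble"]
    out = []
    if run.kind == "classification":
        names = ["ACC", "BACC", "SEN", "SPE"]
        for name in names:
            out.append(bootstrap_ci(
                oof, lambda yy, pp, n=name: classification_metrics(yy, pp)[n],
                metric_name=name, B=B, seed=seed, classification=True))
        out.append(bootstrap_ci(oof, roc_auc_score, metric_name="rocAUC",
                                B=B, seed=seed, classification=True))
    else:
        for name in ["MAE", "MSE", "RMSE", "R2"]:
            out.append(bootstrap_ci(
                oof, lambda yy, pp, n=name: regression_metrics(yy, pp)[n],
                metric_name=name, B=B, seed=seed))
    return out
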