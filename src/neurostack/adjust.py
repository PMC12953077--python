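"""Leakage-safe covariate adjustment.

Implements the annualized MMSE change target and the nuisance-covariate
pipeline: head-size (eTIV) normalization of volumetric features,
fold-wise linear residualization of all imaging features against age and
sex, and fold-wise standardization.  Residualizer and standardizer obey
a strict fit-on-train / apply-on-test contract: parameters are estimated
once from a training fold and then applied unchanged to held-out data.

Sex is coded M=0, F=1.  The standardizer uses the population (divide by
n) standard deviation by default; both choices are toggleable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import MmseVisit, SubjectRecord
from .tables import FeatureTable

#: Tags of columns that are imaging-derived and therefore adjusted.
IMAGING_TAGS = {"MO-SV", "MO-CT", "MO-other", "MS", "GT-local", "GT-global"}
#: Volume-type tags divided by eTIV (BPV included by default).
VOLUME_TAGS = {"MO-SV"}

SEX_CODING = {"M": 0.0, "F": 1.0}


class AdjustmentError(ValueError):
    pass


class NotFittedError(RuntimeError):
    pass


class VisitPairError(ValueError):
    """Subject cannot contribute a visit pair (exclusion signal)."""


def annualized_mmse_change(visit: MmseVisit, followup: MmseVisit) -> float:
    """(MMSE_followup - MMSE_visit) / years elapsed, in points per year."""
    months = followup.months_from_baseline - visit.months_from_baseline
    if months <= 0:
        raise AdjustmentError("follow-up must be strictly later than visit")
    return (followup.mmse - visit.mmse) / (months / 12.0)


def select_visit_pair(subject: SubjectRecord,
                      rule: str = "first_last") -> tuple[MmseVisit, MmseVisit]:
    """Pick the (visit, follow-up) pair: first and last available visit,
    maximizing elapsed time."""
    if rule != "first_last":
        raise AdjustmentError(f"unknown visit-pair rule {rule!r}")
    if len(subject.mmse_visits) < 2:
        raise VisitPairError(f"{subject.subject_id}: needs >= 2 MMSE visits")
    return subject.mmse_visits[0], subject.mmse_visits[-1]


def delta_mmse_targets(cohort: list[SubjectRecord],
                       rule: str = "first_last") -> pd.Series:
    """Annualized MMSE change per subject; subjects with < 2 visits are
    excluded."""
    out = {}
    for subj in cohort:
        try:
            first, last = select_visit_pair(subj, rule=rule)
        except VisitPairError:
            continue
        out[subj.subject_id] = annualized_mmse_change(first, last)
    return pd.Series(out, name="delta_mmse")


def etiv_normalize(table: FeatureTable, cohort: list[SubjectRecord],
                   normalize_bpv: bool = True) -> FeatureTable:
    """Divide volume-type features by each subject's eTIV.

    Cortical thickness, diffusion, and graph features are untouched.
    BPV is treated as a volume by default (toggleable).
    """
    etiv = pd.Series({s.subject_id: s.etiv for s in cohort})
    missing = [sid for sid in table.subjects if sid not in etiv.index]
    if missing:
        raise AdjustmentError(f"missing eTIV for subjects: {missing[:5]}")
    tags = set(VOLUME_TAGS) | ({"MO-other"} if normalize_bpv else set())
    cols = table.columns_with_tags(tags)
    out = table.copy()
    out.data[cols] = out.data[cols].div(etiv.loc[out.data.index], axis=0)
    return out


def _design_matrix(demographics: pd.DataFrame) -> np.ndarray:
    age = demographics["age"].to_numpy(dtype=float)
    sex = demographics["sex"].map(SEX_CODING).to_numpy(dtype=float)
    if np.isnan(sex).any():
        raise AdjustmentError("sex must be coded M/F")
    return np.column_stack([np.ones_like(age), age, sex])


class Residualizer:
    """Per-feature OLS of imaging features on [1, age, sex].

    ``fit`` estimates (beta0, beta1, beta2) per feature on the training
    fold; ``transform`` subtracts the fitted age/sex trend using those
    training coefficients and never refits.
    """

    def __init__(self, fold_id: str | int | None = None) -> None:
        self.fold_id = fold_id
        self.coef_: pd.DataFrame | None = None

    def fit(self, table: FeatureTable,
            demographics: pd.DataFrame) -> "Residualizer":
        cols = table.columns_with_tags(IMAGING_TAGS)
        if len(table.data) < 3:
            raise AdjustmentError("need >= 3 training subjects to fit")
        x = _design_matrix(demographics.loc[table.data.index])
        y = table.data[cols].to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            warnings.warn("rank-deficient design (constant age or single-sex "
                          "fold); using pseudoinverse", stacklevel=2)
            beta = np.linalg.pinv(x) @ y
        else:
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        self.coef_ = pd.DataFrame(beta, index=["beta0", "beta1", "beta2"],
                                  columns=cols)
        return self

    def transform(self, table: FeatureTable,
                  demographics: pd.DataFrame) -> FeatureTable:
        if self.coef_ is None:
            raise NotFittedError("Residualizer.transform before fit")
        cols = list(self.coef_.columns)
        if set(cols) - set(table.features):
            raise AdjustmentError("feature names do not match fitted model")
        x = _design_matrix(demographics.loc[table.data.index])
        fitted = x @ self.coef_.to_numpy()
        out = table.copy()
        out.data[cols] = out.data[cols].to_numpy(dtype=float) - fitted
        return out


class Standardizer:
    """Per-feature z-scoring with train-fold mean and sd.

    ``sd_convention`` is ``population`` (divide by n, default) or
    ``sample`` (divide by n-1).  Constant training features transform to
    0 with a warning.
    """

    def __init__(self, sd_convention: str = "population",
                 fold_id: str | int | None = None) -> None:
        if sd_convention not in ("population", "sample"):
            raise AdjustmentError(f"unknown sd convention {sd_convention!r}")
        self.sd_convention = sd_convention
        self.fold_id = fold_id
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, table: FeatureTable) -> "Standardizer":
        cols = table.columns_with_tags(IMAGING_TAGS)
        ddof = 0 if self.sd_convention == "population" else 1
        self.mean_ = table.data[cols].mean()
        self.sd_ = table.data[cols].std(ddof=ddof)
        if (self.sd_ == 0).any():
            n_const = int((self.sd_ == 0).sum())
            warnings.warn(f"{n_const} constant feature(s) in training fold; "
                          "their z-scores are set to 0", stacklevel=2)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.mean_ is None:
            raise NotFittedError("Standardizer.transform before fit")
        cols = list(self.mean_.index)
        out = table.copy()
        sd = self.sd_.replace(0.0, np.inf)  # constant -> 0 after centering
        out.data[cols] = (out.data[cols] - self.mean_) / sd
        return out


class CovariatePipeline:
    """Fold-wise residualization + standardization with one fit call.

    eTIV normalization is a per-subject operation and is applied to the
    full table before splitting; this pipeline handles the fold-scoped
    steps only.
    """

    def __init__(self, sd_convention: str = "population",
                 fold_id: str | int | None = None) -> None:
        self.residualizer = Residualizer(fold_id=fold_id)
        self.standardizer = Standardizer(sd_convention, fold_id=fold_id)

    def fit(self, table: FeatureTable,
            demographics: pd.DataFrame) -> "CovariatePipeline":
        self.residualizer.fit(table, demographics)
        resid = self.residualizer.transform(table, demographics)
        self.standardizer.fit(resid)
        return self

    def transform(self, table: FeatureTable,
                  demographics: pd.DataFrame) -> FeatureTable:
        resid = self.residualizer.transform(table, demographics)
        return self.standardizer.transform(resid)

    def fit_transform(self, table: FeatureTable,
                      demographics: pd.DataFrame) -> FeatureTable:
        return self.fit(table, demographics).transform(table, demographics)
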