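"""Synthetic cohort generation.

Generates cohorts whose feature tables, structural connectomes, and MMSE
trajectories carry the statistical structure the downstream ablation
analysis assumes: group-dependent atrophy/diffusivity/connectivity
effects, age/sex confounding, amyloid-status class association, and
longitudinal cognitive decline.  Demographic defaults mirror a typical
ADNI-style three-group cohort (cognitively normal, mild cognitive
impairment, Alzheimer's dementia).

Randomness is keyed per (seed, subject) so that adding subjects to one
group never perturbs the draws of existing subjects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .regions import (
    ABETA_FEATURE,
    BPV_FEATURE,
    CC_VOLUMES,
    CONNECTOME_REGIONS,
    CT_FEATURES,
    MO_FEATURES,
    MS_FEATURES,
    SUBCORTICAL_GM,
    SV_FEATURES,
    VENTRICLE_VOLUMES,
    default_tags,
)
from .tables import FeatureTable

GROUPS = ("CN", "MCI", "ADD")

# Per-subject substream ids (third key of the seed sequence).
_STREAM_DEMOGRAPHICS = 0
_STREAM_FEATURES = 1
_STREAM_CONNECTOME = 2
_STREAM_MMSE = 3
# Cohort-level template stream (second key, out of subject-uid range).
_TEMPLATE_UID = 99_000_000


class CohortError(ValueError):
    """Invalid cohort configuration or degenerate request."""


@dataclass
class MmseVisit:
    months_from_baseline: float
    mmse: float

    def __post_init__(self) -> None:
        if self.months_from_baseline < 0:
            raise CohortError("visit months_from_baseline must be >= 0")
        self.mmse = float(np.clip(self.mmse, 0.0, 30.0))


@dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: str                # CN / MCI / ADD
    age: float                    # years
    sex: str                      # M / F
    education: float              # years
    etiv: float                   # mm^3
    abeta_status: int             # 0 = Abeta-, 1 = Abeta+
    mmse_visits: list[MmseVisit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.diagnosis not in GROUPS:
            raise CohortError(f"unknown diagnosis {self.diagnosis!r}")
        if self.etiv <= 0:
            raise CohortError("etiv must be positive")
        self.mmse_visits = sorted(self.mmse_visits,
                                  key=lambda v: v.months_from_baseline)


@dataclass
class GroupProfile:
    """Demographic and clinical sampling distribution for one group."""

    age_mean: float
    age_sd: float
    male_frac: float
    edu_mean: float
    edu_sd: float
    mmse_mean: float
    mmse_sd: float
    abeta_prevalence: float
    decline_rate_mean: float      # MMSE points / year
    decline_rate_sd: float


def _default_profiles() -> dict[str, GroupProfile]:
    # Demographics follow the ADNI-style cohort composition: CN 228
    # (129 M, age 73.5 +- 7.5, Abeta+ 138), MCI 120, ADD 46.
    return {
        "CN": GroupProfile(73.48, 7.51, 129 / 228, 16.71, 2.23,
                           28.89, 1.35, 138 / 228, -0.05, 0.10),
        "MCI": GroupProfile(74.65, 8.57, 55 / 120, 16.13, 2.65,
                            27.69, 2.11, 60 / 120, -0.60, 0.50),
        "ADD": GroupProfile(75.48, 9.30, 22 / 46, 15.35, 2.51,
                            21.39, 4.27, 37 / 46, -2.50, 1.20),
    }


# Mean structure size as a fraction of eTIV (reference eTIV 1.5e6 mm^3)
# and the baseline between-subject SD in mm^3 at that reference.
_SV_FRACTIONS = {
    "Thalamus": 7500 / 1.5e6, "Caudate": 3700 / 1.5e6,
    "Putamen": 5300 / 1.5e6, "Pallidum": 1800 / 1.5e6,
    "Hippocampus": 4300 / 1.5e6, "Amygdala": 1700 / 1.5e6,
    "Accumbens-area": 600 / 1.5e6,
    "Lateral-Ventricle": 15000 / 1.5e6, "3rd-Ventricle": 1500 / 1.5e6,
    "CC_Posterior": 900 / 1.5e6, "CC_Mid_Posterior": 450 / 1.5e6,
    "CC_Central": 500 / 1.5e6, "CC_Mid_Anterior": 500 / 1.5e6,
    "CC_Anterior": 900 / 1.5e6,
}
_BPV_FRACTION = 0.73


def _feature_scales() -> dict[str, tuple[str, float, float]]:
    """Per feature: (kind, location, baseline sd).

    kind ``volume`` -> location is a fraction of eTIV; kind ``abs`` ->
    location is an absolute mean (CT in mm, diffusion in native units).
    """
    scales: dict[str, tuple[str, float, float]] = {}
    for f in SUBCORTICAL_GM + VENTRICLE_VOLUMES:
        key = f.split("-", 1)[1] if f.startswith(("Left-", "Right-")) else f
        frac = _SV_FRACTIONS[key]
        scales[f] = ("volume", frac, 0.08 * frac * 1.5e6)
    for f in CC_VOLUMES:
        frac = _SV_FRACTIONS[f]
        scales[f] = ("volume", frac, 0.10 * frac * 1.5e6)
    for f in CT_FEATURES:
        scales[f] = ("abs", 2.5, 0.12)
    scales[BPV_FEATURE] = ("volume", _BPV_FRACTION, 0.04 * _BPV_FRACTION * 1.5e6)
    scales["WholeBrain-MD"] = ("abs", 7.5e-4, 3.0e-5)
    scales["WholeBrain-FA"] = ("abs", 0.30, 0.015)
    scales["Left-Hippocampus-MD"] = ("abs", 9.0e-4, 5.0e-5)
    scales["Right-Hippocampus-MD"] = ("abs", 9.0e-4, 5.0e-5)
    scales["TBSS-Skeleton-FA"] = ("abs", 0.45, 0.02)
    return scales


FEATURE_SCALES = _feature_scales()

# Medial-temporal / temporal regions carrying the planted disease signal.
_TEMPORAL_CT = [
    f"ctx-{h}-{n}" for h in ("lh", "rh")
    for n in ("entorhinal", "temporalpole", "middletemporal",
              "inferiortemporal", "fusiform", "parahippocampal", "bankssts")
]
_PARIETAL_CT = [f"ctx-{h}-{n}" for h in ("lh", "rh")
                for n in ("precuneus", "inferiorparietal", "supramarginal")]


def default_effect_config() -> dict[str, dict[str, float]]:
    """Standardized group mean shifts (units of the feature's baseline sd)
    relative to CN: hippocampal/temporal atrophy, ventricular enlargement,
    raised diffusivity and lowered anisotropy in MCI and (more so) ADD."""
    eff: dict[str, dict[str, float]] = {}

    def put(features, mci, add):
        for f in features:
            eff[f] = {"MCI": mci, "ADD": add}

    put([f"{s}-Hippocampus" for s in ("Left", "Right")], -0.5, -1.2)
    put([f"{s}-Amygdala" for s in ("Left", "Right")], -0.35, -0.8)
    put([f"{s}-Accumbens-area" for s in ("Left", "Right")], -0.2, -0.5)
    put([f"{s}-Thalamus" for s in ("Left", "Right")], -0.15, -0.4)
    put([f"{s}-Putamen" for s in ("Left", "Right")], -0.15, -0.4)
    put([f"{s}-Lateral-Ventricle" for s in ("Left", "Right")], 0.4, 1.0)
    put(["3rd-Ventricle"], 0.3, 0.8)
    put([BPV_FEATURE], -0.25, -0.6)
    put([f"ctx-{h}-entorhinal" for h in ("lh", "rh")], -0.5, -1.1)
    put([f for f in _TEMPORAL_CT if "entorhinal" not in f], -0.3, -0.8)
    put([f"ctx-{h}-isthmuscingulate" for h in ("lh", "rh")], -0.25, -0.6)
    put(_PARIETAL_CT, -0.2, -0.5)
    put(["WholeBrain-MD"], 0.4, 1.0)
    put(["WholeBrain-FA"], -0.3, -0.7)
    put(["Left-Hippocampus-MD", "Right-Hippocampus-MD"], 0.5, 1.1)
    put(["TBSS-Skeleton-FA"], -0.3, -0.7)
    return eff


def default_confound_config() -> dict[str, tuple[float, float]]:
    """Per-feature (age, sex) loadings in sd units: sd per year of age
    (centered at 74) and sd per unit of sex (M=0, F=1, centered at 0.5).
    Linear by construction, so OLS residualization removes them exactly
    in expectation."""
    conf: dict[str, tuple[float, float]] = {}
    for f in SV_FEATURES:
        conf[f] = (0.04 if "Ventricle" in f else -0.04, 0.0)
    for f in CT_FEATURES:
        conf[f] = (-0.03, 0.0)
    conf[BPV_FEATURE] = (-0.05, 0.10)
    conf["Left-Hippocampus"] = (-0.04, 0.10)
    conf["Right-Hippocampus"] = (-0.04, 0.10)
    conf["WholeBrain-MD"] = (0.03, 0.0)
    conf["WholeBrain-FA"] = (-0.02, 0.0)
    conf["Left-Hippocampus-MD"] = (0.03, 0.0)
    conf["Right-Hippocampus-MD"] = (0.03, 0.0)
    conf["TBSS-Skeleton-FA"] = (-0.02, 0.0)
    return conf


def default_connectome_targets() -> list[str]:
    """Regions whose incident edges are attenuated in MCI/ADD (medial
    temporal network)."""
    return ([f"{s}-Hippocampus" for s in ("Left", "Right")]
            + [f"{s}-Amygdala" for s in ("Left", "Right")]
            + _TEMPORAL_CT)


@dataclass
class ConnectomeConfig:
    density: float = 0.3                 # fraction of node pairs connected
    distance_scale: float = 0.35         # geometric weight decay length
    base_strength: float = 200.0         # fiber-count-like weight scale
    noise_sigma: float = 0.25            # lognormal subject noise (mean 1)
    attenuation: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.0, "MCI": 0.12, "ADD": 0.30})
    target_regions: list[str] = field(default_factory=default_connectome_targets)


@dataclass
class VisitConfig:
    span_months_min: float = 48.0        # last-visit time range; mean 79.2
    span_months_max: float = 110.4       # months = 6.6 years mean follow-up
    interval_months: float = 12.0
    visit_noise_sd: float = 0.8          # per-visit MMSE measurement noise


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_per_group: tuple[int, int, int] = (228, 120, 46)
    seed: int = 0
    profiles: dict[str, GroupProfile] = field(default_factory=_default_profiles)
    age_range: tuple[float, float] = (55.0, 96.0)
    edu_range: tuple[float, float] = (8.0, 20.0)
    etiv_mean: float = 1.5e6             # mm^3
    etiv_sd: float = 1.2e5
    etiv_sex_shift: float = 7.5e4        # males larger by 2x this, +/- around mean
    effect_config: dict[str, dict[str, float]] = field(
        default_factory=default_effect_config)
    confound_config: dict[str, tuple[float, float]] = field(
        default_factory=default_confound_config)
    noise_sd: float = 1.0                # multiplier on baseline feature sd
    connectome: ConnectomeConfig = field(default_factory=ConnectomeConfig)
    visits: VisitConfig = field(default_factory=VisitConfig)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group):
            raise CohortError("group counts must be >= 0")
        if self.noise_sd < 0:
            raise CohortError("noise_sd must be >= 0")
        for g, p in self.profiles.items():
            if not 0.0 <= p.abeta_prevalence <= 1.0:
                raise CohortError(f"abeta prevalence for {g} not in [0, 1]")
            if p.age_sd < 0 or p.edu_sd < 0 or p.mmse_sd < 0:
                raise CohortError(f"negative sd in profile for {g}")
        if self.visits.interval_months <= 0 or self.visits.span_months_min < 0:
            raise CohortError("visit spacing must be positive")
        if self.visits.span_months_max < self.visits.span_months_min:
            raise CohortError("visit span range inverted")
        unknown = set(self.effect_config) - set(FEATURE_SCALES)
        if unknown:
            raise CohortError(f"unknown features in effect_config: "
                              f"{sorted(unknown)[:5]}")


def _subject_rng(seed: int, uid: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, uid, stream]))


def _uid(group_idx: int, j: int) -> int:
    return group_idx * 1_000_000 + j


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw demographics for sum(n_per_group) subjects, group by group.

    Deterministic for a fixed seed; per-subject substreams mean that
    enlarging one group leaves all other subjects' draws unchanged.
    """
    if sum(config.n_per_group) == 0:
        raise CohortError("all group counts are zero: empty cohort")
    cohort: list[SubjectRecord] = []
    lo_age, hi_age = config.age_range
    for gi, group in enumerate(GROUPS):
        prof = config.profiles[group]
        for j in range(config.n_per_group[gi]):
            rng = _subject_rng(config.seed, _uid(gi, j), _STREAM_DEMOGRAPHICS)
            sex = "M" if rng.random() < prof.male_frac else "F"
            age = float(np.clip(rng.normal(prof.age_mean, prof.age_sd),
                                lo_age, hi_age))
            edu = float(np.clip(rng.normal(prof.edu_mean, prof.edu_sd),
                                *config.edu_range))
            etiv_mu = config.etiv_mean + (config.etiv_sex_shift if sex == "M"
                                          else -config.etiv_sex_shift)
            etiv = float(max(rng.normal(etiv_mu, config.etiv_sd), 8e5))
            abeta = int(rng.random() < prof.abeta_prevalence)
            cohort.append(SubjectRecord(
                subject_id=f"{group}-{j:04d}", diagnosis=group, age=age,
                sex=sex, education=edu, etiv=etiv, abeta_status=abeta))
    return cohort


def _subject_uid(subject: SubjectRecord) -> int:
    group, j = subject.subject_id.rsplit("-", 1)
    return _uid(GROUPS.index(subject.diagnosis), int(j))


def generate_mo_ms_features(cohort: list[SubjectRecord],
                            config: CohortConfig) -> FeatureTable:
    """Generate the 91 morphometric + 5 microstructural features.

    Each feature = subject template (fraction-of-eTIV for volumes,
    absolute mean otherwise) + planted group shift + linear age/sex
    confound + Gaussian noise, all in units of the feature's baseline sd.
    """
    if not cohort:
        raise CohortError("cohort is empty")
    columns = MO_FEATURES + MS_FEATURES
    rows = np.empty((len(cohort), len(columns)))
    for i, subj in enumerate(cohort):
        rng = _subject_rng(config.seed, _subject_uid(subj), _STREAM_FEATURES)
        noise = rng.standard_normal(len(columns))
        sex01 = 0.0 if subj.sex == "M" else 1.0
        for k, feat in enumerate(columns):
            kind, loc, base_sd = FEATURE_SCALES[feat]
            mu = loc * subj.etiv if kind == "volume" else loc
            shift = config.effect_config.get(feat, {}).get(subj.diagnosis, 0.0)
            age_load, sex_load = config.confound_config.get(feat, (0.0, 0.0))
            rows[i, k] = (mu
                          + shift * base_sd
                          + age_load * (subj.age - 74.0) * base_sd
                          + sex_load * (sex01 - 0.5) * base_sd
                          + config.noise_sd * base_sd * noise[k])
    data = pd.DataFrame(rows, index=[s.subject_id for s in cohort],
                        columns=columns)
    tags = {c: default_tags()[c] for c in columns}
    return FeatureTable(data, tags)


def abeta_table(cohort: list[SubjectRecord]) -> FeatureTable:
    data = pd.DataFrame({ABETA_FEATURE: [s.abeta_status for s in cohort]},
                        index=[s.subject_id for s in cohort], dtype=float)
    return FeatureTable(data, {ABETA_FEATURE: "ABETA"})


@dataclass
class ConnectivityMatrix:
    """82x82 symmetric non-negative weighted adjacency with region labels."""

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.shape != (n, n):
            raise CohortError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise CohortError("connectivity matrix must be symmetric")
        if (w < 0).any():
            raise CohortError("connectivity weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.weights, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def connectome_template(config: CohortConfig) -> np.ndarray:
    """Shared distance-penalized random-geometric template (82x82).

    Nodes get random 3-D coordinates; pairwise weight decays with
    Euclidean distance; the closest ``density`` fraction of pairs keeps a
    positive weight.  Deterministic per cohort seed, independent of n.
    """
    cc = config.connectome
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _TEMPLATE_UID]))
    n = len(CONNECTOME_REGIONS)
    coords = rng.uniform(size=(n, 3))
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    w = cc.base_strength * np.exp(-d / cc.distance_scale)
    iu = np.triu_indices(n, k=1)
    thresh = np.quantile(w[iu], 1.0 - cc.density)
    w[w < thresh] = 0.0
    np.fill_diagonal(w, 0.0)
    w = np.triu(w, 1)
    return w + w.T


def generate_connectomes(cohort: list[SubjectRecord],
                         config: CohortConfig,
                         template: np.ndarray | None = None,
                         ) -> list[ConnectivityMatrix]:
    """One 82x82 matrix per subject: template x group attenuation on the
    medial-temporal edge subset x mean-one log-normal subject noise."""
    if not cohort:
        raise CohortError("cohort is empty")
    cc = config.connectome
    if template is None:
        template = connectome_template(config)
    template = np.asarray(template, dtype=float)
    if not np.allclose(template, template.T):
        raise CohortError("connectome template must be symmetric")
    labels = list(CONNECTOME_REGIONS)
    n = len(labels)
    target_idx = np.array([labels.index(r) for r in cc.target_regions
                           if r in labels], dtype=int)
    on_target = np.zeros((n, n), dtype=bool)
    if target_idx.size:
        on_target[target_idx, :] = True
        on_target[:, target_idx] = True
    iu = np.triu_indices(n, k=1)
    out: list[ConnectivityMatrix] = []
    for subj in cohort:
        rng = _subject_rng(config.seed, _subject_uid(subj), _STREAM_CONNECTOME)
        atten = cc.attenuation.get(subj.diagnosis, 0.0)
        factor = np.where(on_target, 1.0 - atten, 1.0)
        if cc.noise_sigma > 0:
            ln = np.zeros((n, n))
            draw = rng.normal(-0.5 * cc.noise_sigma ** 2, cc.noise_sigma,
                              size=iu[0].size)
            ln[iu] = draw
            ln = ln + ln.T
            noise = np.exp(ln)
        else:
            noise = 1.0
        w = template * factor * noise
        np.fill_diagonal(w, 0.0)
        out.append(ConnectivityMatrix(labels, w))
    return out


def generate_mmse_trajectories(cohort: list[SubjectRecord],
                               config: CohortConfig) -> list[SubjectRecord]:
    """Attach >= 2 MMSE visits per subject: baseline + rate*years + noise,
    clipped to [0, 30].  Visits run at a fixed interval up to a random
    per-subject span whose mean matches a ~6.6-year follow-up."""
    vc = config.visits
    out: list[SubjectRecord] = []
    for subj in cohort:
        rng = _subject_rng(config.seed, _subject_uid(subj), _STREAM_MMSE)
        prof = config.profiles[subj.diagnosis]
        baseline = float(np.clip(rng.normal(prof.mmse_mean, prof.mmse_sd),
                                 0.0, 30.0))
        rate = rng.normal(prof.decline_rate_mean, prof.decline_rate_sd)
        span = rng.uniform(vc.span_months_min, vc.span_months_max)
        times = list(np.arange(0.0, span, vc.interval_months))
        if not times or times[-1] < span:
            times.append(span)
        visits = []
        for t in times:
            noise = (rng.normal(0.0, vc.visit_noise_sd)
                     if vc.visit_noise_sd > 0 and t > 0 else 0.0)
            visits.append(MmseVisit(t, baseline + rate * (t / 12.0) + noise))
        out.append(replace(subj, mmse_visits=visits))
    return out


# ---------------------------------------------------------------------------
# Cohort I/O: CSV/TSV round trip for all generated artifacts.
# ---------------------------------------------------------------------------

def cohort_demographics(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"diagnosis": [s.diagnosis for s in cohort],
         "age": [s.age for s in cohort],
         "sex": [s.sex for s in cohort],
         "education": [s.education for s in cohort],
         "etiv": [s.etiv for s in cohort],
         "abeta_status": [s.abeta_status for s in cohort]},
        index=pd.Index([s.subject_id for s in cohort], name="subject_id"))


def mmse_long_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    rows = [(s.subject_id, v.months_from_baseline, v.mmse)
            for s in cohort for v in s.mmse_visits]
    return pd.DataFrame(rows, columns=["subject_id", "months_from_baseline",
                                       "mmse"])


def save_cohort(out_dir: str, cohort: list[SubjectRecord],
                features: FeatureTable | None = None,
                connectomes: list[ConnectivityMatrix] | None = None) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cohort_demographics(cohort).to_csv(os.path.join(out_dir, "subjects.csv"))
    mmse = mmse_long_table(cohort)
    if len(mmse):
        mmse.to_csv(os.path.join(out_dir, "mmse.csv"), index=False)
    if features is not None:
        features.to_csv(os.path.join(out_dir, "features.csv"))
    if connectomes is not None:
        cdir = os.path.join(out_dir, "connectomes")
        os.makedirs(cdir, exist_ok=True)
        for subj, cm in zip(cohort, connectomes):
            cm.to_tsv(os.path.join(cdir, f"{subj.subject_id}.tsv"))


def load_cohort(in_dir: str) -> list[SubjectRecord]:
    demo = pd.read_csv(os.path.join(in_dir, "subjects.csv"),
                       index_col="subject_id")
    visits: dict[str, list[MmseVisit]] = {}
    mmse_path = os.path.join(in_dir, "mmse.csv")
    if os.path.exists(mmse_path):
        for _, row in pd.read_csv(mmse_path).iterrows():
            visits.setdefault(row["subject_id"], []).append(
                MmseVisit(row["months_from_baseline"], row["mmse"]))
    return [SubjectRecord(sid, r["diagnosis"], r["age"], r["sex"],
                          r["education"], r["etiv"], int(r["abeta_status"]),
                          visits.get(sid, []))
            for sid, r in demo.iterrows()]
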