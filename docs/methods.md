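# Methods

`neurostack` implements a systematic evaluation of multimodal MRI-derived
feature sets — morphometric (MO), microstructural (MS), and
graph-theoretical (GT) — for Alzheimer's disease stage classification
(DSC) and longitudinal cognitive decline prediction (LCDP). Because the
clinical imaging data it targets (ADNI) are access-controlled, the
package ships a first-class synthetic cohort generator that emulates the
statistical structure the analysis assumes, so every stage of the
pipeline is testable end to end.

## Synthetic cohort model

Each subject belongs to one of three diagnostic groups (CN, MCI, ADD).
Demographics are drawn per group from Gaussian profiles matching a
typical ADNI-style composition: group sizes default to 228/120/46; age
means (years) 73.48 / 74.65 / 75.48 with SDs 7.51 / 8.57 / 9.30, clipped
to [55, 96]; male fractions 129/228, 55/120, 22/46; education means
16.71 / 16.13 / 15.35 years; amyloid-positivity prevalences 138/228,
60/120, 37/46. eTIV is Gaussian (mean 1.5e6 mm³, SD 1.2e5) with a
±7.5e4 mm³ sex offset (males larger).

**Imaging features.** The 91 MO features are 22 subcortical /
ventricular / callosal volumes (mm³), 68 Desikan-Killiany cortical
thicknesses (mm), and brain parenchymal volume; the 5 MS features are
whole-brain MD and FA, left/right hippocampal MD, and TBSS-skeleton FA.
Each feature is generated as

    x = template + d_g·σ + a·(age − 74)·σ + s·(sex − ½)·σ + noise_sd·σ·ε

where the template is fraction-of-eTIV × eTIV for volumes (so that eTIV
normalization is meaningful) and an absolute mean for thickness and
diffusion features; σ is the feature's baseline between-subject SD;
d_g is the planted standardized group shift (defaults: hippocampal and
medial-temporal atrophy, ventricular enlargement, raised diffusivity and
reduced anisotropy, graded MCI < ADD); a and s are linear age/sex
confound loadings. Confounds are linear by construction, so OLS
residualization removes them exactly in expectation, making the
leakage-safety properties of the adjustment pipeline directly testable.
Effect sizes are expressed in units of σ so that a planted shift of −1.0
is recoverable as a standardized mean difference of −1.0 (Monte-Carlo
checked to 3 standard errors).

**Connectomes.** Each subject gets an 82×82 symmetric non-negative
matrix over the 82 DK regions (84 minus the two cerebellar cortices).
A shared template places the 82 nodes at random 3-D coordinates and
keeps the closest 30% of pairs with distance-decaying, fiber-count-like
weights (~200·exp(−d/0.35)); this distance-penalized random-geometric
construction gives non-degenerate clustering, path, and community
structure. Per subject, edges incident to medial-temporal regions are
attenuated multiplicatively per group (defaults 0%, 12%, 30% for
CN/MCI/ADD) and every edge is multiplied by mean-one log-normal noise
(σ = 0.25). Because attenuation and noise are strictly positive and
multiplicative, the binary support is identical across subjects: purely
structural GT features (degree centrality, density, degree entropy) are
constant in a default cohort and are mapped to zero by the standardizer's
constant-feature rule. This is a known, accepted simplification; real
tractography also varies edge presence.

**MMSE trajectories.** MMSE = baseline + rate·years + visit noise,
clipped to [0, 30]. Baselines follow group profiles (28.89 / 27.69 /
21.39, SDs 1.35 / 2.11 / 4.27); annual decline rates default to −0.05 /
−0.6 / −2.5 points/year (SDs 0.10 / 0.50 / 1.20) — near-flat normal
aging, intermediate MCI decline, steep dementia decline. Visits run
every 12 months up to a per-subject span drawn Uniform(48, 110.4)
months, so the mean first-to-last follow-up is 6.6 years.

Randomness is keyed per (cohort seed, subject, substream), so outputs
are bit-identical across runs and enlarging one group never perturbs
other subjects' draws.

## Graph metrics

Connectomes become undirected weighted graphs (edge present iff weight
> 0). Nodal metrics (7 per region): geometric-mean weighted clustering,
degree centrality, eigenvector centrality (leading eigenvector of the
weighted adjacency, unit 2-norm), closeness and betweenness on
inverse-weight distances with standard normalizations, node strength,
and PageRank (damping 0.85). Global metrics (17): density, modularity
(greedy agglomerative maximization — deterministic, unlike Louvain),
weighted degree assortativity (0 by convention on degree-regular graphs,
where the correlation is undefined), transitivity, global efficiency
(mean inverse shortest-path distance, 0 for unreachable pairs),
characteristic path length and diameter (largest component), small-
worldness, degree-distribution entropy (natural log over observed
distinct degrees), spectral radius, and means of degree and of the
seven nodal metrics. The full vector is 7·82 + 17 = 591 features in a
frozen metric-major name order.

Small-worldness uses the ratio form (C/C_rand)/(L/L_rand) against 10
degree-preserving rewired references (10·|E| swap attempts each, seeded;
the binary structure is rewired and the original weight multiset
re-assigned by random permutation). Desk-scale runs in the test suite
and acceptance script use 2 references — the reference count affects
only SW, and the package's property checks do not depend on its
precision.

Shortest-path-based metrics use distance = 1/weight exactly. With
fiber-count-scale weights this places closeness, efficiency, CPL, and
diameter on a 1/weight scale rather than in [0, 1]; the scale-invariant
metrics (clustering, degree centrality, PageRank, density, transitivity)
remain in [0, 1] regardless of weight units. All shortest-path metrics
are verified against exhaustive simple-path enumeration on ≤ 6-node
graphs.

## Covariate adjustment

ΔMMSE (points/year) = (MMSE_followup − MMSE_visit)/(months/12), using
each subject's first and last visit (the pair maximizing elapsed time;
subjects with fewer than two visits are excluded). Volumetric features
(the 22 SV features, and BPV by default — toggleable, since BPV sits
outside the named SV list) are divided by eTIV per subject; cortical
thickness is not eTIV-normalized. All imaging-derived features (MO, MS,
and GT alike) are then residualized per feature against age and sex
(OLS on [1, age, sex]; sex coded M=0/F=1; pseudoinverse with a warning
on rank-deficient folds) and z-scored. Both transforms are fitted on the
training fold only and applied unchanged to held-out data; the
standardizer uses the population (÷n) SD by default with a sample-SD
toggle. Amyloid status is appended after adjustment and left as raw
{0, 1} — it is not imaging-derived. Constant training features z-score
to 0 with a warning.

## Ablation engine

Tasks: CN-ADD, CN-MCI, MCI-ADD (binary, impaired class positive) and
LCDP (ΔMMSE regression over all diagnoses). Feature sets: MO, MS, GT and
their pairwise/three-way unions, always plus amyloid status (92 / 6 /
592 / 688 columns for MO / MS / GT / MO+MS+GT) — 28 runs in the default
grid. Each run: stratified 80/20 hold-out with per-class half-up
rounding of the test count (this reproduces 219/55, 278/70, 133/33, and
124/31 for the four reference cohort compositions), then 5-outer /
3-inner nested CV on the 80% portion. Covariate transforms are fitted
inside each outer training fold; the inner grid search (selection
metric: balanced accuracy for classification, negative MAE for
regression) runs on the transformed outer-train. Base learners — LogR,
LDA, DT, RF, AdaBoost, XGB, SVM for classification; Ridge, DT, RF,
AdaBoost, XGB, GPR, SVR for regression — are standard scikit-learn /
xgboost estimators behind a registry; the registry and default grids
(log-spaced regularization strengths, tree depths {3, 5, 10, ∞}, etc.)
are the package's contract and are config-overridable, including a
reduced `small_grids` variant for desk-scale runs. The decision
threshold is fixed at 0.5; rocAUC is computed from probabilities.

## Diversity-aware stacking

Pairwise Pearson correlations between aligned OOF prediction vectors
measure redundancy; pairs are processed greedily in descending
correlation and, while any retained pair exceeds τ = 0.85, the worse
performer (mean fold BACC, or negated MAE; ties broken lexicographically
by model id) is discarded. Constant OOF vectors are defined maximally
redundant (ρ := 1) so degenerate models are pruned first; the pool never
empties. Retained models' OOF predictions (class-1 probabilities for
classification) form the meta-features of a logistic / ridge meta-model
trained exclusively on pooled OOF predictions. Ensemble fold metrics are
computed on the same outer folds as the base models.

Ensemble importance propagates base attributions through the stacking
weights, I_j = Σ_m |w_m|·|β_j^(m)|, normalized to sum to 1. For linear
models β^(m) are coefficient magnitudes; for tree ensembles, native
normalized impurity importances; models exposing neither (e.g. an RBF
kernel machine) are excluded from the sum with a warning. A
model-agnostic permutation importance (mean metric drop over seeded
column shuffles) is provided alongside, and the attribution hook is
generic so external explainers can be plugged in.

Hold-out evaluation refits each retained base model on the full 80%
training portion using the hyperparameters most frequently selected
across outer folds, and reports hold-out metrics separately from the
nested-CV fold summaries (both views are labeled in the results table).

## Statistics

A-priori comparisons per task — MO vs. MO+MS, and MO+MS vs. MO+MS+GT —
use paired one-sided Wilcoxon signed-rank tests on ensemble fold metrics
(BACC for classification, MAE with differences negated so positive means
improvement). Zero differences are dropped; tied |d| receive average
ranks; for n ≤ 12 usable folds the p-value is exact by enumeration of
all 2^n sign assignments (verified against an independent enumeration
oracle), with a tie-corrected normal approximation above. With 5 folds
the smallest attainable exact p is 1/32 ≈ 0.031, so α = 0.05 is
effectively conservative (empirical null rejection ≈ 0.03); this is
stated in the report footer. No multiple-comparison correction is
applied to the a-priori plan.

Uncertainty on OOF metrics uses percentile bootstrap (default B = 1000,
seeded) over subject-level resamples, with classification resamples
required to contain both classes (100-retry cap); intervals are anchored
to contain the point estimate. ROC curves carry pointwise percentile
bands on a fixed 101-point FPR grid.

## Problem sizes and limitations

The default generator reproduces the reference cohort sizes (394 and 155
subjects); the test suite and acceptance script run scaled-down cohorts
(tens of subjects per group, reduced grids, 2 small-world references) as
the package's own desk-scale configuration of the same procedures. The
generator emulates group effects, confounding, and noise but not
scanner/site effects, non-linear age trends, edge-presence variability,
longitudinal imaging, or missingness — so passing tests demonstrate the
pipeline's correctness and the recoverability of planted structure, not
clinical performance on real data. Gaussian sampling with clipping
slightly biases extreme-group means; Monte-Carlo checks use 3-standard-
error tolerances at the configured n.
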