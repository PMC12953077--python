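# neurostack

Systematic evaluation of multimodal MRI-derived feature sets for
Alzheimer's disease staging and cognitive decline prediction.

Structural MRI yields morphometric (**MO**) features — regional volumes
and cortical thickness; diffusion MRI yields microstructural (**MS**)
features — FA/MD summaries; and structural connectomes yield
graph-theoretical (**GT**) network metrics. Whether stacking these
modalities actually improves machine-learning prediction of disease
stage (CN vs. MCI vs. ADD) or of annualized MMSE decline is an
ablation question. `neurostack` is a tested, reusable pipeline for
exactly that question, built for methodologists who want the full
leakage-safe machinery — synthetic cohorts included, since the clinical
source data (ADNI) are access-controlled.

## What it does

* **Synthetic cohorts** (`neurostack.cohort`): ADNI-style three-group
  cohorts with realistic group demographics, 91 MO + 5 MS features carrying
  planted group effects and linear age/sex confounds, 82×82 weighted
  structural connectomes with group-attenuated medial-temporal edges,
  and per-visit MMSE trajectories. Deterministic per (seed, subject).
* **Connectome metrics** (`neurostack.graphs`): the 591-element GT
  vector — 7 nodal metrics × 82 Desikan-Killiany regions (clustering,
  degree/eigenvector/closeness/betweenness centrality, strength,
  PageRank) plus 17 global metrics (density, modularity, assortativity,
  transitivity, efficiency, CPL, diameter, small-worldness, degree
  entropy, spectral radius, nodal averages). Shortest paths run on
  inverse-weight distances.
* **Covariate adjustment** (`neurostack.adjust`): ΔMMSE =
  (MMSE_followup − MMSE_visit)/years; eTIV normalization of volumes;
  per-feature OLS residualization on age and sex and z-scoring, fitted
  on training folds only and applied unchanged to held-out data.
* **Ablation engine** (`neurostack.ablation`): 7 feature-set
  combinations × 4 tasks = 28 runs; stratified 80/20 hold-out; 5-outer /
  3-inner nested CV with grid search over 7 heterogeneous learners per
  task (LogR, LDA, DT, RF, AdaBoost, XGB, SVM / Ridge … GPR, SVR);
  ACC/BACC/SEN/SPE/rocAUC and MAE/MSE/RMSE/R² suites.
* **Diversity-aware stacking** (`neurostack.ensemble`): out-of-fold
  prediction correlation pruning at τ = 0.85 (worse performer of a
  redundant pair is dropped), logistic/ridge meta-model trained on
  pooled OOF predictions only, and propagated feature importance
  I_j = Σ_m |w_m|·|β_j^(m)|.
* **Statistics & reporting** (`neurostack.stats`): paired one-sided
  Wilcoxon signed-rank tests across folds (exact by 2ⁿ enumeration for
  n ≤ 12), percentile bootstrap CIs (B = 1000) on OOF metrics, ROC
  confidence bands, permutation importance, and a CSV/JSON report
  bundle.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

A scaled-down CN-vs-ADD ablation (30 CN / 20 ADD, reduced grids) over
three nested feature sets:

```python
import neurostack as ns
from neurostack.ablation import (ExperimentConfig, run_single,
                                 prepare_feature_table)
from neurostack.cohort import CohortConfig, abeta_table
from neurostack.stats import compare_feature_sets

cfg = CohortConfig(n_per_group=(30, 0, 20), seed=11)
cohort = ns.generate_mmse_trajectories(ns.generate_cohort(cfg), cfg)
mo_ms = ns.generate_mo_ms_features(cohort, cfg)
gt = ns.gt_feature_table(ns.generate_connectomes(cohort, cfg), seed=11,
                         subject_ids=[s.subject_id for s in cohort],
                         n_random_refs=2)
full = prepare_feature_table(mo_ms, gt, abeta_table(cohort), cohort)

exp = ExperimentConfig(small_grids=True)
results = {("CN-ADD", fs): run_single("CN-ADD", fs, full, cohort, exp)
           for fs in ("MO", "MO+MS", "MO+MS+GT")}
for (task, fs), run in results.items():
    bacc = run.fold_metrics["Ensemble"]["BACC"]
    print(f"{fs:9s} ensemble BACC {bacc.mean():.3f} +/- {bacc.std():.3f} "
          f"({len(run.ensemble.retained)}/7 models retained)")
for c in compare_feature_sets(results, tasks=["CN-ADD"]):
    print(f"{c.label}: W={c.w}, p={c.p_value:.3f}")
```

prints

```
MO        ensemble BACC 0.913 +/- 0.124 (7/7 models retained)
MO+MS     ensemble BACC 0.875 +/- 0.072 (6/7 models retained)
MO+MS+GT  ensemble BACC 1.000 +/- 0.000 (1/7 models retained)
CN-ADD: MO vs. MO+MS: W=1.0, p=0.875
CN-ADD: MO+MS vs. MO+MS+GT: W=10.0, p=0.062
```

Each line is the mean ± SD balanced accuracy over the 5 outer CV folds
of the pruned stacking ensemble. The default generator plants both
atrophy and connectome attenuation, so adding GT features here makes
the task fully separable and the base models so concordant (pairwise
OOF correlation > 0.85) that pruning keeps a single learner. The
Wilcoxon rows test, one-sided across the 5 paired folds, whether each
feature-set addition improved BACC; with 5 folds the smallest attainable
exact p is 1/32 ≈ 0.031, so neither addition is significant at
α = 0.05.

The same pipeline is available from the shell:

```bash
neurostack simulate --out data/ --seed 1 --n-per-group 30 0 20
neurostack extract-gt --in data/connectomes --out gt.csv --seed 1
neurostack run --config experiment.yaml --out results/
neurostack compare --results results/
neurostack report --results results/ --out report/
```

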