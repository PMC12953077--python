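"""Wilcoxon exactness, bootstrap behavior, ROC bands, reporting."""

import itertools
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurostack.stats import (ReportError, bootstrap_ci, compare_feature_sets,
                              permutation_importance, render_report,
                              roc_with_bands, wilcoxon_one_sided)


def oracle_wilcoxon(d):
    """Independent exact oracle: average ranks via sorting, p by itertools
    enumeration over sign subsets."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n)
    sorted_abs = np.abs(d)[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        if sum(r for r, s in zip(ranks, signs) if s) >= w_obs - 1e-12:
            count += 1
    return w_obs, count / 2 ** n


class TestWilcoxon:
    def test_all_positive_differences(self):
        c = wilcoxon_one_sided(np.array([1, 2, 3, 4, 5.0]), np.zeros(5))
        assert c.w == 15.0
        assert c.p_value == pytest.approx(1 / 32)

    def test_mixed_differences(self):
        c = wilcoxon_one_sided(np.array([1, -2, 3, -4, 5.0]), np.zeros(5))
        assert c.w == 9.0
        assert c.p_value == pytest.approx(13 / 32)

    def test_identical_arms_degenerate(self):
        x = np.array([0.7, 0.8, 0.9])
        c = wilcoxon_one_sided(x, x)
        assert c.degenerate and c.p_value == 1.0 and not c.significant

    def test_lower_is_better_orientation(self):
        # arm x has uniformly lower error -> improvement, small p
        x = np.array([0.30, 0.31, 0.29, 0.28, 0.33])
        y = x + 0.1
        c = wilcoxon_one_sided(x, y, higher_is_better=False)
        assert c.p_value == pytest.approx(1 / 32)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = np.round(rng.standard_normal(n), 1)  # rounding induces ties
        c = wilcoxon_one_sided(d, np.zeros(n))
        w, p = oracle_wilcoxon(d)
        assert c.w == pytest.approx(w)
        assert c.p_value == pytest.approx(p)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-20, 20).map(lambda v: v / 4.0),
                    min_size=1, max_size=12).filter(
                        lambda d: any(v != 0 for v in d)))
    def test_exact_p_property(self, diffs):
        """For any difference vector with n <= 12 the p-value equals the
        full sign-enumeration probability (ties and zeros included)."""
        c = wilcoxon_one_sided(np.array(diffs), np.zeros(len(diffs)))
        w, p = oracle_wilcoxon(diffs)
        assert c.w == pytest.approx(w)
        assert c.p_value == pytest.approx(p)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal(30) + 0.5
        c = wilcoxon_one_sided(d, np.zeros(30))
        assert 0.0 < c.p_value < 0.05


def _fake_results():
    rng = np.random.default_rng(10)

    def run(kind, shift=0.0):
        metric = "BACC" if kind == "classification" else "MAE"
        return SimpleNamespace(kind=kind, fold_metrics={
            "Ensemble": pd.DataFrame(
                {metric: 0.7 + shift + 0.05 * rng.standard_normal(5)})})

    results = {}
    for task in ("CN-ADD", "CN-MCI", "MCI-ADD"):
        for fs in ("MO", "MO+MS", "MO+MS+GT"):
            results[(task, fs)] = run("classification")
    for fs in ("MO", "MO+MS", "MO+MS+GT"):
        results[("LCDP", fs)] = run("regression")
    return results


class TestCompareFeatureSets:
    def test_default_plan_yields_eight_comparisons(self):
        comps = compare_feature_sets(_fake_results())
        assert len(comps) == 8
        assert all(c.label for c in comps)

    def test_identical_arms_all_degenerate(self):
        results = _fake_results()
        shared = results[("CN-ADD", "MO")]
        results[("CN-ADD", "MO+MS")] = shared
        results[("CN-ADD", "MO+MS+GT")] = shared
        comps = compare_feature_sets(results, tasks=["CN-ADD"])
        assert all(c.degenerate for c in comps)

    def test_dominating_arm_significant_at_five_folds(self):
        results = _fake_results()
        base = results[("CN-ADD", "MO")].fold_metrics["Ensemble"]["BACC"]
        results[("CN-ADD", "MO+MS")] = SimpleNamespace(
            kind="classification",
            fold_metrics={"Ensemble": pd.DataFrame({"BACC": base + 0.1})})
        comps = compare_feature_sets(results, tasks=["CN-ADD"])
        mo_vs_moms = comps[0]
        assert mo_vs_moms.p_value == pytest.approx(1 / 32)
        assert mo_vs_moms.significant

    def test_missing_arm_rejected(self):
        results = _fake_results()
        del results[("CN-ADD", "MO+MS")]
        with pytest.raises(ReportError):
            compare_feature_sets(results, tasks=["CN-ADD"])


class TestBootstrapCI:
    def test_degenerate_metric_zero_width(self):
        oof = pd.DataFrame({"y_true": [1, 0, 1, 0], "pred": [1, 0, 1, 0.0]})
        ci = bootstrap_ci(oof, lambda y, p: float((y == p).mean()),
                          B=100, seed=0, classification=True)
        assert (ci.lower, ci.estimate, ci.upper) == (1.0, 1.0, 1.0)

    def test_deterministic_per_seed_and_default_iterations(self):
        rng = np.random.default_rng(11)
        oof = pd.DataFrame({"y_true": rng.standard_normal(50),
                            "pred": rng.standard_normal(50)})
        a = bootstrap_ci(oof, lambda y, p: float(np.mean(y)), seed=3)
        b = bootstrap_ci(oof, lambda y, p: float(np.mean(y)), seed=3)
        assert a.iterations == 1000
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.lower <= a.estimate <= a.upper

    def test_nominal_coverage_for_gaussian_mean(self):
        rng = np.random.default_rng(12)
        hits = 0
        for rep in range(200):
            y = rng.standard_normal(100)
            oof = pd.DataFrame({"y_true": y, "pred": y})
            ci = bootstrap_ci(oof, lambda yy, pp: float(np.mean(yy)),
                              B=200, seed=rep)
            hits += ci.lower <= 0.0 <= ci.upper
        assert 0.89 <= hits / 200 <= 0.99

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(13)
        widths = []
        for n in (50, 800):
            y = rng.standard_normal(n)
            oof = pd.DataFrame({"y_true": y, "pred": y})
            ci = bootstrap_ci(oof, lambda yy, pp: float(np.mean(yy)),
                              B=300, seed=0)
            widths.append(ci.upper - ci.lower)
        assert widths[1] < widths[0]


class TestRocBands:
    def test_perfect_scorer(self):
        oof = pd.DataFrame({"y_true": [0, 0, 1, 1], "pred": [0.1, 0.2, 0.8, 0.9]})
        roc = roc_with_bands(oof, B=50, seed=0)
        assert roc.loc[roc["fpr"] == 0.0, "tpr"].iloc[-1] == 1.0
        assert np.trapezoid(roc["tpr"], roc["fpr"]) == pytest.approx(1.0, abs=0.02)

    def test_random_scorer_near_half(self):
        rng = np.random.default_rng(14)
        oof = pd.DataFrame({"y_true": rng.integers(0, 2, 400),
                            "pred": rng.uniform(size=400)})
        roc = roc_with_bands(oof, B=50, seed=0)
        auc = np.trapezoid(roc["tpr"], roc["fpr"])
        assert abs(auc - 0.5) < 0.1

    def test_band_contains_point_curve(self):
        rng = np.random.default_rng(15)
        y = rng.integers(0, 2, 100)
        oof = pd.DataFrame({"y_true": y,
                            "pred": np.clip(y * 0.4 + rng.uniform(size=100),
                                            0, 1)})
        roc = roc_with_bands(oof, B=200, seed=0)
        assert (roc["band_lo"] <= roc["tpr"] + 1e-12).all()
        assert (roc["band_hi"] >= roc["tpr"] - 1e-12).all()

    def test_one_class_rejected(self):
        with pytest.raises(ReportError):
            roc_with_bands(pd.DataFrame({"y_true": [1, 1], "pred": [0.5, 0.6]}))


class TestPermutationImportance:
    def _fit(self):
        from sklearn.linear_model import LinearRegression
        rng = np.random.default_rng(16)
        x = pd.DataFrame(rng.standard_normal((200, 3)),
                         columns=["signal", "junk1", "junk2"])
        y = 3.0 * x["signal"].to_numpy() + 0.1 * rng.standard_normal(200)
        return LinearRegression().fit(x.to_numpy(), y), x, y

    def test_planted_signal_ranks_first_and_junk_near_zero(self):
        model, x, y = self._fit()
        metric = lambda yy, pp: -float(np.mean(np.abs(yy - pp)))
        imp = permutation_importance(model, x, y, metric, repeats=5, seed=0)
        assert imp.index[0] == "signal"
        assert imp[["junk1", "junk2"]].abs().max() < 0.1 * imp["signal"]

    def test_deterministic(self):
        model, x, y = self._fit()
        metric = lambda yy, pp: -float(np.mean((yy - pp) ** 2))
        a = permutation_importance(model, x, y, metric, repeats=3, seed=5)
        b = permutation_importance(model, x, y, metric, repeats=3, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_invalid_repeats_rejected(self):
        model, x, y = self._fit()
        with pytest.raises(ReportError):
            permutation_importance(model, x, y, lambda a, b: 0.0, repeats=0)


class TestRenderReport:
    def _mini_results(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 40)
        oof = pd.DataFrame({"fold": np.repeat(np.arange(5), 8),
                            "y_true": y,
                            "pred": np.clip(0.6 * y + 0.4 *
                                            rng.uniform(size=40), 0, 1)},
                           index=[f"s{i}" for i in range(40)])
        run = SimpleNamespace(
            kind="classification",
            fold_metrics={"Ensemble":
                          pd.DataFrame({"BACC": rng.uniform(0.6, 0.9, 5)})},
            oof={"Ensemble": oof},
            ensemble=SimpleNamespace(importance=pd.Series(
                [0.6, 0.4], index=["f1", "f2"])))
        table = pd.DataFrame([
            {"task": "CN-ADD", "feature_set": "MO", "model": "Ensemble",
             "BACC_mean": 0.8, "BACC_sd": 0.05}])
        return table, {("CN-ADD", "MO"): run}

    def test_bundle_files_and_determinism(self, tmp_path):
        table, results = self._mini_results()
        comps = [wilcoxon_one_sided(np.arange(1, 6.0), np.zeros(5),
                                    label="CN-ADD: MO vs. MO+MS")]
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        render_report(table, results, comps, str(out1), roc_bootstrap=50)
        render_report(table, results, comps, str(out2), roc_bootstrap=50)
        for name in ("best_per_task.csv", "comparisons.csv", "results.csv",
                     "summary.json", "importance_top20_CN-ADD_MO.csv",
                     "roc_CN-ADD_MO.csv"):
            assert (out1 / name).exists()
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        comp = pd.read_csv(out1 / "comparisons.csv")
        assert {"W", "p_value"} <= set(comp.columns)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ReportError):
            render_report(pd.DataFrame(), {}, [], str(tmp_path / "x"))

    def test_ensemble_metric_cis(self):
        from neurostack.stats import ensemble_metric_cis
        _, results = self._mini_results()
        run = results[("CN-ADD", "MO")]
        cis = ensemble_metric_cis(run, B=50, seed=0)
        assert [c.metric for c in cis] == ["ACC", "BACC", "SEN", "SPE",
                                           "rocAUC"]
        for c in cis:
            assert c.lower <= c.estimate <= c.upper
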