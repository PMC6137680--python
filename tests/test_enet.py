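import numpy as np
import pandas as pd
import pytest

from conftest import make_xy_frame
from transdrug.enet import (
    aggregate_associations,
    concordance_index,
    feature_set,
    run_enet_models,
    select_drugs,
    summarize_runs,
)
from transdrug.regression import (
    InsufficientDataError,
    RegressionConfig,
    apply_standardization,
    cv_select_lambda,
    fit_enet,
    kfold_split,
    standardize,
)


def brute_force_ci(pred, obs):
    credit = n_pairs = 0
    for i in range(len(pred)):
        for j in range(i + 1, len(pred)):
            if obs[i] == obs[j]:
                continue
            n_pairs += 1
            if pred[i] == pred[j]:
                credit += 0.5
            elif (pred[i] - pred[j]) * (obs[i] - obs[j]) > 0:
                credit += 1
    return credit / n_pairs if n_pairs else float("nan")


class TestConcordanceIndex:
    def test_perfect_reverse_constant(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert concordance_index(obs, obs) == 1.0
        assert concordance_index(obs[::-1], obs) == 0.0
        assert concordance_index(np.ones(3), obs) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.choice([0.0, 0.5, 1.0, 2.0], size=10)
        obs = rng.choice([0.0, 1.0, 2.0], size=10)
        if len(set(obs)) == 1:
            obs[0] += 1
        assert concordance_index(pred, obs) == pytest.approx(brute_force_ci(pred, obs), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        pred, obs = rng.normal(size=15), rng.normal(size=15)
        assert concordance_index(np.exp(pred), obs) == pytest.approx(
            concordance_index(pred, obs), abs=1e-12
        )

    def test_antisymmetry_without_predicted_ties(self):
        rng = np.random.default_rng(4)
        pred, obs = rng.normal(size=12), rng.normal(size=12)
        assert 1 - concordance_index(pred, obs) == pytest.approx(
            concordance_index(-pred, obs), abs=1e-12
        )

    def test_all_tied_observations_is_missing(self):
        assert np.isnan(concordance_index(np.array([1.0, 2.0]), np.array([5.0, 5.0])))

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index as ll_concordance

        rng = np.random.default_rng(5)
        pred, obs = rng.normal(size=30), rng.normal(size=30)
        assert concordance_index(pred, obs) == pytest.approx(
            ll_concordance(obs, pred), abs=1e-12
        )


def reference_enet_runs(X: pd.DataFrame, y: pd.Series, cfg: RegressionConfig):
    """Literal loop mirroring the published procedure, kept separate as an oracle."""
    Xmat = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    out = []
    for r in range(cfg.n_repeats):
        for f, (train, test) in enumerate(kfold_split(len(yv), cfg.n_folds, cfg.seed + r)):
            X_std, means, sds, zv = standardize(Xmat[train])
            sel = cv_select_lambda(X_std, yv[train], cfg, seed=cfg.seed + 1000 * r + f)
            fit = fit_enet(X_std, yv[train], cfg.alpha, sel.lambda_)
            pred = apply_standardization(Xmat[test], means, sds, zv) @ fit.coefficients + fit.intercept
            ci = concordance_index(pred, yv[test])
            mx = np.max(np.abs(fit.coefficients))
            w = fit.coefficients / mx if mx > 0 else np.zeros_like(fit.coefficients)
            out.append((sel.lambda_, fit.coefficients, w, ci))
    return out


class TestRunEnetModels:
    def test_equals_reference_loop_on_toy(self):
        Xdf, y = make_xy_frame(20, 5, {0: 2.0}, 0.5, seed=1)
        cfg = RegressionConfig(alpha=0.5, n_repeats=2, n_folds=2, seed=9)
        runs, feats = run_enet_models(Xdf, y, cfg)
        ref = reference_enet_runs(Xdf, y, cfg)
        assert feats == list(Xdf.columns)
        assert len(runs) == len(ref) == 4
        for run, (lam, coef, w, ci) in zip(runs, ref):
            assert run.lambda_ == pytest.approx(lam, rel=1e-12)
            assert np.allclose(run.coefficients, coef, atol=1e-12)
            assert np.allclose(run.normalized_weights, w, atol=1e-12)
            assert run.test_ci == pytest.approx(ci, abs=1e-12)

    def test_normalized_weight_invariants(self):
        Xdf, y = make_xy_frame(60, 10, {0: -2.0, 1: 2.0}, 0.5, seed=2)
        runs, _ = run_enet_models(Xdf, y, RegressionConfig(alpha=0.5, n_repeats=2, n_folds=3, seed=0))
        for run in runs:
            w = run.normalized_weights
            assert (np.abs(w) <= 1 + 1e-12).all()
            if np.any(run.coefficients != 0):
                assert np.isclose(np.abs(w).max(), 1.0)
            else:
                assert (w == 0).all()

    def test_too_few_lines_rejected(self):
        Xdf, y = make_xy_frame(15, 3, {0: 1.0}, 0.5, seed=3)
        with pytest.raises(InsufficientDataError):
            run_enet_models(Xdf, y, RegressionConfig(alpha=0.5, n_repeats=1, n_folds=2, seed=0))


class TestAggregation:
    def test_always_selected_positive_feature(self):
        Xdf, y = make_xy_frame(100, 8, {2: 3.0}, 0.2, seed=4)
        runs, feats = run_enet_models(Xdf, y, RegressionConfig(alpha=0.5, n_repeats=2, n_folds=5, seed=0))
        table = aggregate_associations(runs, feats)
        row = table[table["feature"] == "g002"].iloc[0]
        assert row["frequency"] == 1.0
        assert row["mean_weight"] > 0.9
        assert row["direction"] == "resistance"
        assert row["rank"] == 1.0

    def test_never_selected_feature_has_no_rank(self):
        Xdf, y = make_xy_frame(100, 8, {2: 3.0}, 0.2, seed=4)
        runs, feats = run_enet_models(Xdf, y, RegressionConfig(alpha=0.5, n_repeats=1, n_folds=5, seed=0))
        table = aggregate_associations(runs, feats)
        never = table[table["frequency"] == 0]
        assert never["rank"].isna().all()
        assert (never["mean_weight"] == 0).all()

    def test_frequency_equals_mean_of_nonzero_indicators(self):
        Xdf, y = make_xy_frame(80, 6, {0: -2.0}, 0.5, seed=5)
        runs, feats = run_enet_models(Xdf, y, RegressionConfig(alpha=0.5, n_repeats=2, n_folds=4, seed=1))
        table = aggregate_associations(runs, feats).set_index("feature")
        indicators = np.vstack([np.abs(r.coefficients) > 1e-10 for r in runs]).mean(axis=0)
        assert np.allclose(table.loc[feats, "frequency"], indicators)


class TestSelectDrugs:
    def test_boundary_is_strict(self):
        summaries = pd.DataFrame(
            {"drug": ["a", "b"], "mean_ci": [0.650, 0.66], "median_ci": [0.650, 0.66]}
        )
        sel = select_drugs(summaries, threshold=0.65)
        assert list(sel["drug"]) == ["b"]

    def test_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        summaries = pd.DataFrame(
            {"drug": [f"d{i}" for i in range(20)], "mean_ci": rng.uniform(0.4, 0.9, 20)}
        )
        summaries["median_ci"] = summaries["mean_ci"]
        strict = set(select_drugs(summaries, 0.65)["drug"])
        loose = set(select_drugs(summaries, 0.60)["drug"])
        assert strict <= loose

    def test_median_aggregate_available(self):
        summaries = pd.DataFrame({"drug": ["a"], "mean_ci": [0.5], "median_ci": [0.9]})
        assert len(select_drugs(summaries, 0.65, stat="median")) == 1


class TestFeatureSet:
    def test_mode_column_arithmetic(self, small_bundle):
        n_genes = small_bundle.expression.shape[1]
        expr = feature_set(small_bundle, "expression")
        geno = feature_set(small_bundle, "genomics")
        both = feature_set(small_bundle, "combined")
        assert expr.shape[1] == n_genes
        assert geno.shape[1] == 3 * n_genes
        assert both.shape[1] == expr.shape[1] + geno.shape[1]

    def test_expression_mode_has_no_alteration_columns(self, small_bundle):
        expr = feature_set(small_bundle, "expression")
        assert not any(c.startswith(("amp", "del", "var")) for c in expr.columns)

    def test_all_other_genes_is_an_error(self, small_bundle):
        from dataclasses import replace

        stripped = replace(small_bundle, gene_class={})
        with pytest.raises(ValueError, match="transporter"):
            feature_set(stripped, "expression")

    def test_unknown_mode_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="mode"):
            feature_set(small_bundle, "everything")


def test_summarize_runs_drops_missing_ci():
    from transdrug.enet import ModelRun

    runs = [
        ModelRun(0, 0, 0.1, np.zeros(2), np.zeros(2), 0.8),
        ModelRun(0, 1, 0.1, np.zeros(2), np.zeros(2), float("nan")),
    ]
    s = summarize_runs("d", runs)
    assert s["mean_ci"] == pytest.approx(0.8)
    assert s["n_runs"] == 2
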