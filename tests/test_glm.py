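"""GLM engine: design coding, quasi-Poisson fitting, sandwich variance."""

import numpy as np
import pandas as pd
import pytest

from bmicost.glm import (
    DesignError,
    FitError,
    ModelSpec,
    build_design,
    cluster_robust_cov,
    fit_model,
    fit_quasipoisson,
    predict_mean,
)
from bmicost.simulate import generate_cohort, generate_panel
from test_simulate import null_effect_config


def toy_panel(y, cluster=None, **cols):
    n = len(y)
    df = pd.DataFrame({"person_id": cluster if cluster is not None else np.arange(n), "y": y})
    for k, v in cols.items():
        df[k] = v
    return df


class TestBuildDesign:
    def test_three_level_adjuster_gives_three_columns(self):
        df = toy_panel([1, 2, 3, 4, 5, 6], g=["a", "b", "c", "a", "b", "c"])
        d = build_design(df, ModelSpec(outcome="y", exposure=None, adjusters=["g"]))
        assert d.p == 3
        assert d.column_names() == ["intercept", "g[b]", "g[c]"]

    def test_subset_filter_drops_rows(self, panel_small):
        spec = ModelSpec(outcome="consult_count", exposure=None, adjusters=[], subset="bmi > 20")
        d = build_design(panel_small, spec)
        assert (panel_small.loc[d.row_index, "bmi"] > 20).all()
        assert d.n == (panel_small["bmi"] > 20).sum()

    def test_empty_subset_raises(self, panel_small):
        spec = ModelSpec(outcome="consult_count", exposure=None, adjusters=[], subset="bmi > 200")
        with pytest.raises(DesignError, match="no rows"):
            build_design(panel_small, spec)

    def test_missing_becomes_own_level_with_expected_share(self):
        cfg = null_effect_config(n_women=6000, years=1, seed=21, missing_covariate_prob=0.04)
        panel = generate_panel(generate_cohort(cfg), cfg)
        d = build_design(
            panel, ModelSpec(outcome="consult_count", exposure=None, adjusters=["education"])
        )
        j = d.column_names().index("education[missing]")
        assert d.X[:, j].mean() == pytest.approx(0.04, abs=0.01)

    def test_missing_never_reference(self):
        df = toy_panel([1, 2, 3, 4], g=["missing", "missing", "zz", "zz"])
        d = build_design(df, ModelSpec(outcome="y", exposure=None, adjusters=["g"]))
        assert d.levels["g"][0] == "zz"

    def test_rank_deficiency_names_columns(self):
        df = toy_panel([1, 2, 3, 4], g=["a", "a", "b", "b"], h=["x", "x", "z", "z"])
        with pytest.raises(DesignError, match="collinear"):
            build_design(df, ModelSpec(outcome="y", exposure=None, adjusters=["g", "h"]))

    def test_missing_columns_named(self, panel_small):
        with pytest.raises(DesignError, match="nope"):
            build_design(panel_small, ModelSpec(outcome="nope", exposure=None))


class TestFit:
    def test_intercept_only_matches_mean(self):
        d = build_design(toy_panel([2.0, 4.0]), ModelSpec(outcome="y", exposure=None))
        fit = fit_quasipoisson(d)
        assert fit.beta[0] == pytest.approx(np.log(3.0), abs=1e-9)

    def test_saturated_binary_model_is_log_group_mean_ratio(self):
        y = [2, 4, 3, 9, 11, 10]
        g = ["a", "a", "a", "b", "b", "b"]
        fit = fit_quasipoisson(
            build_design(toy_panel(y, g=g), ModelSpec(outcome="y", exposure=None, adjusters=["g"]))
        )
        assert fit.beta[0] == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.beta[1] == pytest.approx(np.log(10.0 / 3.0), abs=1e-8)

    def test_matches_independent_newton_oracle(self, poisson_oracle):
        rng = np.random.default_rng(3)
        n = 200
        X = np.column_stack(
            [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n), rng.uniform(0, 1, n)]
        )
        beta_true = np.array([1.0, 0.3, -0.2, 0.5])
        y = rng.poisson(np.exp(X @ beta_true))
        df = pd.DataFrame({"person_id": np.arange(n), "y": y, "x1": X[:, 1], "x2": X[:, 2], "x3": X[:, 3]})
        df["x2"] = df["x2"].astype(float)
        fit = fit_model(df, ModelSpec(outcome="y", exposure=None, adjusters=["x1", "x2", "x3"]))
        oracle = poisson_oracle(y, fit.design.X)
        assert np.max(np.abs(fit.beta - oracle)) < 1e-6

    def test_mean_preservation(self, panel_small):
        fit = fit_model(
            panel_small,
            ModelSpec(outcome="consult_count", adjusters=["age_band", "fraction_observed"]),
        )
        assert fit.mu.sum() == pytest.approx(fit.design.y.sum(), rel=1e-6)

    def test_continuous_cost_outcome_accepted(self, panel_small):
        fit = fit_model(panel_small, ModelSpec(outcome="consult_cost", adjusters=[]))
        assert fit.dispersion > 1.0  # currency scale inflates Poisson-relative variance

    def test_all_zero_response_raises(self):
        df = toy_panel([0.0, 0.0, 0.0])
        with pytest.raises(FitError, match="zero"):
            fit_quasipoisson(build_design(df, ModelSpec(outcome="y", exposure=None)))


class TestSandwich:
    def test_two_cluster_hand_oracle(self):
        """V = B^-1 (s1 s1' + s2 s2') B^-1 * G/(G-1) computed by hand."""
        y = np.array([1.0, 3.0, 2.0, 6.0])
        x = np.array([0.0, 1.0, 0.0, 1.0])
        df = toy_panel(y, cluster=[1, 1, 2, 2], x=x)
        fit = fit_model(df, ModelSpec(outcome="y", exposure=None, adjusters=["x"]))
        X, mu = fit.design.X, fit.mu
        B = X.T @ (X * mu[:, None])
        s1 = X[:2].T @ (y[:2] - mu[:2])
        s2 = X[2:].T @ (y[2:] - mu[2:])
        Binv = np.linalg.inv(B)
        expected = Binv @ (np.outer(s1, s1) + np.outer(s2, s2)) @ Binv * 2.0
        assert np.allclose(fit.cov_cluster, expected, atol=1e-12)

    def test_cluster_replication_invariance(self):
        """Replicating every cluster k times leaves beta and cluster-robust
        SEs unchanged while model-based SEs shrink by sqrt(k)."""
        rng = np.random.default_rng(9)
        n, k = 60, 3
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.5 + 0.3 * x))
        base = toy_panel(y, cluster=np.arange(n), x=x)
        rep = pd.concat([base] * k, ignore_index=True)
        f1 = fit_model(base, ModelSpec(outcome="y", exposure=None, adjusters=["x"]))
        f2 = fit_model(rep, ModelSpec(outcome="y", exposure=None, adjusters=["x"]))
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        assert np.allclose(
            np.sqrt(np.diag(f1.cov_cluster)), np.sqrt(np.diag(f2.cov_cluster)), rtol=1e-6
        )
        assert np.allclose(
            np.sqrt(np.diag(f2.cov_model)) * np.sqrt(k),
            np.sqrt(np.diag(f1.cov_model)),
            rtol=0.05,
        )

    def test_single_row_clusters_agree_with_model_cov(self):
        """Independent Poisson rows: sandwich and model-based SEs agree
        asymptotically (within 10%)."""
        rng = np.random.default_rng(10)
        n = 20_000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.2 * x)).astype(float)
        df = toy_panel(y, cluster=np.arange(n), x=x)
        fit = fit_model(df, ModelSpec(outcome="y", exposure=None, adjusters=["x"]))
        assert np.allclose(
            np.sqrt(np.diag(fit.cov_cluster)), np.sqrt(np.diag(fit.cov_model)), rtol=0.1
        )

    def test_requires_two_clusters(self):
        df = toy_panel([1.0, 2.0], cluster=[1, 1])
        d = build_design(df, ModelSpec(outcome="y", exposure=None))
        fit = fit_quasipoisson(d)
        with pytest.raises(FitError, match="2 clusters"):
            cluster_robust_cov(fit.beta, d, fit.mu)

    def test_cluster_robust_coverage_beats_model_based(self):
        """With person frailty, 99% cluster-robust Wald intervals for the
        BMI slope reach near-nominal coverage; model-based intervals
        under-cover.  Scaled-down replicate study."""
        from bmicost.config import SimulationConfig

        z = 2.5758
        reps = 120
        cover_cl = cover_mod = 0
        for r in range(reps):
            cfg = null_effect_config(n_women=150, years=4, seed=5000 + r, dropout_rate=0.0)
            cfg.frailty_sd = 0.5
            cfg.slope_per_unit_bmi = {**cfg.slope_per_unit_bmi, "consult": 0.03}
            panel = generate_panel(generate_cohort(cfg), cfg)
            fit = fit_model(
                panel, ModelSpec(outcome="consult_count", exposure="bmi_linear_above20", adjusters=[])
            )
            (j,) = [i for i, t in enumerate(fit.design.columns) if t == ("num", "bmi")]
            true_slope = _implied_linear_slope(cfg)
            for cov, counter in ((fit.cov_cluster, "cl"), (fit.cov_model, "mod")):
                se = np.sqrt(cov[j, j])
                hit = abs(fit.beta[j] - true_slope) <= z * se
                if counter == "cl":
                    cover_cl += hit
                else:
                    cover_mod += hit
        assert cover_cl / reps >= 0.95
        assert cover_mod / reps < cover_cl / reps

    def test_dispersion_scales_model_cov_only(self):
        rng = np.random.default_rng(11)
        y = rng.poisson(5.0, 50).astype(float)
        df = toy_panel(y, cluster=np.arange(50))
        fit = fit_model(df, ModelSpec(outcome="y", exposure=None))
        assert fit.cov_model[0, 0] == pytest.approx(fit.dispersion / fit.mu.sum(), rel=1e-6)


def _implied_linear_slope(cfg):
    """Population slope of the linear-above-20 fit under the generative model."""
    from bmicost import truth

    pct = truth.implied_trend_pct(cfg, "consult", "count")
    return np.log(1 + pct / 100.0) / 2.0


@pytest.fixture(scope="module")
def cat_fit(panel_small):
    return fit_model(
        panel_small,
        ModelSpec(
            outcome="consult_count",
            adjusters=["age_band", "fraction_observed"],
        ),
    )


class TestPredict:
    def test_reference_profile_is_exp_intercept(self, panel_small):
        # model without continuous terms: the all-reference profile is exp(beta0)
        fit = fit_model(
            panel_small, ModelSpec(outcome="consult_count", adjusters=["age_band"])
        )
        row = panel_small.iloc[[0]].copy()
        row["bmi_category_fine"] = "20-22.5"
        row["age_band"] = fit.design.levels["age_band"][0]
        assert predict_mean(fit, row)[0] == pytest.approx(np.exp(fit.beta[0]), rel=1e-12)

    def test_training_rows_reproduce_fitted_means(self, cat_fit, panel_small):
        rows = panel_small.loc[cat_fit.design.row_index]
        pred = predict_mean(cat_fit, rows, fraction_observed=None)
        assert np.allclose(pred, cat_fit.mu, rtol=1e-10)

    def test_category_ratio_is_exp_coefficient(self, cat_fit, panel_small):
        row = panel_small.iloc[[0]].copy()
        row["bmi_category_fine"] = "20-22.5"
        base = predict_mean(cat_fit, row)[0]
        row2 = row.copy()
        row2["bmi_category_fine"] = "30-35"
        j = cat_fit.design.column_names().index("bmi_category_fine[30-35]")
        assert predict_mean(cat_fit, row2)[0] / base == pytest.approx(
            np.exp(cat_fit.beta[j]), rel=1e-12
        )

    def test_unseen_level_raises_with_name(self, cat_fit, panel_small):
        row = panel_small.iloc[[0]].copy()
        row["age_band"] = "80-84"
        with pytest.raises(DesignError, match="80-84"):
            predict_mean(cat_fit, row)
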