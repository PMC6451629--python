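"""Generator behaviour: determinism, distributions, cost/count identities."""

import numpy as np
import pandas as pd
import pytest

from bmicost import truth
from bmicost.categories import FINE_CATEGORIES, assign_fine_category
from bmicost.config import (
    COVARIATES,
    RX_USE_CATEGORIES,
    BMIMixture,
    ConfigError,
    SimulationConfig,
)
from bmicost.glm import ModelSpec, fit_model
from bmicost.simulate import (
    IntegrityError,
    generate_cohort,
    generate_panel,
    generate_population_table,
    unit_cost_table,
)


def null_effect_config(**kw):
    """All BMI/covariate/diabetes/frailty effects switched off."""
    cfg = SimulationConfig(**kw)
    cfg.slope_per_unit_bmi = {o: 0.0 for o in cfg.slope_per_unit_bmi}
    cfg.covariate_effects = {k: [0.0] * len(v) for k, v in cfg.covariate_effects.items()}
    cfg.frailty_sd = 0.0
    cfg.diabetes_model.count_effect = {o: 1.0 for o in cfg.diabetes_model.count_effect}
    return cfg


class TestCohort:
    def test_seeded_determinism(self, base_config, cohort_small, panel_small):
        cohort2 = generate_cohort(base_config)
        panel2 = generate_panel(cohort2, base_config)
        assert cohort2.to_csv() == cohort_small.to_csv()
        assert panel2.to_csv() == panel_small.to_csv()

    def test_different_seeds_differ(self, base_config, cohort_small):
        other = generate_cohort(base_config.with_updates(seed=124))
        assert not other["bmi"].equals(cohort_small["bmi"])

    def test_no_missing_when_probability_zero(self):
        cfg = SimulationConfig(n_women=1000, seed=5, missing_covariate_prob=0.0)
        cohort = generate_cohort(cfg)
        for cov in COVARIATES:
            assert not (cohort[cov] == "missing").any()

    def test_missing_rate_close_to_configured(self):
        cfg = SimulationConfig(n_women=20_000, seed=6, missing_covariate_prob=0.04)
        cohort = generate_cohort(cfg)
        rate = np.mean([(cohort[c] == "missing").mean() for c in COVARIATES])
        assert rate == pytest.approx(0.04, abs=0.005)

    def test_bmi_share_below_25_matches_binomial_oracle(self):
        """The configured mixture puts 47% of mass below 25 kg/m^2; the
        empirical share must fall within 3 binomial standard errors."""
        n = 50_000
        cfg = SimulationConfig(n_women=n, seed=42)
        shares = truth.category_shares(cfg)
        p = sum(shares[c] for c in ("18.5-20", "20-22.5", "22.5-25"))
        assert p == pytest.approx(0.47, abs=1e-6)
        cohort = generate_cohort(cfg)
        observed = (cohort["bmi"] < 25.0).mean()
        assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_bmi_truncation_and_category_consistency(self, cohort_small):
        assert (cohort_small["bmi"] >= 18.5).all()
        expected = assign_fine_category(cohort_small["bmi"].to_numpy())
        assert (cohort_small["bmi_category_fine"] == expected).all()

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="dispersion"):
            SimulationConfig(dispersion={"consult": 0.5, "rx": 1.5, "test": 1.5}).validate()
        with pytest.raises(ConfigError, match="weight2"):
            SimulationConfig(bmi_mix=BMIMixture(weight2=1.5)).validate()
        with pytest.raises(ConfigError, match="dropout_rate"):
            SimulationConfig(dropout_rate=-0.1).validate()


class TestPanel:
    def test_cohort_config_mismatch_raises(self, cohort_small, base_config):
        other = base_config.with_updates(seed=999)
        with pytest.raises(IntegrityError):
            generate_panel(cohort_small, other)

    def test_costs_are_exact_products_of_counts(self, panel_small, base_config):
        cfg = base_config
        assert np.array_equal(
            panel_small["consult_cost"], panel_small["consult_count"] * cfg.unit_cost_consult
        )
        assert np.array_equal(
            panel_small["test_cost"], panel_small["test_count"] * cfg.unit_cost_test
        )
        total = np.zeros(len(panel_small))
        for u in RX_USE_CATEGORIES:
            assert np.array_equal(
                panel_small[f"rx_cost_{u}"],
                panel_small[f"rx_count_{u}"] * cfg.rx_unit_costs[u],
            )
            total += panel_small[f"rx_cost_{u}"]
        assert np.allclose(panel_small["rx_cost"], total)
        counts = sum(panel_small[f"rx_count_{u}"] for u in RX_USE_CATEGORIES)
        assert np.array_equal(counts, panel_small["rx_count"])

    def test_diabetes_flag_monotone_within_person(self, panel_small):
        for _, grp in panel_small.sort_values("year_index").groupby("person_id"):
            assert grp["diabetes_flag"].astype(int).diff().fillna(0).min() >= 0

    def test_fraction_observed_in_unit_interval(self, panel_small):
        f = panel_small["fraction_observed"]
        assert ((f > 0) & (f <= 1)).all()
        # all years before a person's last are complete
        last = panel_small.groupby("person_id")["year_index"].transform("max")
        assert (panel_small.loc[panel_small["year_index"] < last, "fraction_observed"] == 1).all()

    def test_null_effect_config_means_uniform_across_categories(self):
        """With every effect off, category means all equal the baseline."""
        cfg = null_effect_config(n_women=4000, years=5, seed=77, dropout_rate=0.0)
        panel = generate_panel(generate_cohort(cfg), cfg)
        assert len(panel) >= 20_000
        base = cfg.baseline_rate["consult"]
        for cat, grp in panel.groupby("bmi_category_fine"):
            se = np.sqrt(cfg.dispersion["consult"] * base / len(grp))
            assert abs(grp["consult_count"].mean() - base) < 4 * se

    def test_poisson_case_dispersion_near_one(self):
        """dispersion=1 with no frailty is plain Poisson: fitted Pearson
        dispersion of a quasi-Poisson model is ~1."""
        cfg = null_effect_config(n_women=10_000, years=5, seed=88, dropout_rate=0.0)
        cfg.dispersion = {o: 1.0 for o in cfg.dispersion}
        panel = generate_panel(generate_cohort(cfg), cfg)
        assert len(panel) >= 50_000
        fit = fit_model(panel, ModelSpec(outcome="consult_count", exposure=None, adjusters=[]))
        assert fit.dispersion == pytest.approx(1.0, abs=0.1)

    def test_configured_dispersion_recovered(self):
        """Generated dispersion 1.5 (no frailty) shows up as Pearson phi."""
        cfg = null_effect_config(n_women=10_000, years=5, seed=89, dropout_rate=0.0)
        panel = generate_panel(generate_cohort(cfg), cfg)
        fit = fit_model(panel, ModelSpec(outcome="consult_count", exposure=None, adjusters=[]))
        assert 1.35 <= fit.dispersion <= 1.65

    def test_category_mean_ratio_matches_configured_slope(self):
        """Slope chosen so the top-category consultation mean is 11.1/7.0
        times the reference; generated category means reproduce it within 5%."""
        target_ratio = 11.1 / 7.0
        cfg = null_effect_config(n_women=40_000, years=3, seed=90, dropout_rate=0.0)
        # solve the slope from the truth module's category means
        cfg.slope_per_unit_bmi = dict(cfg.slope_per_unit_bmi)
        from scipy import optimize

        def f(s):
            c = cfg.with_updates(
                slope_per_unit_bmi={**cfg.slope_per_unit_bmi, "consult": s}
            )
            m = truth.category_means(c, "consult", "count")
            return m["40+"] / m["20-22.5"] - target_ratio

        cfg.slope_per_unit_bmi["consult"] = optimize.brentq(f, 0.005, 0.08)
        panel = generate_panel(generate_cohort(cfg), cfg)
        means = panel.groupby("bmi_category_fine")["consult_count"].mean()
        ratio = means["40+"] / means["20-22.5"]
        assert ratio == pytest.approx(target_ratio, rel=0.05)


class TestPopulationAndCosts:
    def test_default_population_totals(self, population):
        assert population.total_million == pytest.approx(6.63, abs=1e-9)
        assert population.coarse_counts["<25"] == 2.83

    def test_fine_weights_sum_to_one_per_coarse(self, population):
        df = population.to_frame()
        sums = df.groupby("coarse_category")["fine_weight"].sum()
        assert np.allclose(sums, 1.0)

    def test_invalid_weights_rejected(self, population):
        bad = dict(population.fine_weights)
        bad["20-22.5"] = 0.2  # <25 group no longer sums to 1
        with pytest.raises(ConfigError, match="sum to 1"):
            generate_population_table(fine_weights=bad)

    def test_config_implied_weights_match_mixture(self):
        cfg = SimulationConfig()
        pop = generate_population_table(cfg)
        shares = truth.category_shares(cfg)
        expect = shares["20-22.5"] / (shares["18.5-20"] + shares["20-22.5"] + shares["22.5-25"])
        assert pop.fine_weights["20-22.5"] == pytest.approx(expect)

    def test_unit_cost_table_covers_all_categories(self, base_config):
        tab = unit_cost_table(base_config)
        assert len(tab) == 2 + len(RX_USE_CATEGORIES)
        assert tab["category"].is_unique
        assert (tab["unit_cost"] >= 0).all()


class TestTruthRecord:
    def test_truth_recomputable_and_consistent(self, population):
        cfg = SimulationConfig()
        rec = truth.truth_record(cfg, population)
        # direct percentage differences are a closed form of the slope
        for out, s in cfg.slope_per_unit_bmi.items():
            assert rec["direct_pct_per_2kgm2"][out] == pytest.approx(
                100 * (np.exp(2 * s) - 1)
            )
        # category shares sum to one; category means increase for positive slope
        assert sum(rec["category_shares"].values()) == pytest.approx(1.0, abs=1e-6)
        cons = rec["category_means"]["consult_cost"]
        vals = [cons[c] for c in FINE_CATEGORIES[1:]]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_null_config_trend_is_zero(self):
        cfg = null_effect_config()
        assert truth.implied_trend_pct(cfg, "consult", "cost") == pytest.approx(0.0, abs=1e-8)
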