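"""Synthetic cohort, person-year panel, unit-cost and population tables.

The generator produces, with known ground truth, the data structures the
analysis pipeline consumes: a baseline cohort of women with self-reported
BMI and categorical covariates, a person-year panel of overdispersed
consultation / prescription / test counts and exactly-derived costs, a
unit-cost lookup, and a population BMI-distribution table for projection.

Counts are negative-binomial with variance ``dispersion * mean``
conditional on a person-level log-normal frailty; the frailty induces the
within-person correlation across years that cluster-robust variance must
absorb.  Partial years scale the count mean multiplicatively, while the
analysis model enters the observed fraction as a covariate — a deliberate,
documented mismatch that keeps standardization at fraction 1 testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .categories import (
    COARSE_CATEGORIES,
    FINE_CATEGORIES,
    FINE_TO_COARSE,
    REFERENCE_KNOT,
    assign_fine_category,
)
from .config import (
    COVARIATES,
    DEFAULT_COVARIATE_LEVELS,
    OUTCOMES,
    RX_USE_CATEGORIES,
    ConfigError,
    SimulationConfig,
)


class IntegrityError(RuntimeError):
    """Cohort and configuration do not belong together."""


_FINGERPRINT_KEY = "bmicost_config_fingerprint"

#: Default population of women aged 55-79 in England (millions) by coarse
#: self-reported BMI category, mid-2013.
DEFAULT_COARSE_COUNTS = {
    "<25": 2.83,
    "25-29.9": 2.28,
    "30-34.9": 1.06,
    "35-39.9": 0.30,
    "40+": 0.16,
}


@dataclass
class PopulationTable:
    """Counts of women (millions) by coarse BMI category with fine weights.

    ``fine_weights[c]`` is the share of the enclosing coarse category's
    population in fine band ``c``; shares sum to one within each coarse
    category.
    """

    coarse_counts: dict
    fine_weights: dict
    fine_to_coarse: dict = field(default_factory=lambda: dict(FINE_TO_COARSE))

    def validate(self) -> None:
        if set(self.coarse_counts) != set(COARSE_CATEGORIES):
            raise ConfigError("population table must cover exactly the 5 coarse categories")
        if any(v <= 0 for v in self.coarse_counts.values()):
            raise ConfigError("population counts must be positive")
        if set(self.fine_weights) != set(FINE_CATEGORIES):
            raise ConfigError("fine_weights must cover exactly the 8 fine categories")
        for coarse in COARSE_CATEGORIES:
            members = [c for c in FINE_CATEGORIES if self.fine_to_coarse[c] == coarse]
            tot = sum(self.fine_weights[c] for c in members)
            if any(self.fine_weights[c] < 0 for c in members) or abs(tot - 1.0) > 1e-6:
                raise ConfigError(
                    f"fine_weights within coarse category {coarse!r} must sum to 1 (got {tot:.6f})"
                )

    @property
    def total_million(self) -> float:
        return float(sum(self.coarse_counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fine in FINE_CATEGORIES:
            coarse = self.fine_to_coarse[fine]
            rows.append(
                {
                    "coarse_category": coarse,
                    "fine_category": fine,
                    "n_women_million": self.coarse_counts[coarse],
                    "fine_weight": self.fine_weights[fine],
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationTable":
        required = {"coarse_category", "fine_category", "n_women_million", "fine_weight"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"population table missing columns: {sorted(missing)}")
        coarse_counts = {}
        fine_weights = {}
        for _, row in df.iterrows():
            coarse_counts[row["coarse_category"]] = float(row["n_women_million"])
            fine_weights[row["fine_category"]] = float(row["fine_weight"])
        tab = cls(coarse_counts=coarse_counts, fine_weights=fine_weights)
        tab.validate()
        return tab


def generate_population_table(
    config: SimulationConfig | None = None, coarse_counts=None, fine_weights=None
) -> PopulationTable:
    """Population BMI-distribution table; defaults to the mid-2013 counts.

    When a :class:`SimulationConfig` is given, fine weights within each
    coarse category default to the shares implied by its BMI mixture, so
    the projection population is self-consistent with the synthetic
    cohort's BMI distribution.  Without a config they default to equal
    shares within each coarse category.
    """
    counts = dict(DEFAULT_COARSE_COUNTS if coarse_counts is None else coarse_counts)
    if fine_weights is None:
        if config is not None:
            from .truth import category_shares

            shares = category_shares(config)
            fine_weights = {}
            for coarse in COARSE_CATEGORIES:
                members = [c for c in FINE_CATEGORIES if FINE_TO_COARSE[c] == coarse]
                tot = sum(shares[c] for c in members)
                for c in members:
                    fine_weights[c] = shares[c] / tot
        else:
            fine_weights = {}
            for coarse in COARSE_CATEGORIES:
                members = [c for c in FINE_CATEGORIES if FINE_TO_COARSE[c] == coarse]
                for c in members:
                    fine_weights[c] = 1.0 / len(members)
    tab = PopulationTable(coarse_counts=counts, fine_weights=dict(fine_weights))
    tab.validate()
    return tab


def unit_cost_table(config: SimulationConfig) -> pd.DataFrame:
    """Unit-cost lookup: one row per service / therapeutic-use category."""
    rows = [
        {"category": "consult", "unit_cost": config.unit_cost_consult},
        {"category": "test", "unit_cost": config.unit_cost_test},
    ]
    rows += [
        {"category": f"rx_{u}", "unit_cost": config.rx_unit_costs[u]}
        for u in RX_USE_CATEGORIES
    ]
    return pd.DataFrame(rows)


def _rng_streams(config: SimulationConfig):
    """Named child streams so panel draws never perturb cohort draws."""
    ss = np.random.SeedSequence(config.seed)
    cohort_ss, panel_ss = ss.spawn(2)
    return np.random.default_rng(cohort_ss), np.random.default_rng(panel_ss)


def _sample_bmi(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mix = config.bmi_mix
    n = config.n_women
    comp2 = rng.random(n) < mix.weight2
    bmi = np.empty(n)
    for is2, (mu, sd) in ((False, (mix.mean1, mix.sd1)), (True, (mix.mean2, mix.sd2))):
        m = comp2 == is2
        if m.any():
            a = (mix.truncate_at - mu) / sd
            bmi[m] = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=m.sum(), random_state=rng)
    return bmi


def _sample_covariates(config: SimulationConfig, bmi: np.ndarray, rng: np.random.Generator):
    """True covariate levels and their summed log-scale effect.

    With ``confounding_strength`` > 0, deprivation becomes BMI-dependent
    (higher BMI shifts mass towards the most deprived third), creating
    genuine confounding for standardization tests.
    """
    n = len(bmi)
    true_levels: dict[str, np.ndarray] = {}
    lp = np.zeros(n)
    for cov in COVARIATES:
        levels = DEFAULT_COVARIATE_LEVELS[cov]
        probs = np.asarray(config.covariate_probs[cov], dtype=float)
        effects = np.asarray(config.covariate_effects[cov], dtype=float)
        if cov == "deprivation_third" and config.confounding_strength != 0.0:
            grad = np.array([-1.0, 0.0, 1.0])
            logits = np.log(probs)[None, :] + config.confounding_strength * (
                bmi[:, None] - 25.0
            ) * grad[None, :]
            p = np.exp(logits - logits.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n)
            idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        else:
            idx = rng.choice(len(levels), size=n, p=probs)
        true_levels[cov] = np.asarray(levels, dtype=object)[idx]
        lp += effects[idx]
    return true_levels, lp


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate the baseline cohort table.

    Returns one row per woman: BMI (truncated mixture), fine BMI category,
    observed covariates (with injected ``"missing"`` labels), simulated
    diabetes onset year (NaN if never during follow-up), and the hidden
    ground-truth columns ``_covariate_lp`` (summed log-scale effect of the
    *true* covariate values) and ``_frailty_log`` used by the panel
    generator.
    """
    config.validate()
    rng, _ = _rng_streams(config)
    n = config.n_women
    bmi = _sample_bmi(config, rng)
    true_levels, lp = _sample_covariates(config, bmi, rng)

    observed = {}
    for cov in COVARIATES:
        vals = true_levels[cov].copy()
        if config.missing_covariate_prob > 0:
            mask = rng.random(n) < config.missing_covariate_prob
            vals[mask] = "missing"
        observed[cov] = vals

    diabetes_p = expit(
        config.diabetes_model.log_odds_intercept
        + config.diabetes_model.log_odds_per_unit_bmi * bmi
    )
    u = rng.random(n)
    with np.errstate(divide="ignore"):
        onset = np.floor(np.log(u) / np.log1p(-diabetes_p))
    onset[onset >= config.years] = np.nan

    frailty_log = (
        rng.normal(0.0, config.frailty_sd, n) if config.frailty_sd > 0 else np.zeros(n)
    )

    cohort = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "bmi": bmi,
            "bmi_category_fine": assign_fine_category(bmi),
            **observed,
            "diabetes_onset_year": onset,
            "_covariate_lp": lp,
            "_frailty_log": frailty_log,
        }
    )
    cohort.attrs[_FINGERPRINT_KEY] = config.fingerprint()
    return cohort


def _negbin_counts(mu: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Counts with variance phi * mu (Poisson when phi == 1)."""
    if phi <= 1.0 + 1e-12:
        return rng.poisson(mu)
    theta = mu / (phi - 1.0)
    return rng.negative_binomial(theta, theta / (theta + mu))


def generate_panel(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Generate the person-year panel for a cohort.

    One row per person per observed year, counting from financial year 0.
    Follow-up ends mid-year with annual probability ``dropout_rate``; the
    exit year has a partial observed fraction.  Costs equal counts times
    unit costs exactly.
    """
    if cohort.attrs.get(_FINGERPRINT_KEY) != config.fingerprint():
        raise IntegrityError(
            "cohort was not generated by this configuration; regenerate the cohort "
            "with generate_cohort(config)"
        )
    _, rng = _rng_streams(config)
    n = len(cohort)
    years = config.years

    if config.dropout_rate > 0:
        u = rng.random(n)
        exit_year = np.floor(np.log(u) / np.log1p(-config.dropout_rate))
    else:
        exit_year = np.full(n, np.inf)
    last_year = np.minimum(exit_year, years - 1).astype(int)
    n_years = last_year + 1

    idx = np.repeat(np.arange(n), n_years)
    year = np.concatenate([np.arange(k) for k in n_years])
    is_exit_year = (year == exit_year[idx]) & (exit_year[idx] <= years - 1)
    fraction = np.ones(len(idx))
    fraction[is_exit_year] = rng.uniform(1.0 / 12.0, 11.0 / 12.0, is_exit_year.sum())

    bmi = cohort["bmi"].to_numpy()[idx]
    lp = cohort["_covariate_lp"].to_numpy()[idx]
    frailty = cohort["_frailty_log"].to_numpy()[idx]
    onset = cohort["diabetes_onset_year"].to_numpy()[idx]
    flag = ~np.isnan(onset) & (year >= onset)

    panel = pd.DataFrame(
        {
            "person_id": cohort["person_id"].to_numpy()[idx],
            "year_index": year,
            "financial_year": np.char.add("fy", (2006 + year).astype(str)),
            "fraction_observed": fraction,
            "bmi": bmi,
            "bmi_category_fine": cohort["bmi_category_fine"].to_numpy()[idx],
            "diabetes_flag": flag,
        }
    )
    for cov in COVARIATES:
        panel[cov] = cohort[cov].to_numpy()[idx]

    base_lp = lp + frailty + np.log(fraction)
    shape = {
        out: np.exp(
            np.log(config.baseline_rate[out])
            + config.slope_per_unit_bmi[out] * np.maximum(bmi - REFERENCE_KNOT, 0.0)
            + base_lp
        )
        for out in OUTCOMES
    }
    if config.underweight_rx_excess:
        shape["rx"] = shape["rx"] * np.exp(config.underweight_rx_excess * (bmi < 20.0))
    for out in OUTCOMES:
        me = config.diabetes_model.count_effect[out]
        if me != 1.0:
            shape[out] = shape[out] * np.where(flag, me, 1.0)

    panel["consult_count"] = _negbin_counts(shape["consult"], config.dispersion["consult"], rng)
    panel["test_count"] = _negbin_counts(shape["test"], config.dispersion["test"], rng)
    rx_total = _negbin_counts(shape["rx"], config.dispersion["rx"], rng)
    panel["rx_count"] = rx_total

    shares_nd = np.array([config.rx_shares[u] for u in RX_USE_CATEGORIES])
    shares_d = np.array([config.rx_shares_diabetic[u] for u in RX_USE_CATEGORIES])
    by_use = np.zeros((len(panel), len(RX_USE_CATEGORIES)), dtype=np.int64)
    for mask, pvals in ((~flag, shares_nd), (flag, shares_d)):
        if mask.any():
            by_use[mask] = rng.multinomial(rx_total[mask], pvals)

    unit = np.array([config.rx_unit_costs[u] for u in RX_USE_CATEGORIES])
    panel["consult_cost"] = panel["consult_count"] * config.unit_cost_consult
    panel["test_cost"] = panel["test_count"] * config.unit_cost_test
    panel["rx_cost"] = by_use @ unit
    for j, use in enumerate(RX_USE_CATEGORIES):
        panel[f"rx_count_{use}"] = by_use[:, j]
        panel[f"rx_cost_{use}"] = by_use[:, j] * unit[j]

    panel.attrs[_FINGERPRINT_KEY] = config.fingerprint()
    return panel
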