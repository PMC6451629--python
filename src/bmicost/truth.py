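"""Closed-form implied quantities of the generative model.

Everything here is recomputable exactly from a :class:`SimulationConfig`
(plus a population table for attributable quantities) by deterministic
numerical integration over the BMI distribution — no simulation.  These
truths are what parameter-recovery tests target and what
``truth_vs_estimate`` reports compare against.

Implied quantities:

* per-category true standardized annual counts and costs (the large-sample
  limit of the g-computation estimates),
* the true percentage difference per 2 kg/m^2 above 20 (the probability
  limit of the quasi-Poisson linear fit on the BMI > 20 subset, solved
  from its estimating equations),
* the true excess-weight attributable cost proportions under a given
  population table.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .categories import (
    COARSE_CATEGORIES,
    EXCESS_COARSE,
    FINE_CATEGORIES,
    FINE_EDGES,
    REFERENCE_BANDS,
    REFERENCE_KNOT,
)
from .config import RX_USE_CATEGORIES, SimulationConfig, covariate_mean_multiplier

_GRID_N = 4001
_GRID_MAX = 75.0


def bmi_grid(config: SimulationConfig, n: int = _GRID_N) -> np.ndarray:
    return np.linspace(config.bmi_mix.truncate_at, _GRID_MAX, n)


def bmi_pdf(config: SimulationConfig, b: np.ndarray) -> np.ndarray:
    """Density of the truncated two-component normal mixture."""
    mix = config.bmi_mix
    w2 = mix.weight2
    pdf = (1 - w2) * stats.norm.pdf(b, mix.mean1, mix.sd1) + w2 * stats.norm.pdf(
        b, mix.mean2, mix.sd2
    )
    mass = (1 - w2) * stats.norm.sf(mix.truncate_at, mix.mean1, mix.sd1) + w2 * stats.norm.sf(
        mix.truncate_at, mix.mean2, mix.sd2
    )
    out = pdf / mass
    out[np.asarray(b) < mix.truncate_at] = 0.0
    return out


def diabetes_annual_prob(config: SimulationConfig, b: np.ndarray) -> np.ndarray:
    dm = config.diabetes_model
    return expit(dm.log_odds_intercept + dm.log_odds_per_unit_bmi * np.asarray(b))


def diabetes_personyear_prevalence(config: SimulationConfig, b: np.ndarray) -> np.ndarray:
    """Expected share of observed person-years with the diabetes flag set.

    A person-year at index t (0-based) is observed with probability
    (1-dropout)^t and carries the flag with probability 1-(1-p)^(t+1),
    where p is the person's annual incident hazard.  The tiny dependence
    of the flag on partial-year exposure is ignored.
    """
    p = diabetes_annual_prob(config, b)[..., None]
    t = np.arange(config.years)
    w = (1.0 - config.dropout_rate) ** t
    prev = 1.0 - (1.0 - p) ** (t + 1)
    return (prev * w).sum(axis=-1) / w.sum()


def rx_mean_item_cost(config: SimulationConfig, diabetic: bool) -> float:
    shares = config.rx_shares_diabetic if diabetic else config.rx_shares
    return float(sum(shares[u] * config.rx_unit_costs[u] for u in RX_USE_CATEGORIES))


def _base_shape(config: SimulationConfig, outcome: str, b: np.ndarray) -> np.ndarray:
    """BMI-dependent count multiplier before diabetes, relative to baseline."""
    s = config.slope_per_unit_bmi[outcome]
    shape = np.exp(s * np.maximum(np.asarray(b, float) - REFERENCE_KNOT, 0.0))
    if outcome == "rx" and config.underweight_rx_excess:
        shape = shape * np.exp(config.underweight_rx_excess * (np.asarray(b) < 20.0))
    return shape


def mean_annual_count(config: SimulationConfig, outcome: str, b: np.ndarray) -> np.ndarray:
    """True annual count mean at BMI b, marginal over diabetes, covariates and frailty."""
    d = diabetes_personyear_prevalence(config, b)
    me = config.diabetes_model.count_effect[outcome]
    common = covariate_mean_multiplier(config) * np.exp(config.frailty_sd**2 / 2.0)
    return config.baseline_rate[outcome] * _base_shape(config, outcome, b) * (
        1.0 + d * (me - 1.0)
    ) * common


def mean_annual_cost(config: SimulationConfig, outcome: str, b: np.ndarray) -> np.ndarray:
    """True annual cost mean at BMI b (2016 GBP)."""
    d = diabetes_personyear_prevalence(config, b)
    me = config.diabetes_model.count_effect[outcome]
    common = covariate_mean_multiplier(config) * np.exp(config.frailty_sd**2 / 2.0)
    base = config.baseline_rate[outcome] * _base_shape(config, outcome, b) * common
    if outcome == "consult":
        return base * (1.0 + d * (me - 1.0)) * config.unit_cost_consult
    if outcome == "test":
        return base * (1.0 + d * (me - 1.0)) * config.unit_cost_test
    if outcome == "rx":
        c_nd = rx_mean_item_cost(config, diabetic=False)
        c_d = rx_mean_item_cost(config, diabetic=True)
        return base * ((1.0 - d) * c_nd + d * me * c_d)
    raise ValueError(f"unknown outcome {outcome!r}")


def _category_masks(b: np.ndarray) -> dict[str, np.ndarray]:
    edges = np.append(FINE_EDGES, np.inf)
    return {
        cat: (b >= edges[i]) & (b < edges[i + 1]) for i, cat in enumerate(FINE_CATEGORIES)
    }


def category_means(config: SimulationConfig, outcome: str, kind: str = "cost") -> dict[str, float]:
    """True standardized annual mean per fine BMI category.

    These are the large-sample targets of g-computation under a model
    saturated in the fine category: the within-category average of the
    generative annual mean.
    """
    b = bmi_grid(config)
    f = bmi_pdf(config, b)
    vals = mean_annual_cost(config, outcome, b) if kind == "cost" else mean_annual_count(
        config, outcome, b
    )
    out = {}
    for cat, mask in _category_masks(b).items():
        w = f * mask
        out[cat] = float(np.trapezoid(w * vals, b) / np.trapezoid(w, b))
    return out


def category_shares(config: SimulationConfig) -> dict[str, float]:
    """Population share of each fine BMI category under the mixture."""
    b = bmi_grid(config)
    f = bmi_pdf(config, b)
    total = np.trapezoid(f, b)
    return {
        cat: float(np.trapezoid(f * mask, b) / total)
        for cat, mask in _category_masks(b).items()
    }


def implied_trend_pct(config: SimulationConfig, outcome: str, kind: str = "cost") -> float:
    """Probability limit of the per-2 kg/m^2 percentage difference above 20.

    The analysis fits a log-linear quasi-Poisson model in BMI on the
    BMI > 20 subset.  Its slope converges to the root of the population
    estimating equations  E[(1, b)' (M(b) - exp(a + s b))] = 0  over the
    BMI distribution restricted to b > 20, where M is the true annual
    mean.  Solved by Newton iteration on the two-parameter system.
    """
    b = bmi_grid(config)
    keep = b > 20.0
    b = b[keep]
    f = bmi_pdf(config, b)
    m = (
        mean_annual_cost(config, outcome, b)
        if kind == "cost"
        else mean_annual_count(config, outcome, b)
    )

    def eqs(theta):
        a, s = theta
        mu = np.exp(a + s * b)
        r = m - mu
        return [np.trapezoid(f * r, b), np.trapezoid(f * b * r, b)]

    s0 = config.slope_per_unit_bmi[outcome]
    a0 = float(np.log(np.trapezoid(f * m, b) / np.trapezoid(f, b))) - s0 * 27.0
    sol = optimize.fsolve(eqs, [a0, s0], full_output=False, xtol=1e-12)
    slope = float(sol[1])
    return 100.0 * (np.exp(2.0 * slope) - 1.0)


def attributable_truth(config: SimulationConfig, population, outcome: str, kind: str = "cost") -> dict:
    """True excess-weight attributable costs under a population table.

    Returns per-coarse-category totals T_k, attributable A_k and
    proportions P_k (fractions, not percent), plus the >=25 aggregate.
    Population counts are in millions of women, costs in GBP, so totals
    are in GBP millions.
    """
    fine = category_means(config, outcome, kind)
    coarse_cost = {}
    for coarse in COARSE_CATEGORIES:
        members = [c for c in FINE_CATEGORIES if population.fine_to_coarse[c] == coarse]
        w = np.array([population.fine_weights[c] for c in members])
        coarse_cost[coarse] = float(np.sum(w * np.array([fine[c] for c in members])))
    w_ref = np.array([population.fine_weights[c] for c in REFERENCE_BANDS])
    c_ref = float(np.sum(w_ref / w_ref.sum() * np.array([fine[c] for c in REFERENCE_BANDS])))
    rows = {}
    agg_T = agg_A = 0.0
    for coarse in EXCESS_COARSE:
        N = population.coarse_counts[coarse]
        T = N * coarse_cost[coarse]
        A = N * (coarse_cost[coarse] - c_ref)
        rows[coarse] = {"total": T, "attributable": A, "proportion": A / T}
        agg_T += T
        agg_A += A
    rows["25+"] = {"total": agg_T, "attributable": agg_A, "proportion": agg_A / agg_T}
    rows["reference_cost"] = c_ref
    return rows


def truth_record(config: SimulationConfig, population=None) -> dict:
    """All ground-truth generative parameters plus implied quantities."""
    rec: dict = {"config": config.to_dict()}
    rec["covariate_mean_multiplier"] = covariate_mean_multiplier(config)
    rec["frailty_mean_multiplier"] = float(np.exp(config.frailty_sd**2 / 2.0))
    rec["category_shares"] = category_shares(config)
    rec["direct_pct_per_2kgm2"] = {
        out: 100.0 * (np.exp(2.0 * config.slope_per_unit_bmi[out]) - 1.0)
        for out in config.slope_per_unit_bmi
    }
    rec["implied_trend_pct_per_2kgm2"] = {
        f"{out}_{kind}": implied_trend_pct(config, out, kind)
        for out in ("consult", "rx", "test")
        for kind in ("count", "cost")
    }
    rec["category_means"] = {
        f"{out}_{kind}": category_means(config, out, kind)
        for out in ("consult", "rx", "test")
        for kind in ("count", "cost")
    }
    b = bmi_grid(config)
    f = bmi_pdf(config, b)
    prev = diabetes_personyear_prevalence(config, b)
    rec["diabetes_personyear_prevalence"] = float(
        np.trapezoid(f * prev, b) / np.trapezoid(f, b)
    )
    if population is not None:
        rec["attributable"] = {
            f"{out}_cost": attributable_truth(config, population, out, "cost")
            for out in ("consult", "rx")
        }
    return rec
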