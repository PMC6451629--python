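"""Effect measures for BMI-category models.

Converts fitted categorical models into the reporting scale used in
dose-response cohort tables: percentage differences versus the 20-<22.5
reference with *floating* (quasi-variance) group-specific confidence
intervals, the percentage difference per 2 kg/m^2 above 20 from a linear
model, a measured-BMI remapping for self-report correction, and an
inverse-variance chi-square test of subgroup heterogeneity.

The floating absolute risk construction assigns a pseudo-variance v_k to
every category, the reference included, such that the variance of any
pairwise log contrast is approximated by v_i + v_j.  This lets readers
compare any two categories, not just each against the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .glm import DesignError, FitResult, build_design, fit_quasipoisson

#: Normal quantile for 99% intervals.
Z99 = 2.5758293035489004


class EffectsError(ValueError):
    pass


@dataclass
class FloatedEffects:
    """Per-category log effects with floated variances and 99% CIs."""

    categories: list
    log_effect: np.ndarray  # lambda_k, reference = 0
    floated_var: np.ndarray  # v_k > 0, reference included
    reference: str

    def frame(self) -> pd.DataFrame:
        lam, v = self.log_effect, self.floated_var
        lo = lam - Z99 * np.sqrt(v)
        hi = lam + Z99 * np.sqrt(v)
        return pd.DataFrame(
            {
                "category": self.categories,
                "log_effect": lam,
                "floated_var": v,
                "pct_diff": 100.0 * (np.exp(lam) - 1.0),
                "pct_lo": 100.0 * (np.exp(lo) - 1.0),
                "pct_hi": 100.0 * (np.exp(hi) - 1.0),
            }
        )


def floated_variances(contrast_cov: np.ndarray) -> np.ndarray:
    """Quasi-variances for K categories from the (K-1)x(K-1) contrast covariance.

    Minimises  sum_{i<j} (log(v_i + v_j) - log Var(lambda_i - lambda_j))^2
    over all category pairs, the reference included (for which
    Var(lambda_ref - lambda_j) = Var(lambda_j)).  The log-scale objective
    is scale-free and standard in the quasi-variance literature.  Solved
    by deterministic least squares on theta = log v, initialised from the
    shared-reference decomposition v0 = mean off-diagonal covariance,
    which is exact whenever the covariance has the structure
    Cov = v0 + diag(v_1..v_{K-1}).

    Returns v of length K with the reference variance first.
    """
    C = np.asarray(contrast_cov, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise EffectsError("contrast covariance must be square")
    Km1 = C.shape[0]
    K = Km1 + 1
    if K < 3:
        raise EffectsError("floated variances need at least 3 categories")
    eig = np.linalg.eigvalsh((C + C.T) / 2.0)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise EffectsError("contrast covariance is not positive semi-definite")

    # target pairwise contrast variances over all K categories
    pairs = []
    targets = []
    for j in range(Km1):  # reference vs j
        pairs.append((0, j + 1))
        targets.append(C[j, j])
    for i in range(Km1):
        for j in range(i + 1, Km1):
            pairs.append((i + 1, j + 1))
            targets.append(C[i, i] + C[j, j] - 2.0 * C[i, j])
    targets = np.asarray(targets)
    if np.any(targets <= 0):
        raise EffectsError("a pairwise contrast variance is non-positive")
    pi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])

    def resid(theta):
        v = np.exp(theta)
        return np.log(v[pi] + v[pj]) - np.log(targets)

    def objective(theta):
        return float(np.sum(resid(theta) ** 2))

    # deterministic multistart: the shared-reference decomposition (exact
    # when Cov = v0 + diag) plus an equal-split init for degenerate shapes
    if Km1 > 1:
        v0 = float(np.mean(C[np.triu_indices(Km1, k=1)]))
    else:
        v0 = 0.5 * float(C[0, 0])
    v0 = max(v0, 1e-3 * float(np.min(np.diag(C))))
    inits = [
        np.concatenate([[v0], np.maximum(np.diag(C) - v0, 1e-3 * np.diag(C))]),
        np.full(K, 0.5 * float(np.mean(np.diag(C)))),
    ]
    best = None
    for vinit in inits:
        sol = optimize.least_squares(resid, np.log(vinit), method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or objective(sol.x) < objective(best):
            best = sol.x
    # derivative-free polish guards against stalls at the v -> 0 boundary
    polish = optimize.minimize(
        objective, best, method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 20000},
    )
    if polish.fun < objective(best):
        best = polish.x
    return np.exp(best)


def percent_differences(fit: FitResult) -> FloatedEffects:
    """Percentage differences vs the reference category with floated 99% CIs.

    Extracts the category log relative rates and their cluster-robust
    contrast covariance from a categorical fit and delegates to
    :func:`floated_variances`.
    """
    if fit.design.spec.exposure != "bmi_category_fine":
        raise EffectsError(
            "percent differences require a model with the categorical BMI exposure"
        )
    idx = fit.design.exposure_indices()
    if len(idx) < 2:
        raise EffectsError("too few BMI categories in the fitted model")
    lam = np.concatenate([[0.0], fit.beta[idx]])
    C = fit.cov_cluster[np.ix_(idx, idx)]
    v = floated_variances(C)
    ref = fit.design.spec.reference
    cats = [ref] + [fit.design.columns[i][2] for i in idx]
    order = np.argsort([_cat_sort_key(c) for c in cats])
    return FloatedEffects(
        categories=[cats[i] for i in order],
        log_effect=lam[order],
        floated_var=v[order],
        reference=ref,
    )


def _cat_sort_key(label: str) -> float:
    try:
        return float(str(label).split("-")[0].rstrip("+"))
    except ValueError:
        return np.inf


@dataclass
class TrendEstimate:
    """Log-linear BMI trend above 20 kg/m^2 with cluster-robust 99% CI."""

    slope: float  # per 1 kg/m^2
    se_cluster: float
    n: int

    @property
    def pct_per_2(self) -> float:
        return 100.0 * (np.exp(2.0 * self.slope) - 1.0)

    @property
    def ci_pct_per_2(self) -> tuple[float, float]:
        lo = 100.0 * (np.exp(2.0 * (self.slope - Z99 * self.se_cluster)) - 1.0)
        hi = 100.0 * (np.exp(2.0 * (self.slope + Z99 * self.se_cluster)) - 1.0)
        return lo, hi


def trend_above_20(panel: pd.DataFrame, spec) -> TrendEstimate:
    """Percentage difference per 2 kg/m^2 higher BMI above 20 kg/m^2.

    Fits the model spec with BMI entered linearly on the subset of rows
    with BMI > 20 (strict, matching the half-open category convention).
    """
    spec = spec.__class__(**{**spec.__dict__, "exposure": "bmi_linear_above20"})
    design = build_design(panel, spec)
    fit = fit_quasipoisson(design)
    (j,) = [i for i, t in enumerate(design.columns) if t == ("num", "bmi")]
    return TrendEstimate(
        slope=float(fit.beta[j]),
        se_cluster=float(np.sqrt(fit.cov_cluster[j, j])),
        n=design.n,
    )


def remap_measured_bmi(panel: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Replace self-reported BMI by mean measured BMI per category.

    Used as a sensitivity analysis for self-report error: every row's
    continuous BMI becomes ``mapping[its fine category]``; downstream
    linear trends are then re-estimated on the remapped values.  The
    category column itself is untouched.
    """
    cats = panel["bmi_category_fine"].unique()
    unmapped = [c for c in cats if c not in mapping]
    if unmapped:
        raise EffectsError(f"mapping lacks fine categories: {sorted(unmapped)}")
    out = panel.copy()
    out["bmi"] = out["bmi_category_fine"].map(mapping).astype(float)
    return out


def subgroup_heterogeneity(estimates) -> tuple[float, int, float]:
    """Chi-square heterogeneity test for subgroup slopes.

    ``estimates`` is a sequence of (slope, variance) pairs, one per
    subgroup.  Returns (Q, df, p) where Q is the inverse-variance
    weighted sum of squared deviations from the pooled slope.
    """
    est = [(float(b), float(v)) for b, v in estimates]
    if len(est) < 2:
        raise EffectsError("heterogeneity test needs at least 2 subgroups")
    if any(v <= 0 for _, v in est):
        raise EffectsError("all subgroup variances must be positive")
    b = np.array([e[0] for e in est])
    w = 1.0 / np.array([e[1] for e in est])
    bbar = float(np.sum(w * b) / np.sum(w))
    Q = float(np.sum(w * (b - bbar) ** 2))
    df = len(est) - 1
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p
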