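"""Population projection of excess-weight-attributable annual costs.

Standardized per-person annual costs by fine BMI category are combined
with a population table (millions of women by coarse category, with fine
weights inside each coarse band) to give total annual costs T_k = N_k c_k,
costs attributable to excess weight A_k = N_k (c_k - c_ref), and
attributable proportions P_k = A_k / T_k, per coarse category and for the
>=25 aggregate.  The reference cost c_ref is the weighted average of the
20-<22.5 and 22.5-<25 standardized costs (the 20-24.9 band).

Uncertainty: parameter-simulation draws of the standardized costs are
re-projected draw by draw; 99% intervals are the 0.5/99.5 percentiles
(population counts are treated as fixed).  Attributable costs may be
negative when a category is cheaper than the reference; they are never
truncated.  Percentages are reported rounded half away from zero, with
full precision retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .categories import (
    COARSE_CATEGORIES,
    EXCESS_COARSE,
    FINE_CATEGORIES,
    REFERENCE_BANDS,
)
from .simulate import PopulationTable
from .standardize import standardized_draws


class ProjectionError(ValueError):
    pass


AGGREGATE = "25+"


def round_half_away(x) -> np.ndarray:
    """Round to integer, halves away from zero (not banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def coarse_costs(std: dict, pop: PopulationTable) -> tuple[dict, float]:
    """Per-person cost by coarse category, and the 20-24.9 reference cost.

    ``std`` maps every fine category to its standardized per-person cost.
    Coarse costs are fine-weight averages; the reference uses the weights
    of the two reference bands renormalised within themselves.
    """
    missing = [c for c in FINE_CATEGORIES if c not in std]
    if missing:
        raise ProjectionError(f"standardized estimates missing fine categories: {missing}")
    coarse = {}
    for cat in COARSE_CATEGORIES:
        members = [f for f in FINE_CATEGORIES if pop.fine_to_coarse[f] == cat]
        w = np.array([pop.fine_weights[f] for f in members])
        coarse[cat] = float(np.sum(w * np.array([std[f] for f in members])))
    w_ref = np.array([pop.fine_weights[f] for f in REFERENCE_BANDS])
    if w_ref.sum() <= 0:
        raise ProjectionError("reference bands carry no population weight")
    c_ref = float(
        np.sum(w_ref / w_ref.sum() * np.array([std[f] for f in REFERENCE_BANDS]))
    )
    return coarse, c_ref


@dataclass
class ProjectionResult:
    """Projection table: totals, attributable costs and proportions.

    ``table`` has one row per coarse category plus the >=25 aggregate;
    costs are GBP millions per year (population counts are millions of
    women, per-person costs GBP).  CI columns are present after a
    bootstrap run.
    """

    table: pd.DataFrame
    reference_cost: float
    outcome: str = ""

    def row(self, category: str) -> pd.Series:
        return self.table.set_index("category").loc[category]

    @property
    def aggregate_proportion(self) -> float:
        return float(self.row(AGGREGATE)["proportion"])

    @property
    def aggregate_attributable(self) -> float:
        return float(self.row(AGGREGATE)["attributable"])


def _project_arrays(c_fine: np.ndarray, cats: list, pop: PopulationTable):
    """Vectorised projection of (d, K) standardized-cost draws.

    Returns per-coarse totals/attributables/proportions, each of shape
    (d, len(EXCESS_COARSE) + 1) with the aggregate last.
    """
    pos = {c: i for i, c in enumerate(cats)}
    W = np.zeros((len(cats), len(COARSE_CATEGORIES)))
    for j, coarse in enumerate(COARSE_CATEGORIES):
        for f in FINE_CATEGORIES:
            if pop.fine_to_coarse[f] == coarse:
                W[pos[f], j] = pop.fine_weights[f]
    coarse_c = c_fine @ W  # (d, 5)
    w_ref = np.array([pop.fine_weights[f] for f in REFERENCE_BANDS])
    w_ref = w_ref / w_ref.sum()
    c_ref = c_fine[:, [pos[f] for f in REFERENCE_BANDS]] @ w_ref  # (d,)
    N = np.array([pop.coarse_counts[c] for c in COARSE_CATEGORIES])
    excess_idx = [COARSE_CATEGORIES.index(c) for c in EXCESS_COARSE]
    T = coarse_c[:, excess_idx] * N[excess_idx]
    A = (coarse_c[:, excess_idx] - c_ref[:, None]) * N[excess_idx]
    T = np.column_stack([T, T.sum(axis=1)])
    A = np.column_stack([A, A.sum(axis=1)])
    P = A / T
    return T, A, P, c_ref, coarse_c


def project(std, pop: PopulationTable, outcome: str = "") -> ProjectionResult:
    """Point projection from standardized fine-category costs.

    ``std`` is a mapping fine category -> standardized per-person cost
    (a :class:`StandardizedEstimates` also works via ``as_dict``).
    """
    if hasattr(std, "as_dict"):
        std = std.as_dict()
    if any(n <= 0 for n in pop.coarse_counts.values()):
        raise ProjectionError("population counts must be positive")
    cats = list(FINE_CATEGORIES)
    c = np.array([[std[f] for f in cats]])
    T, A, P, c_ref, coarse_c = _project_arrays(c, cats, pop)
    rows = []
    # the <25 row carries total costs only; nothing is attributable there
    n_lt25 = pop.coarse_counts["<25"]
    rows.append(
        {
            "category": "<25",
            "n_million": n_lt25,
            "total": n_lt25 * coarse_c[0, 0],
            "attributable": np.nan,
            "proportion": np.nan,
        }
    )
    labels = EXCESS_COARSE + [AGGREGATE]
    n_agg = sum(pop.coarse_counts[c] for c in EXCESS_COARSE)
    for j, lab in enumerate(labels):
        rows.append(
            {
                "category": lab,
                "n_million": pop.coarse_counts.get(lab, n_agg),
                "total": T[0, j],
                "attributable": A[0, j],
                "proportion": P[0, j],
            }
        )
    table = pd.DataFrame(rows)
    table["proportion_pct_rounded"] = round_half_away(100.0 * table["proportion"])
    return ProjectionResult(table=table, reference_cost=float(c_ref[0]), outcome=outcome)


def bootstrap_projection(
    fit,
    panel: pd.DataFrame,
    pop: PopulationTable,
    n_draws: int = 10_000,
    seed: int = 0,
    outcome: str = "",
) -> ProjectionResult:
    """Projection with bootstrap-percentile 99% CIs for A_k and P_k.

    Parameter draws are re-standardized and re-projected; population
    counts carry no sampling error.
    """
    cats, point, draws = standardized_draws(fit, panel, n_draws, seed)
    result = project(dict(zip(cats, point)), pop, outcome=outcome)
    T, A, P, _, _ = _project_arrays(draws, cats, pop)
    a_lo, a_hi = np.percentile(A, [0.5, 99.5], axis=0)
    p_lo, p_hi = np.percentile(P, [0.5, 99.5], axis=0)
    table = result.table.set_index("category")
    labels = EXCESS_COARSE + [AGGREGATE]
    for name, arr in [
        ("attributable_lo99", a_lo),
        ("attributable_hi99", a_hi),
        ("proportion_lo99", p_lo),
        ("proportion_hi99", p_hi),
    ]:
        table[name] = np.nan
        table.loc[labels, name] = arr
    return ProjectionResult(
        table=table.reset_index(), reference_cost=result.reference_cost, outcome=outcome
    )


def therapeutic_attribution(
    fits_by_use: dict, panel: pd.DataFrame, pop: PopulationTable, n_draws: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Excess-weight-attributable annual prescription costs by therapeutic use.

    One fitted cost model per use category; each is standardized,
    projected, and its >=25 aggregate attributable cost reported along
    with its share of the summed attributable cost.
    """
    rows = []
    for use, fit in fits_by_use.items():
        outcome_col = fit.design.spec.outcome
        if outcome_col not in panel.columns:
            raise ProjectionError(
                f"panel lacks the fitted outcome column {outcome_col!r} for use {use!r}"
            )
        cats, point, _ = standardized_draws(fit, panel, max(n_draws, 100), seed)
        res = project(dict(zip(cats, point)), pop, outcome=use)
        rows.append({"therapeutic_use": use, "attributable": res.aggregate_attributable})
    out = pd.DataFrame(rows)
    total = out["attributable"].sum()
    if total == 0:
        raise ProjectionError("total attributable cost is zero; shares undefined")
    out["share"] = out["attributable"] / total
    return out.sort_values("attributable", ascending=False, ignore_index=True)
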