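"""End-to-end orchestration: simulate or load, fit, standardize, project.

``run_all`` reproduces the full reporting stack on one dataset:

* per-outcome standardized annual rates/costs with 99% CIs and floated
  percentage differences (table2.csv),
* linear trends per 2 kg/m^2 above 20 (trends.csv),
* population projection of attributable consultation and prescription
  costs with bootstrap-percentile CIs (table3.csv),
* attributable prescription costs by therapeutic use (fig2_attribution.csv),
* the diabetes mediation decomposition (mediation.csv),
* for simulated data, truth-versus-estimate comparisons
  (truth_vs_estimate.csv) and a run manifest.

All randomness flows from the single run seed through named substreams:
the simulation stream is the config seed itself; the bootstrap stream is
an independent child, so changing n_draws never perturbs the simulated
data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import truth as truth_mod
from .categories import FINE_CATEGORIES
from .config import COVARIATES, RX_USE_CATEGORIES, SimulationConfig
from .effects import percent_differences, trend_above_20
from .glm import ModelSpec, fit_model
from .io import RunConfig, read_tables, write_dataset
from .mediate import mediation_proportion
from .project import bootstrap_projection, project, therapeutic_attribution
from .simulate import generate_cohort, generate_panel, generate_population_table, unit_cost_table
from .standardize import standardized_cis, standardized_draws

logger = logging.getLogger("bmicost")

#: Adjustment set of the primary analysis models.
DEFAULT_ADJUSTERS = [
    "age_band",
    "region",
    "deprivation_third",
    "education",
    "parity",
    "age_first_birth",
    "smoking",
    "alcohol",
    "financial_year",
    "fraction_observed",
]

#: Outcome columns reported in the rate/cost table.
TABLE2_OUTCOMES = [
    "consult_count",
    "consult_cost",
    "test_count",
    "test_cost",
    "rx_count",
    "rx_cost",
]


class PipelineError(RuntimeError):
    pass


def seed_streams(seed: int) -> tuple[int, int]:
    """(simulation_seed, bootstrap_seed) derived from the run seed."""
    children = np.random.SeedSequence(seed).spawn(2)
    return tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)


def default_spec(outcome: str, adjusters=None, extra_adjusters=()) -> ModelSpec:
    adj = list(DEFAULT_ADJUSTERS if adjusters is None else adjusters)
    adj += [a for a in extra_adjusters if a not in adj]
    return ModelSpec(outcome=outcome, exposure="bmi_category_fine", adjusters=adj)


def apply_filters(panel: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    out = panel
    for name, mask in [
        (
            f"exclude_bmi_above={config.exclude_bmi_above}",
            None if config.exclude_bmi_above is None else out["bmi"] <= config.exclude_bmi_above,
        ),
        (
            "never_smokers_only",
            (out["smoking"] == "never") if config.never_smokers_only else None,
        ),
        (
            f"min_year_index={config.min_year_index}",
            None if config.min_year_index is None else out["year_index"] >= config.min_year_index,
        ),
    ]:
        if mask is None:
            continue
        out = out[mask]
        if len(out) == 0:
            raise PipelineError(f"filter {name} removed every person-year")
    return out


def _obtain_data(config: RunConfig):
    if config.simulate is not None:
        sim_seed, _ = seed_streams(config.seed)
        sim = config.simulate.with_updates(seed=sim_seed)
        cohort = generate_cohort(sim)
        panel = generate_panel(cohort, sim)
        population = generate_population_table()
        truth = truth_mod.truth_record(sim, population)
        return cohort, panel, population, unit_cost_table(sim), truth, sim
    tables = read_tables(config.inputs)
    if "panel" not in tables or "population" not in tables:
        raise PipelineError("inputs must provide at least person_years and population paths")
    return (
        tables.get("cohort"),
        tables["panel"],
        tables["population"],
        tables.get("unit_costs"),
        None,
        None,
    )


def run_all(config: RunConfig) -> dict:
    """Run the complete analysis; writes CSV reports and returns them."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, boot_seed = seed_streams(config.seed)

    cohort, panel, population, unit_costs, truth, sim = _obtain_data(config)
    panel = apply_filters(panel, config)
    logger.info("analysis panel: %d person-years, %d women", len(panel), panel["person_id"].nunique())

    if sim is not None and cohort is not None:
        write_dataset(out_dir / "data", cohort, panel, unit_costs, population, truth)

    # --- table 2: standardized rates/costs + floated percent differences
    table2_rows = []
    fits = {}
    for k, outcome in enumerate(TABLE2_OUTCOMES):
        logger.info("fitting %s", outcome)
        fit = fit_model(panel, default_spec(outcome))
        fits[outcome] = fit
        std = standardized_cis(fit, panel, n_draws=config.n_draws, seed=boot_seed + k)
        fl = percent_differences(fit).frame().set_index("category")
        for cat, row in std.frame().set_index("category").iterrows():
            table2_rows.append(
                {
                    "outcome": outcome,
                    "category": cat,
                    "estimate": row["estimate"],
                    "lo99": row["lo99"],
                    "hi99": row["hi99"],
                    "pct_diff": fl.loc[cat, "pct_diff"],
                    "pct_lo99": fl.loc[cat, "pct_lo"],
                    "pct_hi99": fl.loc[cat, "pct_hi"],
                    "dispersion": fit.dispersion,
                }
            )
    table2 = pd.DataFrame(table2_rows)

    # --- linear trends above 20 for cost outcomes
    trend_rows = []
    for outcome in ("consult_cost", "rx_cost", "test_cost"):
        tr = trend_above_20(panel, default_spec(outcome))
        lo, hi = tr.ci_pct_per_2
        trend_rows.append(
            {
                "outcome": outcome,
                "slope_per_unit": tr.slope,
                "pct_per_2": tr.pct_per_2,
                "pct_lo99": lo,
                "pct_hi99": hi,
                "n_person_years": tr.n,
            }
        )
    trends = pd.DataFrame(trend_rows)

    # --- table 3: projection with bootstrap CIs
    table3_parts = []
    projections = {}
    for k, outcome in enumerate(("consult_cost", "rx_cost")):
        proj = bootstrap_projection(
            fits[outcome], panel, population,
            n_draws=config.n_draws, seed=boot_seed + 100 + k, outcome=outcome,
        )
        projections[outcome] = proj
        part = proj.table.copy()
        part.insert(0, "outcome", outcome)
        table3_parts.append(part)
    table3 = pd.concat(table3_parts, ignore_index=True)

    # --- fig 2: attributable prescription costs by therapeutic use
    logger.info("therapeutic-use attribution (18 cost models)")
    fits_by_use = {
        use: fit_model(panel, default_spec(f"rx_cost_{use}"))
        for use in RX_USE_CATEGORIES
        if panel[f"rx_cost_{use}"].sum() > 0
    }
    fig2 = therapeutic_attribution(fits_by_use, panel, population, seed=boot_seed + 200)

    # --- mediation via diabetes adjustment
    med_rows = []
    for outcome in ("consult_cost", "rx_cost"):
        fit_adj = fit_model(panel, default_spec(outcome, extra_adjusters=("diabetes_flag",)))
        cats, point, _ = standardized_draws(fit_adj, panel, 100, boot_seed)
        proj_adj = project(dict(zip(cats, point)), population, outcome=outcome)
        med = mediation_proportion(projections[outcome], proj_adj, outcome=outcome)
        med_rows.append(med.frame())
    mediation = pd.concat(med_rows, ignore_index=True)

    outputs = {
        "table2": table2,
        "trends": trends,
        "table3": table3,
        "fig2_attribution": fig2,
        "mediation": mediation,
    }

    # --- truth vs estimate (simulation mode only)
    if truth is not None:
        tv_rows = []
        for outcome, key in (("consult_cost", "consult_cost"), ("rx_cost", "rx_cost"), ("test_cost", "test_cost")):
            tr = trends.set_index("outcome").loc[outcome]
            true_pct = truth["implied_trend_pct_per_2kgm2"][key]
            tv_rows.append(
                {
                    "quantity": f"trend_pct_per_2_{outcome}",
                    "truth": true_pct,
                    "estimate": tr["pct_per_2"],
                    "lo99": tr["pct_lo99"],
                    "hi99": tr["pct_hi99"],
                    "covered": bool(tr["pct_lo99"] <= true_pct <= tr["pct_hi99"]),
                }
            )
        for outcome in ("consult_cost", "rx_cost"):
            true_p = truth["attributable"][outcome]["25+"]["proportion"]
            row = projections[outcome].row("25+")
            tv_rows.append(
                {
                    "quantity": f"attributable_proportion_25plus_{outcome}",
                    "truth": true_p,
                    "estimate": row["proportion"],
                    "lo99": row["proportion_lo99"],
                    "hi99": row["proportion_hi99"],
                    "covered": bool(row["proportion_lo99"] <= true_p <= row["proportion_hi99"]),
                }
            )
        outputs["truth_vs_estimate"] = pd.DataFrame(tv_rows)

    for name, df in outputs.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "seed": config.seed,
        "n_draws": config.n_draws,
        "n_person_years": int(len(panel)),
        "n_women": int(panel["person_id"].nunique()),
        "simulated": sim is not None,
        "package": "bmicost 0.1.0",
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    outputs["manifest"] = manifest
    return outputs
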