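"""Reading, writing and validation of the pipeline's delimited tables.

All files are UTF-8 comma-separated CSV with "." decimals; currency is
GBP units (not pence).  Financial-year convention: year index t covers
April of calendar year 2006+t to March of the following year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .categories import FINE_CATEGORIES
from .config import COVARIATES, RX_USE_CATEGORIES, ConfigError, SimulationConfig
from .simulate import PopulationTable


class SchemaError(ValueError):
    """An input table violates its schema."""


PANEL_REQUIRED = [
    "person_id",
    "year_index",
    "fraction_observed",
    "bmi",
    "bmi_category_fine",
    "diabetes_flag",
    "consult_count",
    "test_count",
    "rx_count",
    "consult_cost",
    "test_cost",
    "rx_cost",
]

COHORT_REQUIRED = ["person_id", "bmi", "bmi_category_fine"] + COVARIATES

COUNT_COLUMNS = ["consult_count", "test_count", "rx_count"] + [
    f"rx_count_{u}" for u in RX_USE_CATEGORIES
]


def validate_panel(panel: pd.DataFrame, name: str = "person_years.csv") -> pd.DataFrame:
    missing = [c for c in PANEL_REQUIRED if c not in panel.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    bad_cat = set(panel["bmi_category_fine"].unique()) - set(FINE_CATEGORIES)
    if bad_cat:
        raise SchemaError(f"{name}: unknown BMI categories {sorted(bad_cat)}")
    for col in COUNT_COLUMNS:
        if col not in panel.columns:
            continue
        vals = pd.to_numeric(panel[col], errors="coerce")
        bad = panel.index[(vals < 0) | vals.isna()]
        if len(bad):
            raise SchemaError(f"{name}: column {col!r} invalid at row {bad[0]}")
    frac = pd.to_numeric(panel["fraction_observed"], errors="coerce")
    bad = panel.index[~((frac > 0) & (frac <= 1))]
    if len(bad):
        raise SchemaError(f"{name}: fraction_observed outside (0, 1] at row {bad[0]}")
    return panel


def validate_cohort(cohort: pd.DataFrame, name: str = "cohort.csv") -> pd.DataFrame:
    missing = [c for c in COHORT_REQUIRED if c not in cohort.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    if cohort["person_id"].duplicated().any():
        raise SchemaError(f"{name}: duplicate person_id values")
    if (pd.to_numeric(cohort["bmi"], errors="coerce") < 18.5).any():
        raise SchemaError(f"{name}: BMI below 18.5")
    return cohort


def validate_unit_costs(table: pd.DataFrame, name: str = "unit_costs.csv") -> pd.DataFrame:
    for col in ("category", "unit_cost"):
        if col not in table.columns:
            raise SchemaError(f"{name}: missing column {col!r}")
    if table["category"].duplicated().any():
        raise SchemaError(f"{name}: duplicate categories")
    if (pd.to_numeric(table["unit_cost"], errors="coerce") < 0).any():
        raise SchemaError(f"{name}: negative unit cost")
    return table


def write_dataset(
    out_dir,
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    unit_costs: pd.DataFrame,
    population: PopulationTable,
    truth: dict | None = None,
) -> dict:
    """Write the synthetic dataset as CSV (+ truth.json); returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "person_years": out / "person_years.csv",
        "unit_costs": out / "unit_costs.csv",
        "population": out / "population.csv",
    }
    cohort.drop(columns=[c for c in cohort.columns if c.startswith("_")]).to_csv(
        paths["cohort"], index=False
    )
    panel.to_csv(paths["person_years"], index=False)
    unit_costs.to_csv(paths["unit_costs"], index=False)
    population.to_frame().to_csv(paths["population"], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, default=float)
    return {k: str(v) for k, v in paths.items()}


def read_tables(paths: dict) -> dict:
    """Read and validate the four input tables.

    ``paths`` maps any of cohort / person_years / unit_costs / population
    to file paths; person_years and population are required for the full
    pipeline.
    """
    out: dict = {}
    if "person_years" in paths:
        out["panel"] = validate_panel(pd.read_csv(paths["person_years"]), str(paths["person_years"]))
    if "cohort" in paths:
        out["cohort"] = validate_cohort(pd.read_csv(paths["cohort"]), str(paths["cohort"]))
    if "unit_costs" in paths:
        out["unit_costs"] = validate_unit_costs(
            pd.read_csv(paths["unit_costs"]), str(paths["unit_costs"])
        )
    if "population" in paths:
        try:
            out["population"] = PopulationTable.from_frame(pd.read_csv(paths["population"]))
        except ConfigError as e:
            raise SchemaError(f"{paths['population']}: {e}") from e
    return out


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-serialisable).

    Exactly one of ``simulate`` (a simulation config) or ``inputs``
    (paths to the four tables) must be given.  Optional filters emulate
    the sensitivity re-runs: dropping very high BMI, restricting to
    never-smokers, or restricting follow-up years.
    """

    simulate: Optional[SimulationConfig] = None
    inputs: Optional[dict] = None
    n_draws: int = 1000
    seed: int = 0
    output_dir: str = "bmicost_out"
    exclude_bmi_above: Optional[float] = None
    never_smokers_only: bool = False
    min_year_index: Optional[int] = None

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be set")
        if self.n_draws < 100:
            raise ConfigError("n_draws must be at least 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            simulate=SimulationConfig.from_dict(sim) if sim is not None else None,
            **raw,
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        raw = {
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "inputs": self.inputs,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "exclude_bmi_above": self.exclude_bmi_above,
            "never_smokers_only": self.never_smokers_only,
            "min_year_index": self.min_year_index,
        }
        with open(path, "w") as fh:
            yaml.safe_dump({k: v for k, v in raw.items() if v is not None}, fh, sort_keys=False)
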