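"""Diabetes mediation of excess-weight-attributable costs.

The adjusted-difference heuristic: refit the cost model with diabetes
status added as a covariate, re-project, and express the drop in the
>=25 aggregate attributable proportion relative to the unadjusted
proportion.  This is not a causal natural-effect decomposition; it simply
asks how much of the attributable proportion survives conditioning on
diabetes.  A secondary measure on absolute attributable costs is also
reported because the proportion-based and cost-based readings can differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .project import ProjectionResult


class MediationError(ValueError):
    pass


def carry_forward_diabetes(panel: pd.DataFrame, onset: dict) -> pd.DataFrame:
    """Set the diabetes flag from each person's onset year onward.

    ``onset`` maps person_id -> first year index with evidence of
    diabetes; persons absent from the mapping are never flagged.  An
    onset before the first observed year simply flags every year.
    """
    out = panel.copy()
    onset_years = out["person_id"].map(onset)
    out["diabetes_flag"] = (~onset_years.isna()) & (
        out["year_index"] >= onset_years.fillna(np.inf)
    )
    return out


@dataclass
class MediationResult:
    """Share of the attributable proportion accounted for by diabetes."""

    outcome: str
    p_base: float
    p_adj: float
    a_base: float
    a_adj: float

    @property
    def explained(self) -> float:
        """Relative reduction of the >=25 attributable *proportion*."""
        return (self.p_base - self.p_adj) / self.p_base

    @property
    def explained_absolute(self) -> float:
        """Secondary measure: relative reduction of absolute attributable cost."""
        return (self.a_base - self.a_adj) / self.a_base

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "p_base": self.p_base,
                    "p_adj": self.p_adj,
                    "explained": self.explained,
                    "attributable_base": self.a_base,
                    "attributable_adj": self.a_adj,
                    "explained_absolute": self.explained_absolute,
                }
            ]
        )


def mediation_proportion(
    base: ProjectionResult, adjusted: ProjectionResult, outcome: str = ""
) -> MediationResult:
    """Proportion of attributable costs explained by diabetes.

    ``base`` is the primary projection; ``adjusted`` comes from the same
    panel and population with diabetes status added to the model.
    """
    p_base = base.aggregate_proportion
    p_adj = adjusted.aggregate_proportion
    if not np.isfinite(p_base) or p_base <= 0:
        raise MediationError(
            "base attributable proportion is not positive; mediation undefined"
        )
    return MediationResult(
        outcome=outcome or base.outcome,
        p_base=p_base,
        p_adj=p_adj,
        a_base=base.aggregate_attributable,
        a_adj=adjusted.aggregate_attributable,
    )
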