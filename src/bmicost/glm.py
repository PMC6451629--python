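"""Quasi-Poisson GLM engine with cluster-robust covariance.

Log-link models with Poisson-like variance ``Var(y) = phi * mu`` are fit
by iteratively reweighted least squares (via statsmodels); the quasi-
likelihood score equations are identical for integer counts and for
non-negative continuous costs, so both outcome kinds share one family.
Overdispersion ``phi`` is the Pearson statistic over residual degrees of
freedom.  Cluster-robust (sandwich) covariance sums score contributions
within persons, absorbing the within-person correlation across follow-up
years; the meat carries no dispersion factor and a G/(G-1) small-sample
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml


class DesignError(ValueError):
    """Design matrix cannot be built as requested."""


class FitError(RuntimeError):
    """Model fitting failed."""


#: Columns treated as continuous whenever they appear as adjusters.
CONTINUOUS_ADJUSTERS = {"fraction_observed", "bmi"}


@dataclass
class ModelSpec:
    """Specification of one outcome model.

    ``exposure`` is either ``"bmi_category_fine"`` (categorical, coded
    against ``reference``), ``"bmi_linear_above20"`` (continuous BMI,
    restricted to rows with BMI > 20) or ``None``.  Categorical adjusters
    are reference-coded with the first level in sorted order as reference;
    an injected ``"missing"`` label is always kept as a non-reference
    level.  ``cluster`` names the independence unit.
    """

    outcome: str
    exposure: Optional[str] = "bmi_category_fine"
    adjusters: Sequence[str] = field(default_factory=list)
    subset: Optional[str] = None
    cluster: str = "person_id"
    reference: str = "20-22.5"

    def __post_init__(self) -> None:
        if self.exposure not in (None, "bmi_category_fine", "bmi_linear_above20"):
            raise DesignError(f"unsupported exposure {self.exposure!r}")
        if self.exposure in self.adjusters:
            raise DesignError("exposure and adjusters must be disjoint")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "outcome": self.outcome,
                "exposure": self.exposure,
                "adjusters": list(self.adjusters),
                "subset": self.subset,
                "cluster": self.cluster,
                "reference": self.reference,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls(**yaml.safe_load(text))


@dataclass
class DesignBundle:
    """Response, design matrix and coding metadata for one model."""

    y: np.ndarray
    X: np.ndarray
    columns: list  # parallel to X columns: ("intercept",), ("cat", var, level), ("num", var)
    cluster_ids: np.ndarray
    row_index: np.ndarray  # positional index into the source panel
    spec: ModelSpec
    levels: dict  # categorical var -> full ordered level list (reference first)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_names(self) -> list[str]:
        out = []
        for term in self.columns:
            if term[0] == "intercept":
                out.append("intercept")
            elif term[0] == "cat":
                out.append(f"{term[1]}[{term[2]}]")
            else:
                out.append(term[1])
        return out

    def exposure_indices(self) -> list[int]:
        exp = self.spec.exposure
        if exp == "bmi_category_fine":
            return [
                i
                for i, t in enumerate(self.columns)
                if t[0] == "cat" and t[1] == "bmi_category_fine"
            ]
        if exp == "bmi_linear_above20":
            return [i for i, t in enumerate(self.columns) if t == ("num", "bmi")]
        return []

    def encode(self, rows: pd.DataFrame, fraction_observed: float | None = 1.0) -> np.ndarray:
        """Encode new rows with this bundle's coding.

        ``fraction_observed`` replaces the observed fraction column unless
        set to None (keep the rows' own values).  Unseen category levels
        raise an error naming the level.
        """
        n = len(rows)
        X = np.empty((n, self.p))
        for j, term in enumerate(self.columns):
            if term[0] == "intercept":
                X[:, j] = 1.0
            elif term[0] == "num":
                var = term[1]
                if var == "fraction_observed" and fraction_observed is not None:
                    X[:, j] = fraction_observed
                else:
                    X[:, j] = pd.to_numeric(rows[var]).to_numpy()
            else:
                _, var, level = term
                vals = rows[var].astype(str)
                unseen = set(vals.unique()) - set(self.levels[var])
                if unseen:
                    raise DesignError(
                        f"column {var!r} contains level(s) unseen at fit time: {sorted(unseen)}"
                    )
                X[:, j] = (vals == level).to_numpy(dtype=float)
        return X


def _is_categorical(panel: pd.DataFrame, col: str) -> bool:
    if col in CONTINUOUS_ADJUSTERS:
        return False
    return not pd.api.types.is_numeric_dtype(panel[col]) or pd.api.types.is_bool_dtype(
        panel[col]
    )


def build_design(panel: pd.DataFrame, spec: ModelSpec) -> DesignBundle:
    """Build the reference-coded design matrix for a model spec.

    The exposure ``bmi_linear_above20`` implicitly restricts rows to
    BMI > 20 and enters BMI linearly.  ``fraction_observed`` enters
    untransformed as a covariate whenever listed among adjusters.
    Rank deficiency raises an error naming the offending columns.
    """
    needed = [spec.outcome, spec.cluster] + [a for a in spec.adjusters]
    if spec.exposure is not None:
        needed.append("bmi" if spec.exposure == "bmi_linear_above20" else "bmi_category_fine")
    missing = [c for c in dict.fromkeys(needed) if c not in panel.columns]
    if missing:
        raise DesignError(f"panel is missing required column(s): {missing}")

    df = panel
    if spec.subset:
        df = df.query(spec.subset)
    if spec.exposure == "bmi_linear_above20":
        df = df[df["bmi"] > 20.0]
    if len(df) == 0:
        raise DesignError(
            f"no rows left after applying subset {spec.subset!r}"
            + (" and the BMI > 20 restriction" if spec.exposure == "bmi_linear_above20" else "")
        )
    y = pd.to_numeric(df[spec.outcome]).to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise DesignError(f"outcome {spec.outcome!r} contains undefined values")
    if np.any(y < 0):
        raise DesignError(f"outcome {spec.outcome!r} contains negative values")

    columns: list = [("intercept",)]
    blocks = [np.ones((len(df), 1))]
    levels: dict = {}

    def add_categorical(var: str, reference: str | None):
        vals = df[var].astype(str)
        lev = sorted(vals.unique())
        if reference is None:
            # "missing" must never be the reference level
            non_missing = [l for l in lev if l != "missing"]
            if not non_missing:
                raise DesignError(f"column {var!r} has only missing values")
            reference = non_missing[0]
        elif reference not in lev:
            raise DesignError(
                f"reference level {reference!r} absent from column {var!r}; "
                f"observed levels: {lev}"
            )
        ordered = [reference] + [l for l in lev if l != reference]
        levels[var] = ordered
        for l in ordered[1:]:
            columns.append(("cat", var, l))
            blocks.append((vals == l).to_numpy(dtype=float)[:, None])

    if spec.exposure == "bmi_category_fine":
        add_categorical("bmi_category_fine", spec.reference)
    elif spec.exposure == "bmi_linear_above20":
        columns.append(("num", "bmi"))
        blocks.append(df["bmi"].to_numpy(dtype=float)[:, None])

    for adj in spec.adjusters:
        if _is_categorical(df, adj):
            add_categorical(adj, None)
        else:
            columns.append(("num", adj))
            blocks.append(pd.to_numeric(df[adj]).to_numpy(dtype=float)[:, None])

    X = np.hstack(blocks)
    # name collinear columns via pivoted QR
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        names = np.asarray(DesignBundle(
            y=y, X=X, columns=columns, cluster_ids=np.empty(0), row_index=np.empty(0),
            spec=spec, levels=levels,
        ).column_names())
        bad = sorted(names[piv[rank:]])
        raise DesignError(f"design matrix is rank deficient; collinear column(s): {bad}")

    return DesignBundle(
        y=y,
        X=X,
        columns=columns,
        cluster_ids=df[spec.cluster].to_numpy(),
        row_index=df.index.to_numpy(),
        spec=spec,
        levels=levels,
    )


@dataclass
class FitResult:
    """Fitted quasi-Poisson model: coefficients, covariances, dispersion."""

    beta: np.ndarray
    cov_model: np.ndarray
    cov_cluster: np.ndarray
    dispersion: float
    mu: np.ndarray
    design: DesignBundle
    iterations: int
    deviance: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.design.column_names(),
                "estimate": self.beta,
                "se_model": np.sqrt(np.diag(self.cov_model)),
                "se_cluster": np.sqrt(np.diag(self.cov_cluster)),
            }
        )

    def to_csv(self, path) -> None:
        """Write coefficients with a dispersion header block."""
        with open(path, "w") as fh:
            fh.write(f"# outcome,{self.design.spec.outcome}\n")
            fh.write(f"# dispersion,{self.dispersion:.10g}\n")
            fh.write(f"# n,{self.design.n}\n")
            self.summary_frame().to_csv(fh, index=False)


def cluster_robust_cov(
    beta: np.ndarray, design: DesignBundle, mu: np.ndarray
) -> np.ndarray:
    """Cluster-robust sandwich covariance for a fitted quasi-Poisson model.

    ``V = B^-1 (sum_g s_g s_g') B^-1`` with bread ``B = X'WX`` (W = mu for
    the log link) and cluster scores ``s_g = sum_{i in g} x_i (y_i - mu_i)``.
    No dispersion factor enters the meat; the G/(G-1) small-sample factor
    is applied.  The estimator is invariant to replicating whole clusters.
    """
    X, y, ids = design.X, design.y, design.cluster_ids
    codes, uniques = pd.factorize(ids)
    G = len(uniques)
    if G < 2:
        raise FitError("cluster-robust covariance requires at least 2 clusters")
    B = X.T @ (X * mu[:, None])
    U = X * (y - mu)[:, None]
    S = np.zeros((G, X.shape[1]))
    np.add.at(S, codes, U)
    meat = S.T @ S
    Binv = np.linalg.inv(B)
    V = Binv @ meat @ Binv * (G / (G - 1))
    return (V + V.T) / 2.0


def fit_quasipoisson(design: DesignBundle, tol: float = 1e-8, maxiter: int = 100) -> FitResult:
    """Fit the log-link quasi-Poisson model by IRLS.

    Dispersion is the Pearson X^2 over n - p.  Model-based covariance is
    ``phi * (X'WX)^-1``; the cluster-robust covariance is attached when
    the design has 2 or more clusters (else it equals the model-based
    one and working with it raises in `cluster_robust_cov`).
    """
    y, X = design.y, design.X
    if y.sum() == 0:
        raise FitError(
            "response is identically zero: the log link has no support; "
            "drop the outcome or enlarge the data"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer counts are fine for quasi-likelihood
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(tol=tol, maxiter=maxiter)
    if not res.converged:
        raise FitError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(final deviance {res.deviance:.6g})"
        )
    beta = np.asarray(res.params)
    mu = np.asarray(res.mu)
    n, p = X.shape
    if n <= p:
        raise FitError("no residual degrees of freedom to estimate dispersion")
    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / (n - p)
    cov_model = np.asarray(res.normalized_cov_params) * phi
    n_clusters = len(pd.unique(design.cluster_ids))
    if n_clusters >= 2:
        cov_cluster = cluster_robust_cov(beta, design, mu)
    else:
        cov_cluster = cov_model.copy()
    return FitResult(
        beta=beta,
        cov_model=cov_model,
        cov_cluster=cov_cluster,
        dispersion=phi,
        mu=mu,
        design=design,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        deviance=float(res.deviance),
    )


def fit_model(panel: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Convenience: build the design and fit in one step."""
    return fit_quasipoisson(build_design(panel, spec))


def predict_mean(
    fit: FitResult, rows: pd.DataFrame, fraction_observed: float | None = 1.0
) -> np.ndarray:
    """Predicted annual means ``exp(x beta)`` for new covariate rows.

    ``fraction_observed`` defaults to 1, giving annualised predictions;
    pass None to use the rows' own observed fractions.
    """
    X = fit.design.encode(rows, fraction_observed=fraction_observed)
    return np.exp(X @ fit.beta)
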