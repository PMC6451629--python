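"""Simulation configuration: the generative model for synthetic cohorts.

The synthetic cohort emulates the structure of a UK primary-care linkage
study of women aged 55-79: self-reported BMI at baseline, categorical
covariates, partial-year follow-up, overdispersed annual counts of
consultations / prescription items / tests with a log-linear BMI effect
above 20 kg/m^2, BMI-dependent incident diabetes that raises subsequent
use, and costs that are exact products of counts and unit costs.

Default parameter values are calibrated so that the generative truth
matches the headline conditions of the emulated study population: a 5.2%
(consultations) and 9.9% (prescriptions) higher annual cost per 2 kg/m^2
higher BMI above 20, reference-category annual means of 7.0 consultations
(~£288), 27.0 prescribed items (~£227) and 8.4 tests (~£53), 47% of women
below 25 kg/m^2, and excess-weight attributable proportions of ~17%
(consultation costs) and ~31% (prescription costs) under the default
population table.  See ``bmicost.truth`` for the closed-form implied
quantities.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


OUTCOMES = ["consult", "rx", "test"]

#: Therapeutic-use categories for prescription items: the 15 standard BNF
#: chapters plus analgesics, drugs in diabetes, and dressings/appliances.
RX_USE_CATEGORIES = [
    "gastro_intestinal",
    "circulatory",
    "respiratory",
    "cns",
    "infections",
    "endocrine",
    "gyn_urinary",
    "malignancy_immunosupp",
    "nutrition_blood",
    "musculoskeletal",
    "eye",
    "ear_nose_throat",
    "skin",
    "vaccines",
    "anaesthesia",
    "analgesics",
    "diabetes_drugs",
    "dressings_appliances",
]

COVARIATES = [
    "age_band",
    "region",
    "deprivation_third",
    "education",
    "smoking",
    "alcohol",
    "parity",
    "age_first_birth",
]

DEFAULT_COVARIATE_LEVELS: dict[str, list[str]] = {
    "age_band": ["55-59", "60-64", "65-69", "70-74", "75-79"],
    "region": [
        "north_east",
        "north_west",
        "yorkshire",
        "east_midlands",
        "west_midlands",
        "east",
        "london",
        "south_east",
        "south_west",
    ],
    "deprivation_third": ["least", "middle", "most"],
    "education": ["none", "secondary", "tertiary"],
    "smoking": ["never", "former", "current"],
    "alcohol": ["drinker", "non_drinker"],
    "parity": ["0", "1-2", "3+"],
    "age_first_birth": ["none", "under25", "25plus"],
}

DEFAULT_COVARIATE_PROBS: dict[str, list[float]] = {
    "age_band": [0.20, 0.26, 0.24, 0.18, 0.12],
    "region": [1 / 9] * 9,
    "deprivation_third": [0.36, 0.335, 0.305],
    "education": [0.42, 0.445, 0.135],
    "smoking": [0.524, 0.289, 0.187],
    "alcohol": [0.776, 0.224],
    "parity": [0.15, 0.55, 0.30],
    "age_first_birth": [0.15, 0.50, 0.35],
}

#: Log-scale multiplicative covariate effects on annual counts, shared
#: across outcomes.  Drawn independently of BMI by default, so they do
#: not confound the BMI association (a confounding option exists below).
DEFAULT_COVARIATE_EFFECTS: dict[str, list[float]] = {
    "age_band": [0.0, 0.08, 0.16, 0.24, 0.32],
    "region": [0.0] * 9,
    "deprivation_third": [0.0, 0.03, 0.07],
    "education": [0.0, -0.02, -0.05],
    "smoking": [0.0, 0.05, 0.10],
    "alcohol": [0.0, 0.04],
    "parity": [0.0, 0.02, 0.04],
    "age_first_birth": [0.0, 0.01, 0.02],
}

#: Baseline (non-diabetic) share of prescription items by therapeutic use.
DEFAULT_RX_SHARES = {
    "gastro_intestinal": 0.06,
    "circulatory": 0.28,
    "respiratory": 0.06,
    "cns": 0.10,
    "infections": 0.05,
    "endocrine": 0.05,
    "gyn_urinary": 0.03,
    "malignancy_immunosupp": 0.01,
    "nutrition_blood": 0.05,
    "musculoskeletal": 0.04,
    "eye": 0.03,
    "ear_nose_throat": 0.02,
    "skin": 0.04,
    "vaccines": 0.01,
    "anaesthesia": 0.005,
    "analgesics": 0.13,
    "diabetes_drugs": 0.015,
    "dressings_appliances": 0.02,
}

#: Item share by therapeutic use for person-years with diabetes: mass moves
#: into drugs in diabetes and circulatory-system medications.
DEFAULT_RX_SHARES_DIABETIC = {
    "gastro_intestinal": 0.045,
    "circulatory": 0.25,
    "respiratory": 0.04,
    "cns": 0.07,
    "infections": 0.04,
    "endocrine": 0.035,
    "gyn_urinary": 0.02,
    "malignancy_immunosupp": 0.007,
    "nutrition_blood": 0.04,
    "musculoskeletal": 0.028,
    "eye": 0.025,
    "ear_nose_throat": 0.012,
    "skin": 0.028,
    "vaccines": 0.008,
    "anaesthesia": 0.003,
    "analgesics": 0.11,
    "diabetes_drugs": 0.22,
    "dressings_appliances": 0.019,
}

#: Unit cost per prescription item (2016 GBP) by therapeutic use, scaled in
#: calibration so the item-share-weighted mean is 227/27 GBP.
DEFAULT_RX_UNIT_COSTS = {
    "gastro_intestinal": 7.9859,
    "circulatory": 6.9877,
    "respiratory": 11.9788,
    "cns": 9.9824,
    "infections": 5.9894,
    "endocrine": 9.9824,
    "gyn_urinary": 8.9842,
    "malignancy_immunosupp": 39.9294,
    "nutrition_blood": 6.9877,
    "musculoskeletal": 6.9877,
    "eye": 7.9859,
    "ear_nose_throat": 5.9894,
    "skin": 6.9877,
    "vaccines": 8.9842,
    "anaesthesia": 7.9859,
    "analgesics": 6.9877,
    "diabetes_drugs": 13.9753,
    "dressings_appliances": 9.9824,
}


@dataclass
class BMIMixture:
    """Two-component normal mixture for baseline BMI, truncated below.

    Component one is the bulk of the distribution; component two is a
    heavier upper tail.  Calibrated so ~47% of mass lies below 25 kg/m^2,
    ~36% in 25-30 and ~17% at 30+.
    """

    mean1: float = 24.064139
    sd1: float = 2.5561
    mean2: float = 28.6281
    sd2: float = 5.434
    weight2: float = 0.4145
    truncate_at: float = 18.5

    def validate(self) -> None:
        if not (0.0 <= self.weight2 <= 1.0):
            raise ConfigError("bmi_mix.weight2 must lie in [0, 1]")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ConfigError("bmi_mix standard deviations must be positive")
        if self.truncate_at < 18.5:
            raise ConfigError("bmi_mix.truncate_at must be >= 18.5")


@dataclass
class DiabetesModel:
    """Annual incident-diabetes hazard and its effect on service use.

    ``log_odds_intercept + log_odds_per_unit_bmi * bmi`` is the logit of
    the per-year probability of incident diabetes; once present, diabetes
    multiplies the annual count mean of each outcome by
    ``count_effect[outcome]`` and shifts the prescription mix towards
    drugs in diabetes.
    """

    log_odds_intercept: float = -7.6
    log_odds_per_unit_bmi: float = 0.155
    count_effect: dict = field(
        default_factory=lambda: {"consult": 1.35, "rx": 1.5, "test": 1.0}
    )

    def validate(self) -> None:
        for k, v in self.count_effect.items():
            if k not in OUTCOMES:
                raise ConfigError(f"diabetes_model.count_effect has unknown outcome {k!r}")
            if v <= 0:
                raise ConfigError("diabetes_model.count_effect values must be positive")


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_women: int = 5000
    years: int = 6
    seed: int = 0
    bmi_mix: BMIMixture = field(default_factory=BMIMixture)
    #: log-rate increase per kg/m^2 above the reference knot (21.25), per outcome
    slope_per_unit_bmi: dict = field(
        default_factory=lambda: {"consult": 0.01882, "rx": 0.03458, "test": 0.0}
    )
    #: non-diabetic, frailty-free annual count at/below the knot, per outcome
    baseline_rate: dict = field(
        default_factory=lambda: {"consult": 4.7423, "rx": 18.0484, "test": 5.828}
    )
    #: overdispersion target (variance = dispersion * mean given frailty)
    dispersion: dict = field(
        default_factory=lambda: {"consult": 1.5, "rx": 1.5, "test": 1.5}
    )
    frailty_sd: float = 0.5
    covariate_probs: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_COVARIATE_PROBS.items()})
    covariate_effects: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()})
    dropout_rate: float = 0.03
    diabetes_model: DiabetesModel = field(default_factory=DiabetesModel)
    missing_covariate_prob: float = 0.02
    #: extra log prescription rate for the 18.5-<20 band (off by default)
    underweight_rx_excess: float = 0.0
    #: strength of BMI -> deprivation dependence (0 = no confounding)
    confounding_strength: float = 0.0
    unit_cost_consult: float = 41.1432
    unit_cost_test: float = 6.3095
    rx_shares: dict = field(default_factory=lambda: dict(DEFAULT_RX_SHARES))
    rx_shares_diabetic: dict = field(default_factory=lambda: dict(DEFAULT_RX_SHARES_DIABETIC))
    rx_unit_costs: dict = field(default_factory=lambda: dict(DEFAULT_RX_UNIT_COSTS))

    def validate(self) -> None:
        if self.n_women < 1:
            raise ConfigError("n_women must be >= 1")
        if self.years < 1:
            raise ConfigError("years must be >= 1")
        self.bmi_mix.validate()
        self.diabetes_model.validate()
        for name, d in [
            ("slope_per_unit_bmi", self.slope_per_unit_bmi),
            ("baseline_rate", self.baseline_rate),
            ("dispersion", self.dispersion),
        ]:
            for out in OUTCOMES:
                if out not in d:
                    raise ConfigError(f"{name} missing outcome {out!r}")
        for out, r in self.baseline_rate.items():
            if r <= 0:
                raise ConfigError(f"baseline_rate[{out!r}] must be > 0")
        for out, phi in self.dispersion.items():
            if phi < 1:
                raise ConfigError(f"dispersion[{out!r}] must be >= 1")
        if self.frailty_sd < 0:
            raise ConfigError("frailty_sd must be >= 0")
        for p_name, p in [
            ("dropout_rate", self.dropout_rate),
            ("missing_covariate_prob", self.missing_covariate_prob),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{p_name} must lie in [0, 1]")
        for cov in COVARIATES:
            probs = self.covariate_probs.get(cov)
            effects = self.covariate_effects.get(cov)
            levels = DEFAULT_COVARIATE_LEVELS[cov]
            if probs is None or len(probs) != len(levels):
                raise ConfigError(f"covariate_probs[{cov!r}] must give {len(levels)} probabilities")
            if effects is None or len(effects) != len(levels):
                raise ConfigError(f"covariate_effects[{cov!r}] must give {len(levels)} effects")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-8:
                raise ConfigError(f"covariate_probs[{cov!r}] must be non-negative and sum to 1")
        for name, shares in [("rx_shares", self.rx_shares), ("rx_shares_diabetic", self.rx_shares_diabetic)]:
            if set(shares) != set(RX_USE_CATEGORIES):
                raise ConfigError(f"{name} must cover exactly the 18 therapeutic-use categories")
            tot = sum(shares.values())
            if any(v < 0 for v in shares.values()) or abs(tot - 1.0) > 1e-6:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if set(self.rx_unit_costs) != set(RX_USE_CATEGORIES):
            raise ConfigError("rx_unit_costs must cover exactly the 18 therapeutic-use categories")
        if any(v < 0 for v in self.rx_unit_costs.values()):
            raise ConfigError("rx_unit_costs must be non-negative")
        if self.unit_cost_consult < 0 or self.unit_cost_test < 0:
            raise ConfigError("unit costs must be non-negative")

    def with_updates(self, **kwargs) -> "SimulationConfig":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "bmi_mix" in d and isinstance(d["bmi_mix"], dict):
            d["bmi_mix"] = BMIMixture(**d["bmi_mix"])
        if "diabetes_model" in d and isinstance(d["diabetes_model"], dict):
            d["diabetes_model"] = DiabetesModel(**d["diabetes_model"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def fingerprint(self) -> str:
        """Stable digest used to check cohort/config integrity."""
        import hashlib
        import json

        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def covariate_mean_multiplier(config: SimulationConfig) -> float:
    """Population mean of the multiplicative covariate effect, exp-scale.

    Covariates are independent, so the mean multiplier factorises over
    covariates as sum_l p_l * exp(effect_l).
    """
    total = 1.0
    for cov in COVARIATES:
        p = np.asarray(config.covariate_probs[cov])
        b = np.asarray(config.covariate_effects[cov])
        total *= float(np.sum(p * np.exp(b)))
    return total
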