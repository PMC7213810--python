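"""Configuration schema and study-condition defaults.

The defaults encode the modelled scenario: a 25% ad valorem excise on
sugar-sweetened beverages (SSBs) in Zambia with 100% pass-through to retail
prices, applied to the 2015 adult population (ages 15+, 8,344,486 persons of
whom 51% are female). Beverage demand responds through a meta-analytic
own-price elasticity of -1.30 and cross-price substitution into fruit juice
(0.32) and milk (0.18); energy-intake changes are converted to steady-state
weight changes at 94 kJ/day per kg; mortality responds to the shifted BMI
distribution through potential impact fractions over eight BMI classes; and
revenue combines excise receipts with VAT changes on all three beverages.

Every number here is a configuration value, not a hard-coded constant: a
YAML or JSON file with the same structure overrides any subset of fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

Sex = Literal["female", "male"]
Beverage = Literal["ssb", "fruit_juice", "milk"]

SEXES: tuple[str, ...] = ("female", "male")
AGE_GROUPS: tuple[str, ...] = ("15-24", "25-34", "35-44", "45-54", "55-64", "65+")
BEVERAGES: tuple[str, ...] = ("ssb", "fruit_juice", "milk")

#: Single-year ages covered by each age group. The open-ended 65+ group is
#: closed at 84 so that it seeds a finite set of single-year cohorts; cohorts
#: that age past the last bound keep the 65+ mortality rate.
AGE_SPANS: Mapping[str, tuple[int, int]] = {
    "15-24": (15, 24),
    "25-34": (25, 34),
    "35-44": (35, 44),
    "45-54": (45, 54),
    "55-64": (55, 64),
    "65+": (65, 84),
}

#: Interior BMI class edges (kg/m^2). Classes are half-open [lo, hi), with the
#: first open below 18.5 and the last closed above at infinity:
#: <18.5, 18.5-20.9, 21-22.9, 23-24.9, 25-26.9, 27-29.9, 30-34.9, >=35.
BMI_CLASS_EDGES: tuple[float, ...] = (18.5, 21.0, 23.0, 25.0, 27.0, 30.0, 35.0)
BMI_CLASS_LABELS: tuple[str, ...] = (
    "<18.5", "18.5-20.9", "21-22.9", "23-24.9", "25-26.9", "27-29.9", "30-34.9", ">=35",
)

#: All-cause mortality relative risk by BMI class (reference 21-24.9).
DEFAULT_RELATIVE_RISKS: tuple[float, ...] = (1.16, 1.03, 1.00, 1.00, 1.06, 1.13, 1.13, 1.59)

OBESITY_CUTOFF = 30.0  # kg/m^2
#: Steady-state energy-balance rule: a sustained change of 94 kJ/day shifts
#: adult body weight by about 1 kg over a lifetime.
KJ_PER_KG_WEIGHT = 94.0
DAYS_PER_WEEK = 7.0
#: A 95% normal interval spans 2 x 1.96 standard errors.
CI95_WIDTH_IN_SE = 3.92

#: Weekly per-capita beverage consumption (300 mL servings) by sex and age
#: group, from the 2015 household consumption survey.
DEFAULT_WEEKLY_SERVINGS: dict[str, dict[str, dict[str, float]]] = {
    "male": {
        "15-24": {"ssb": 1.77, "fruit_juice": 1.47, "milk": 0.98},
        "25-34": {"ssb": 2.17, "fruit_juice": 1.32, "milk": 1.21},
        "35-44": {"ssb": 2.05, "fruit_juice": 1.30, "milk": 1.31},
        "45-54": {"ssb": 1.82, "fruit_juice": 1.12, "milk": 1.28},
        "55-64": {"ssb": 1.52, "fruit_juice": 1.11, "milk": 1.27},
        "65+": {"ssb": 1.21, "fruit_juice": 1.22, "milk": 1.30},
    },
    "female": {
        "15-24": {"ssb": 1.71, "fruit_juice": 0.79, "milk": 1.01},
        "25-34": {"ssb": 1.73, "fruit_juice": 1.52, "milk": 1.15},
        "35-44": {"ssb": 1.70, "fruit_juice": 1.52, "milk": 1.31},
        "45-54": {"ssb": 1.61, "fruit_juice": 1.46, "milk": 1.29},
        "55-64": {"ssb": 1.30, "fruit_juice": 1.30, "milk": 1.21},
        "65+": {"ssb": 0.93, "fruit_juice": 1.20, "milk": 1.25},
    },
}


class UncertainParam(BaseModel):
    """A scalar parameter with an optional 95% confidence interval.

    The standard error used for probabilistic draws is (ci_high - ci_low)/3.92;
    a parameter without an interval is held fixed (SE = 0).
    """

    model_config = ConfigDict(frozen=True)

    mean: float
    ci_low: float | None = None
    ci_high: float | None = None

    @model_validator(mode="after")
    def _check_interval(self) -> "UncertainParam":
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None and self.ci_high < self.ci_low:
            raise ValueError("ci_high must be >= ci_low")
        return self

    @property
    def se(self) -> float:
        if self.ci_low is None:
            return 0.0
        return (self.ci_high - self.ci_low) / CI95_WIDTH_IN_SE


class ElasticityConfig(BaseModel):
    """Own- and cross-price elasticities of beverage demand.

    The cross elasticities are with respect to the SSB price: a positive
    value means the beverage substitutes for SSBs when SSBs become dearer.
    """

    own_ssb: UncertainParam = Field(
        default_factory=lambda: UncertainParam(mean=-1.30, ci_low=-1.51, ci_high=-1.10)
    )
    cross_fruit_juice: UncertainParam = Field(
        default_factory=lambda: UncertainParam(mean=0.32, ci_low=0.01, ci_high=0.77)
    )
    cross_milk: UncertainParam = Field(
        default_factory=lambda: UncertainParam(mean=0.18, ci_low=-0.10, ci_high=0.34)
    )
    #: "linear" applies dq/q = e * dp/p; "power" applies q1 = q0 (1+dp/p)^e.
    functional_form: Literal["linear", "power"] = "linear"


class TaxScenario(BaseModel):
    """The fiscal scenario: excise, pass-through, VAT, horizon and discounting."""

    model_config = ConfigDict(frozen=True)

    tax_rate: float = Field(default=0.25, ge=0.0)
    pass_on: float = Field(default=1.00, ge=0.0)
    vat_rate: float = Field(default=0.16, ge=0.0, lt=1.0)
    horizon_years: int = Field(default=40, ge=1)
    discount_rate: float = Field(default=0.06, ge=0.0)
    fx_rate: float = Field(default=9.53, gt=0.0)  # ZMW per USD
    weeks_per_year: int = Field(default=52, ge=1)


class BeverageConfig(BaseModel):
    """Retail price and energy content of one beverage, per 300 mL serving."""

    price_per_serving: float = Field(gt=0.0)  # ZMW
    energy_per_serving: float = Field(ge=0.0)  # kJ


def _default_beverages() -> dict[str, BeverageConfig]:
    return {
        "ssb": BeverageConfig(price_per_serving=3.77, energy_per_serving=590.0),
        "fruit_juice": BeverageConfig(price_per_serving=4.93, energy_per_serving=675.0),
        "milk": BeverageConfig(price_per_serving=3.64, energy_per_serving=810.0),
    }


class PopulationConfig(BaseModel):
    """Adult population structure and beverage consumption by stratum."""

    sex_totals: dict[Sex, float] = Field(
        default_factory=lambda: {"female": 4_271_631.0, "male": 4_072_855.0}
    )
    #: Share of each sex's population in the six age groups (young-skewed,
    #: matching a high-fertility age pyramid); must sum to 1.
    age_shares: tuple[float, float, float, float, float, float] = (
        0.35, 0.25, 0.16, 0.11, 0.07, 0.06,
    )
    weekly_servings: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_WEEKLY_SERVINGS))
    )
    #: Fraction of the population that consumes SSBs at all; scales the
    #: revenue base but not per-capita health effects.
    consumer_share: float = Field(default=0.13, ge=0.0, le=1.0)
    #: Whether the consumer base multiplies the adult or the total population.
    consumer_base: Literal["adult", "total"] = "adult"
    total_population: float = Field(default=15_473_905.0, gt=0.0)
    reference_year: int = 2015

    @field_validator("sex_totals")
    @classmethod
    def _totals_complete(cls, v: dict) -> dict:
        for sex in SEXES:
            if sex not in v:
                raise ValueError(f"sex_totals missing entry for '{sex}'")
            if v[sex] < 0:
                raise ValueError(f"sex_totals['{sex}'] must be >= 0")
        return v

    @field_validator("age_shares")
    @classmethod
    def _shares_valid(cls, v: tuple) -> tuple:
        if any(s < 0 for s in v):
            raise ValueError("age_shares must be non-negative")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"age_shares must sum to 1, got {sum(v)!r}")
        return v

    @field_validator("weekly_servings")
    @classmethod
    def _servings_complete(cls, v: dict) -> dict:
        for sex in SEXES:
            for age in AGE_GROUPS:
                for bev in BEVERAGES:
                    try:
                        val = v[sex][age][bev]
                    except KeyError as exc:
                        raise ValueError(
                            f"weekly_servings missing stratum ({sex}, {age}, {bev})"
                        ) from exc
                    if not (val >= 0.0):  # also rejects NaN
                        raise ValueError(
                            f"weekly_servings[{sex}][{age}][{bev}] must be finite and >= 0"
                        )
        return v


class BmiTarget(BaseModel):
    mean_bmi: float = Field(gt=10.0, lt=70.0)
    obesity_prevalence: float = Field(ge=0.0, lt=1.0)


class HeightConfig(BaseModel):
    mean_m: float = Field(gt=1.2, lt=2.2)
    sd_m: float = Field(default=0.07, ge=0.0)


class BmiConfig(BaseModel):
    """Per-sex calibration targets for the baseline BMI distribution.

    Each sex's distribution is a two-parameter log-normal exactly identified
    by the mean BMI and the obesity prevalence (fraction with BMI >= 30).
    """

    family: Literal["lognormal"] = "lognormal"
    targets: dict[Sex, BmiTarget] = Field(
        default_factory=lambda: {
            "female": BmiTarget(mean_bmi=24.3, obesity_prevalence=0.135),
            "male": BmiTarget(mean_bmi=22.5, obesity_prevalence=0.0399),
        }
    )
    heights: dict[Sex, HeightConfig] = Field(
        default_factory=lambda: {
            "female": HeightConfig(mean_m=1.59, sd_m=0.07),
            "male": HeightConfig(mean_m=1.68, sd_m=0.07),
        }
    )


class MortalityConfig(BaseModel):
    """Age-specific all-cause mortality schedule.

    Group-level rates follow a Gompertz curve exp(slope * age) evaluated at
    each group's midpoint and rescaled so that the population-weighted mean
    annual rate equals ``mean_annual_rate``.
    """

    mean_annual_rate: float = Field(default=0.0085, gt=0.0, lt=1.0)
    gompertz_slope: float = Field(default=0.09, gt=0.0)


class RrConfig(BaseModel):
    """Relative risks of all-cause mortality by BMI class."""

    relative_risks: tuple[float, ...] = DEFAULT_RELATIVE_RISKS
    #: Optional per-sex overrides, same length as relative_risks.
    per_sex: dict[Sex, tuple[float, ...]] | None = None
    #: Coefficient of variation of the mean-one log-normal multipliers applied
    #: to each class in probabilistic draws (0 = relative risks held fixed).
    cv: float = Field(default=0.0, ge=0.0)

    @field_validator("relative_risks")
    @classmethod
    def _positive(cls, v: tuple) -> tuple:
        if len(v) != len(BMI_CLASS_LABELS):
            raise ValueError(f"need {len(BMI_CLASS_LABELS)} relative risks")
        if any(x <= 0 for x in v):
            raise ValueError("relative risks must be > 0")
        return v


class UncertaintyConfig(BaseModel):
    """Monte Carlo settings for the probabilistic sensitivity analysis."""

    n_draws: int = Field(default=500, ge=1)
    #: Percentile band reported around the Monte Carlo mean. The study design
    #: labels the 5th/95th percentiles as its confidence band; (2.5, 97.5) is
    #: the usual 95% alternative.
    percentiles: tuple[float, float] = (5.0, 95.0)
    vary_elasticities: bool = True
    vary_pass_on: bool = True
    #: 95% interval for the pass-on rate when varied.
    pass_on_ci: tuple[float, float] = (0.80, 1.20)

    @field_validator("percentiles")
    @classmethod
    def _ordered(cls, v: tuple) -> tuple:
        lo, hi = v
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        return v


class RunConfig(BaseModel):
    """Complete, validated configuration for one model run."""

    population: PopulationConfig = Field(default_factory=PopulationConfig)
    scenario: TaxScenario = Field(default_factory=TaxScenario)
    elasticities: ElasticityConfig = Field(default_factory=ElasticityConfig)
    beverages: dict[Beverage, BeverageConfig] = Field(default_factory=_default_beverages)
    bmi: BmiConfig = Field(default_factory=BmiConfig)
    mortality: MortalityConfig = Field(default_factory=MortalityConfig)
    rr: RrConfig = Field(default_factory=RrConfig)
    uncertainty: UncertaintyConfig = Field(default_factory=UncertaintyConfig)
    #: Individuals sampled per stratum for the BMI microsimulation
    #: (12 strata -> ~1e5 individuals per sex at the default).
    n_per_stratum: int = Field(default=17_000, ge=100)
    #: Credit decedents half a person-year in their year of death.
    half_cycle_correction: bool = True
    #: If true, VAT on SSBs is levied on the excise-inclusive price
    #: (cascading); the default keeps the VAT base at the pre-excise price.
    vat_on_excise: bool = False

    @field_validator("beverages")
    @classmethod
    def _beverages_complete(cls, v: dict) -> dict:
        for bev in BEVERAGES:
            if bev not in v:
                raise ValueError(f"beverages missing profile for '{bev}'")
        return v

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for provenance stamping."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a configuration from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)
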