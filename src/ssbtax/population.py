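"""Synthetic baseline population: strata, consumption, BMI and mortality.

Builds the 12-stratum (2 sexes x 6 age groups) adult population with stratum
counts, weekly beverage consumption, an age-specific mortality schedule, and
per-sex baseline BMI distributions calibrated to the survey summaries (mean
BMI 24.3 kg/m^2 and 13.5% obesity for women; 22.5 kg/m^2 and 3.99% for men).

The BMI distribution is a two-parameter log-normal per sex: positive support
and right skew match adult BMI data, and the family is exactly identified by
the two published moments (mean and tail mass above 30 kg/m^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    AGE_GROUPS,
    AGE_SPANS,
    BEVERAGES,
    OBESITY_CUTOFF,
    SEXES,
    RunConfig,
)

__all__ = [
    "CalibrationError",
    "Stratum",
    "PopulationTable",
    "BmiSample",
    "fit_lognormal_bmi",
    "build_population",
    "sample_bmi_heights",
    "allocate_consumption",
    "load_fixture",
]

#: Canonical stratum ordering used by every array in the package.
STRATA_KEYS: tuple[tuple[str, str], ...] = tuple(
    (sex, age) for sex in SEXES for age in AGE_GROUPS
)

_HEIGHT_LO, _HEIGHT_HI = 1.2, 2.2
_BMI_LO, _BMI_HI = 10.0, 70.0


class CalibrationError(ValueError):
    """Raised when a BMI distribution cannot match its calibration targets."""


@dataclass(frozen=True)
class Stratum:
    """One sex x age-group cell of the adult population."""

    sex: str
    age_group: str
    count: float
    weekly_servings: Mapping[str, float]  # beverage -> 300 mL servings/week
    mortality_rate: float  # annual deaths per person, each single year of age
    mean_height_m: float
    bmi_dist: Mapping[str, float]  # {"family", "mu", "sigma"} on the log scale

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0 for stratum ({self.sex}, {self.age_group})")
        if not (0.0 < self.mortality_rate < 1.0):
            raise ValueError(
                f"mortality_rate must lie in (0, 1) for ({self.sex}, {self.age_group}); "
                f"got {self.mortality_rate}"
            )
        for bev, q in self.weekly_servings.items():
            if not np.isfinite(q) or q < 0:
                raise ValueError(f"weekly_servings[{bev}] invalid for ({self.sex}, {self.age_group})")


@dataclass
class PopulationTable:
    """The 12 strata plus population-level attributes."""

    strata: list[Stratum]
    consumer_share: float
    reference_year: int

    def __post_init__(self) -> None:
        keys = [(s.sex, s.age_group) for s in self.strata]
        if keys != list(STRATA_KEYS):
            raise ValueError("strata must contain all 12 (sex, age_group) cells in canonical order")
        if not (0.0 <= self.consumer_share <= 1.0):
            raise ValueError("consumer_share must lie in [0, 1]")

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.count for s in self.strata])

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    def sex_count(self, sex: str) -> float:
        return float(sum(s.count for s in self.strata if s.sex == sex))

    def stratum(self, sex: str, age_group: str) -> Stratum:
        return self.strata[STRATA_KEYS.index((sex, age_group))]

    def weighted_mean_servings(self, beverage: str) -> float:
        """Population-weighted mean weekly servings of one beverage."""
        w = self.counts
        q = np.array([s.weekly_servings[beverage] for s in self.strata])
        return float((w * q).sum() / w.sum())

    def mortality_rates(self, sex: str) -> np.ndarray:
        return np.array([self.stratum(sex, a).mortality_rate for a in AGE_GROUPS])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            row = {
                "sex": s.sex,
                "age_group": s.age_group,
                "count": s.count,
                "mortality_rate": s.mortality_rate,
                "mean_height_m": s.mean_height_m,
            }
            row.update({f"weekly_{b}": s.weekly_servings[b] for b in BEVERAGES})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class BmiSample:
    """Per-stratum individual BMI values and heights, reproducible by seed."""

    bmi: dict[tuple[str, str], np.ndarray]
    height: dict[tuple[str, str], np.ndarray]
    seed: int
    n_per_stratum: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.n_per_stratum:
            self.n_per_stratum = len(next(iter(self.bmi.values())))


def fit_lognormal_bmi(
    mean_bmi: float, obesity_prevalence: float, cutoff: float = OBESITY_CUTOFF
) -> tuple[float, float]:
    """Fit a log-normal to a target mean and tail mass above ``cutoff``.

    Solves for (mu, sigma) such that exp(mu + sigma^2/2) = mean_bmi and
    P(X >= cutoff) = obesity_prevalence. The two moment equations reduce to a
    quadratic in sigma: sigma^2/2 - z*sigma + (ln cutoff - ln mean) = 0 with
    z the standard-normal quantile of 1 - prevalence; the smaller root keeps
    the distribution unimodal near the mean.

    A zero prevalence is honoured as the degenerate distribution at the mean
    (sigma = 0). Raises :class:`CalibrationError` when no real solution
    exists (prevalence too large for the requested mean).
    """
    if not (0.0 <= obesity_prevalence < 1.0):
        raise CalibrationError(f"obesity prevalence must lie in [0, 1); got {obesity_prevalence}")
    if mean_bmi >= cutoff:
        raise CalibrationError(f"mean BMI {mean_bmi} must lie below the cutoff {cutoff}")
    if obesity_prevalence == 0.0:
        return math.log(mean_bmi), 0.0

    z = float(stats.norm.ppf(1.0 - obesity_prevalence))
    c = math.log(cutoff) - math.log(mean_bmi)
    disc = z * z - 2.0 * c
    if disc < 0.0 or z <= 0.0:
        raise CalibrationError(
            "log-normal cannot reach the requested calibration: "
            f"mean={mean_bmi}, P(BMI>={cutoff})={obesity_prevalence} "
            f"(quantile z={z:.4f}, discriminant={disc:.4f})"
        )
    sigma = z - math.sqrt(disc)
    mu = math.log(cutoff) - z * sigma
    return mu, sigma


def _mortality_schedule(cfg: RunConfig, counts_by_age: np.ndarray) -> np.ndarray:
    """Group-level annual mortality rates, Gompertz-shaped and calibrated.

    ``counts_by_age`` holds the six age-group counts pooled over sex; the
    returned rates satisfy sum(w * m) / sum(w) == cfg.mortality.mean_annual_rate.
    """
    mids = np.array([(lo + hi + 1) / 2.0 for lo, hi in (AGE_SPANS[a] for a in AGE_GROUPS)])
    raw = np.exp(cfg.mortality.gompertz_slope * mids)
    w = counts_by_age / counts_by_age.sum()
    scale = cfg.mortality.mean_annual_rate / float((w * raw).sum())
    rates = scale * raw
    if rates.max() >= 1.0:
        raise ValueError(
            f"calibrated mortality schedule leaves the unit interval (max {rates.max():.4f}); "
            "lower mean_annual_rate or gompertz_slope"
        )
    return rates


def build_population(config: RunConfig) -> PopulationTable:
    """Assemble the 12-stratum population from a validated configuration.

    Stratum counts are sex totals split by the configured age shares; weekly
    consumption is taken from the configured per-stratum table; mortality and
    BMI-distribution parameters are derived as documented on their configs.
    """
    pcfg = config.population
    shares = np.asarray(pcfg.age_shares)
    counts = {
        sex: pcfg.sex_totals[sex] * shares for sex in SEXES
    }
    counts_by_age = sum(counts[sex] for sex in SEXES)
    rates = _mortality_schedule(config, counts_by_age)

    bmi_params = {}
    for sex in SEXES:
        t = config.bmi.targets[sex]
        mu, sigma = fit_lognormal_bmi(t.mean_bmi, t.obesity_prevalence)
        bmi_params[sex] = {"family": "lognormal", "mu": mu, "sigma": sigma}

    strata = []
    for sex in SEXES:
        for i, age in enumerate(AGE_GROUPS):
            servings = dict(pcfg.weekly_servings[sex][age])
            strata.append(
                Stratum(
                    sex=sex,
                    age_group=age,
                    count=float(counts[sex][i]),
                    weekly_servings=servings,
                    mortality_rate=float(rates[i]),
                    mean_height_m=config.bmi.heights[sex].mean_m,
                    bmi_dist=bmi_params[sex],
                )
            )
    return PopulationTable(
        strata=strata,
        consumer_share=pcfg.consumer_share,
        reference_year=pcfg.reference_year,
    )


def sample_bmi_heights(
    population: PopulationTable,
    n_per_stratum: int,
    seed: int,
    height_sd: Mapping[str, float] | None = None,
) -> BmiSample:
    """Draw individual BMI values and heights for every stratum.

    Each stratum gets an independent substream spawned from ``seed``, so the
    sample is bit-reproducible and insensitive to stratum evaluation order.
    Heights are normal around the stratum mean (default sd 0.07 m), truncated
    to the physiological range (1.2, 2.2) m; BMI draws are clipped to
    (10, 70) kg/m^2 (the clipped mass is negligible at the calibrated
    parameters).
    """
    if n_per_stratum < 100:
        raise ValueError("n_per_stratum must be >= 100 for stable calibration")
    sd = dict(height_sd) if height_sd else {sex: 0.07 for sex in SEXES}

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(population.strata))
    bmi: dict[tuple[str, str], np.ndarray] = {}
    height: dict[tuple[str, str], np.ndarray] = {}
    for s, child in zip(population.strata, children):
        rng = np.random.default_rng(child)
        mu, sigma = s.bmi_dist["mu"], s.bmi_dist["sigma"]
        if sigma == 0.0:
            b = np.full(n_per_stratum, math.exp(mu))
        else:
            b = rng.lognormal(mean=mu, sigma=sigma, size=n_per_stratum)
        h = rng.normal(loc=s.mean_height_m, scale=sd[s.sex], size=n_per_stratum)
        bmi[(s.sex, s.age_group)] = np.clip(b, _BMI_LO + 1e-9, _BMI_HI - 1e-9)
        height[(s.sex, s.age_group)] = np.clip(h, _HEIGHT_LO + 1e-9, _HEIGHT_HI - 1e-9)
    return BmiSample(bmi=bmi, height=height, seed=seed, n_per_stratum=n_per_stratum)


def achieved_bmi_moments(
    population: PopulationTable, sample: BmiSample
) -> pd.DataFrame:
    """Count-weighted per-sex sample mean BMI and obesity prevalence."""
    rows = []
    for sex in SEXES:
        w, means, prevs = [], [], []
        for age in AGE_GROUPS:
            arr = sample.bmi[(sex, age)]
            w.append(population.stratum(sex, age).count)
            means.append(arr.mean())
            prevs.append(float((arr >= OBESITY_CUTOFF).mean()))
        w = np.asarray(w) / np.sum(w)
        rows.append(
            {
                "sex": sex,
                "mean_bmi": float(np.dot(w, means)),
                "obesity_prevalence": float(np.dot(w, prevs)),
            }
        )
    return pd.DataFrame(rows).set_index("sex")


def allocate_consumption(
    per_capita_weekly: float,
    allocation_shares: Sequence[float],
    counts: Sequence[float],
) -> np.ndarray:
    """Allocate a per-capita mean across strata according to share weights.

    The allocated values are proportional to the shares and rescaled so the
    count-weighted mean reproduces ``per_capita_weekly`` exactly
    (conservation of total consumption).
    """
    shares = np.asarray(allocation_shares, dtype=float)
    w = np.asarray(counts, dtype=float)
    if shares.shape != w.shape:
        raise ValueError("allocation_shares and counts must have equal length")
    if (shares < 0).any():
        raise ValueError("allocation_shares must be non-negative")
    denom = float((shares * w).sum())
    if denom == 0.0:
        raise ValueError("allocation_shares are all zero for populated strata")
    return per_capita_weekly * shares * w.sum() / denom


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged summary-table fixtures (``table1``/``table2``)."""
    path = resources.files("ssbtax").joinpath(f"data/{name}.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)
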