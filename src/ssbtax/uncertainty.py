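"""Probabilistic (Monte Carlo) and deterministic sensitivity analysis.

The probabilistic analysis redraws the uncertain parameters - the three
demand elasticities, the pass-on rate and (optionally) mean-one multipliers
on the relative risks - from normal distributions via inverse-CDF sampling,
re-runs the full pipeline per draw, and summarises each outcome by its mean
and a percentile band (default 5th/95th). Standard errors come from the 95%
intervals as width / 3.92; parameters without published intervals are held
fixed. Draws are indexed substreams of the run seed, so any single draw can
be reproduced in isolation, and the baseline BMI sample and life table are
shared across draws (common random numbers), making per-draw health effects
pure parameter contrasts.

The deterministic analysis re-runs the pipeline at mean parameters over
one-way or two-way grids of the tax and pass-on rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .demand import ElasticityValues
from .lifetable import RrSchedule, run_life_table
from .pipeline import evaluate_scenario
from .population import BmiSample, PopulationTable, build_population, sample_bmi_heights

__all__ = [
    "ParameterDraw",
    "UncertaintyResult",
    "draw_parameters",
    "run_monte_carlo",
    "one_way_grid",
    "two_way_grid",
]


@dataclass(frozen=True)
class ParameterDraw:
    """One realisation of the uncertain parameters."""

    own_ssb: float
    cross_fruit_juice: float
    cross_milk: float
    pass_on: float
    rr_multipliers: tuple[float, ...]
    index: int
    seed: int

    @property
    def elasticities(self) -> ElasticityValues:
        return ElasticityValues(
            own_ssb=self.own_ssb,
            cross_fruit_juice=self.cross_fruit_juice,
            cross_milk=self.cross_milk,
        )


def _inverse_normal(rng: np.random.Generator, mean: float, se: float) -> float:
    """Inverse-CDF normal draw; degenerate at the mean when SE is zero."""
    u = rng.random()
    if se == 0.0:
        return mean
    return float(stats.norm.ppf(u, loc=mean, scale=se))


def draw_parameters(cfg: RunConfig, seed: int, index: int) -> ParameterDraw:
    """Draw one parameter set, reproducible from (seed, index) alone."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
    e = cfg.elasticities
    u = cfg.uncertainty
    vary = u.vary_elasticities
    own = _inverse_normal(rng, e.own_ssb.mean, e.own_ssb.se if vary else 0.0)
    juice = _inverse_normal(
        rng, e.cross_fruit_juice.mean, e.cross_fruit_juice.se if vary else 0.0
    )
    milk = _inverse_normal(rng, e.cross_milk.mean, e.cross_milk.se if vary else 0.0)

    pass_se = 0.0
    if u.vary_pass_on:
        lo, hi = u.pass_on_ci
        pass_se = (hi - lo) / 3.92
    pass_on = _inverse_normal(rng, cfg.scenario.pass_on, pass_se)
    pass_on = max(pass_on, 0.0)

    n_classes = len(cfg.rr.relative_risks)
    if cfg.rr.cv > 0.0:
        # Mean-one log-normal multipliers with coefficient of variation cv.
        sigma = float(np.sqrt(np.log1p(cfg.rr.cv**2)))
        us = rng.random(n_classes)
        mults = tuple(
            float(np.exp(stats.norm.ppf(x) * sigma - sigma**2 / 2.0)) for x in us
        )
    else:
        rng.random(n_classes)  # keep the stream aligned across configs
        mults = tuple(1.0 for _ in range(n_classes))
    return ParameterDraw(
        own_ssb=own,
        cross_fruit_juice=juice,
        cross_milk=milk,
        pass_on=pass_on,
        rr_multipliers=mults,
        index=index,
        seed=seed,
    )


@dataclass
class UncertaintyResult:
    """Per-draw outcome values plus mean and percentile-band summaries."""

    draws: pd.DataFrame  # index: draw; columns: outcomes
    summary: pd.DataFrame  # index: outcome; columns: mean, lower, upper
    percentiles: tuple[float, float]
    n_draws: int
    seed: int


def run_monte_carlo(
    cfg: RunConfig,
    n_draws: int | None = None,
    seed: int = 0,
    population: PopulationTable | None = None,
    sample: BmiSample | None = None,
) -> UncertaintyResult:
    """Repeat the full pipeline over parameter draws and summarise.

    The baseline population, BMI sample and baseline life table are built
    once and reused across draws; only the drawn parameters vary.
    """
    n = n_draws if n_draws is not None else cfg.uncertainty.n_draws
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    if population is None:
        population = build_population(cfg)
    if sample is None:
        sample = sample_bmi_heights(
            population, cfg.n_per_stratum, seed,
            height_sd={s: cfg.bmi.heights[s].sd_m for s in cfg.bmi.heights},
        )
    lt_baseline = run_life_table(
        population, cfg.scenario.horizon_years, cfg.scenario.discount_rate,
        half_cycle=cfg.half_cycle_correction, collect_trace=False,
    )

    records = []
    for i in range(n):
        d = draw_parameters(cfg, seed, i)
        rr = RrSchedule.from_config(cfg.rr, multipliers=np.asarray(d.rr_multipliers))
        res = evaluate_scenario(
            population, sample, cfg,
            pass_on=d.pass_on,
            elasticities=d.elasticities,
            rr=rr,
            lt_baseline=lt_baseline,
            collect_trace=False,
        )
        records.append(res.outcomes)
    draws = pd.DataFrame.from_records(records)
    draws.index.name = "draw"

    lo, hi = cfg.uncertainty.percentiles
    summary = pd.DataFrame(
        {
            "mean": draws.mean(),
            "lower": draws.quantile(lo / 100.0),
            "upper": draws.quantile(hi / 100.0),
        }
    )
    summary.index.name = "outcome"
    return UncertaintyResult(
        draws=draws, summary=summary, percentiles=(lo, hi), n_draws=n, seed=seed
    )


def _grid_eval(
    cfg: RunConfig,
    pairs: Sequence[tuple[float, float]],
    seed: int,
    population: PopulationTable | None,
    sample: BmiSample | None,
) -> pd.DataFrame:
    if population is None:
        population = build_population(cfg)
    if sample is None:
        sample = sample_bmi_heights(
            population, cfg.n_per_stratum, seed,
            height_sd={s: cfg.bmi.heights[s].sd_m for s in cfg.bmi.heights},
        )
    lt_baseline = run_life_table(
        population, cfg.scenario.horizon_years, cfg.scenario.discount_rate,
        half_cycle=cfg.half_cycle_correction, collect_trace=False,
    )
    rows = []
    for tax, pas in pairs:
        res = evaluate_scenario(
            population, sample, cfg,
            tax_rate=tax, pass_on=pas,
            lt_baseline=lt_baseline, collect_trace=False,
        )
        rows.append({"tax_rate": tax, "pass_on": pas, **res.outcomes})
    return pd.DataFrame(rows)


def one_way_grid(
    cfg: RunConfig,
    parameter: str,
    values: Sequence[float],
    seed: int = 0,
    population: PopulationTable | None = None,
    sample: BmiSample | None = None,
) -> pd.DataFrame:
    """Deterministic sensitivity run varying one parameter at mean values."""
    values = list(values)
    if not values:
        raise ValueError("empty sensitivity grid")
    if parameter == "tax_rate":
        pairs = [(v, cfg.scenario.pass_on) for v in values]
    elif parameter == "pass_on":
        pairs = [(cfg.scenario.tax_rate, v) for v in values]
    else:
        raise ValueError(f"unknown grid parameter '{parameter}'")
    return _grid_eval(cfg, pairs, seed, population, sample)


def two_way_grid(
    cfg: RunConfig,
    tax_values: Sequence[float],
    pass_on_values: Sequence[float],
    seed: int = 0,
    population: PopulationTable | None = None,
    sample: BmiSample | None = None,
) -> pd.DataFrame:
    """Deterministic sensitivity run over the tax x pass-on cross product."""
    tax_values, pass_on_values = list(tax_values), list(pass_on_values)
    if not tax_values or not pass_on_values:
        raise ValueError("empty sensitivity grid")
    pairs = [(t, p) for t in tax_values for p in pass_on_values]
    return _grid_eval(cfg, pairs, seed, population, sample)
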