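"""End-to-end orchestration: population -> demand -> energy/BMI -> life table -> revenue.

:func:`evaluate_scenario` runs the four modelling steps once at a given
parameter point and returns every intermediate object plus a flat dictionary
of headline outcomes; it is the unit of work the Monte Carlo and the
sensitivity grids repeat. :func:`run_pipeline` wraps it with configuration
loading, seeding, optional uncertainty propagation and report writing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import BEVERAGES, RunConfig, SEXES, AGE_GROUPS
from .demand import ConsumptionDelta, ElasticityValues, apply_tax_scenario, price_after_tax
from .energy import BmiShiftResult, energy_delta, shift_bmi, weight_delta
from .lifetable import (
    HealthOutcomes,
    LifeTableResult,
    RrSchedule,
    health_outcomes,
    pif,
    run_life_table,
)
from .population import BmiSample, PopulationTable, build_population, sample_bmi_heights
from .revenue import RevenueLedger, compute_revenue

__all__ = ["ScenarioResult", "ResultBundle", "evaluate_scenario", "run_pipeline", "write_reports"]


@dataclass
class ScenarioResult:
    """All intermediates and outcomes of one deterministic model evaluation."""

    outcomes: dict[str, float]
    consumption: ConsumptionDelta
    energy: pd.Series
    bmi_shift: BmiShiftResult
    pif_by_stratum: dict[tuple[str, str], float]
    lt_baseline: LifeTableResult
    lt_intervention: LifeTableResult
    health: HealthOutcomes
    revenue: RevenueLedger
    tax_rate: float
    pass_on: float


def evaluate_scenario(
    population: PopulationTable,
    sample: BmiSample,
    cfg: RunConfig,
    *,
    tax_rate: float | None = None,
    pass_on: float | None = None,
    elasticities: ElasticityValues | None = None,
    rr: RrSchedule | None = None,
    lt_baseline: LifeTableResult | None = None,
    collect_trace: bool = True,
) -> ScenarioResult:
    """Run the model once at a single parameter point.

    Keyword overrides replace the corresponding configured means; the
    baseline life table (which does not depend on the tax parameters) may be
    passed in to avoid recomputation across repeated evaluations.
    """
    scenario = cfg.scenario
    if tax_rate is not None or pass_on is not None:
        scenario = scenario.model_copy(
            update={
                **({"tax_rate": tax_rate} if tax_rate is not None else {}),
                **({"pass_on": pass_on} if pass_on is not None else {}),
            }
        )
    if elasticities is None:
        elasticities = ElasticityValues.from_config(cfg.elasticities)
    if rr is None:
        rr = RrSchedule.from_config(cfg.rr)

    # Step 1-2: price pass-through and demand response.
    price = price_after_tax(
        cfg.beverages["ssb"].price_per_serving, scenario.tax_rate, scenario.pass_on
    )
    delta = apply_tax_scenario(
        population, scenario, elasticities, cfg.beverages,
        functional_form=cfg.elasticities.functional_form,
    )

    # Step 3: energy intake, weight, BMI distribution.
    energy = energy_delta(delta, cfg.beverages)
    dkg = weight_delta(energy)
    bmi_shift = shift_bmi(sample, dkg.to_dict(), population)

    # Step 4: PIF-adjusted mortality and the cohort life tables.
    pifs: dict[tuple[str, str], float] = {}
    for key in bmi_shift.probs_before:
        sex, _ = key
        p0, p1 = bmi_shift.probs_before[key], bmi_shift.probs_after[key]
        if np.array_equal(p0, p1):
            pifs[key] = 0.0
        else:
            pifs[key] = pif(p0, p1, rr.for_sex(sex))

    if lt_baseline is None:
        lt_baseline = run_life_table(
            population, scenario.horizon_years, scenario.discount_rate,
            pif_by_stratum=None, half_cycle=cfg.half_cycle_correction,
            collect_trace=collect_trace,
        )
    lt_int = run_life_table(
        population, scenario.horizon_years, scenario.discount_rate,
        pif_by_stratum=pifs, half_cycle=cfg.half_cycle_correction,
        collect_trace=collect_trace,
    )
    health = health_outcomes(lt_baseline, lt_int)

    # Revenue, annualised at the post-tax steady state.
    ledger = compute_revenue(
        population, scenario, delta, cfg.beverages,
        base=cfg.population.consumer_base,
        total_population=cfg.population.total_population,
        vat_on_excise=cfg.vat_on_excise,
    )

    # Count-weighted per-capita PIF by sex (equity summary).
    pif_by_sex = {}
    for sex in SEXES:
        w = np.array([population.stratum(sex, a).count for a in AGE_GROUPS])
        vals = np.array([pifs[(sex, a)] for a in AGE_GROUPS])
        pif_by_sex[sex] = float((w * vals).sum() / w.sum())

    outcomes = {
        "price_increase_zmw": price.increase,
        "ssb_reduction_servings_week": -delta.weighted_mean(population, "ssb"),
        "fruit_juice_change_servings_week": delta.weighted_mean(population, "fruit_juice"),
        "milk_change_servings_week": delta.weighted_mean(population, "milk"),
        "energy_reduction_kj_day": -float(
            (energy.to_numpy() * population.counts).sum() / population.total_count
        ),
        "bmi_reduction": -bmi_shift.mean_dbmi,
        "obesity_reduction_pp": -bmi_shift.obesity_change_pp,
        "pif_female": pif_by_sex["female"],
        "pif_male": pif_by_sex["male"],
        "deaths_averted_female": health.deaths_averted["female"],
        "deaths_averted_male": health.deaths_averted["male"],
        "deaths_averted_total": health.deaths_averted["total"],
        "life_years_gained_female": health.life_years_gained["female"],
        "life_years_gained_male": health.life_years_gained["male"],
        "life_years_gained_total": health.life_years_gained["total"],
        "excise_revenue_usd_m": ledger.excise_usd_m,
        "vat_change_usd_m": ledger.vat_usd_m,
        "total_revenue_usd_m": ledger.total_usd_m,
    }
    return ScenarioResult(
        outcomes=outcomes,
        consumption=delta,
        energy=energy,
        bmi_shift=bmi_shift,
        pif_by_stratum=pifs,
        lt_baseline=lt_baseline,
        lt_intervention=lt_int,
        health=health,
        revenue=ledger,
        tax_rate=scenario.tax_rate,
        pass_on=scenario.pass_on,
    )


@dataclass
class ResultBundle:
    """A complete run: the mean-parameter result, optional uncertainty, provenance."""

    scenario_result: ScenarioResult
    uncertainty: "object | None"  # UncertaintyResult, typed loosely to avoid a cycle
    provenance: dict[str, object]
    population: PopulationTable


def run_pipeline(
    cfg: RunConfig,
    seed: int,
    outdir: str | Path | None = None,
    with_uncertainty: bool = False,
    n_draws: int | None = None,
) -> ResultBundle:
    """Execute the full pipeline from a validated configuration.

    The seed controls the BMI microsimulation sample and, when uncertainty
    propagation is enabled, every parameter draw; identical (config, seed)
    pairs reproduce every output byte.
    """
    population = build_population(cfg)
    sample = sample_bmi_heights(
        population, cfg.n_per_stratum, seed,
        height_sd={s: cfg.bmi.heights[s].sd_m for s in SEXES},
    )
    result = evaluate_scenario(population, sample, cfg)

    uncertainty = None
    if with_uncertainty:
        from .uncertainty import run_monte_carlo

        uncertainty = run_monte_carlo(
            cfg, n_draws=n_draws, seed=seed, population=population, sample=sample
        )

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": int(seed),
        "version": __version__,
    }
    bundle = ResultBundle(
        scenario_result=result,
        uncertainty=uncertainty,
        provenance=provenance,
        population=population,
    )
    if outdir is not None:
        write_reports(bundle, outdir)
    return bundle


def _write_csv(df: pd.DataFrame, path: Path, provenance: Mapping[str, object]) -> None:
    header = f"# ssbtax config={provenance['config_hash']} seed={provenance['seed']}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_reports(bundle: ResultBundle, outdir: str | Path) -> list[Path]:
    """Write CSV tables and the summary JSON for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = bundle.provenance
    res = bundle.scenario_result
    written = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        _write_csv(df, path, prov)
        written.append(path)

    emit(res.consumption.frame, "consumption.csv")

    per_stratum = res.bmi_shift.per_stratum.copy()
    per_stratum.insert(2, "energy_kj_day", res.energy.to_numpy())
    per_stratum["pif"] = [
        res.pif_by_stratum[(r.sex, r.age_group)] for r in per_stratum.itertuples()
    ]
    emit(per_stratum, "energy_bmi.csv")

    if res.lt_baseline.by_cycle is not None:
        emit(res.lt_baseline.by_cycle, "lifetable_baseline.csv")
        emit(res.lt_intervention.by_cycle, "lifetable_intervention.csv")

    rows = []
    for name, mean_val in (
        ("excise", res.revenue.excise_usd_m),
        ("vat", res.revenue.vat_usd_m),
        ("total", res.revenue.total_usd_m),
    ):
        row = {"component": name, "mean_usd_m": mean_val, "lower": None, "upper": None}
        if bundle.uncertainty is not None:
            key = {"excise": "excise_revenue_usd_m", "vat": "vat_change_usd_m",
                   "total": "total_revenue_usd_m"}[name]
            summ = bundle.uncertainty.summary.loc[key]
            row.update(mean_usd_m=summ["mean"], lower=summ["lower"], upper=summ["upper"])
        rows.append(row)
    emit(pd.DataFrame(rows), "table5.csv")

    if bundle.uncertainty is not None:
        emit(bundle.uncertainty.draws.reset_index(), "mc_draws.csv")
        emit(bundle.uncertainty.summary.reset_index(), "mc_summary.csv")

    summary = {
        "provenance": prov,
        "scenario": {"tax_rate": res.tax_rate, "pass_on": res.pass_on},
        "outcomes": res.outcomes,
    }
    if bundle.uncertainty is not None:
        summary["uncertainty"] = {
            "n_draws": bundle.uncertainty.n_draws,
            "percentiles": list(bundle.uncertainty.percentiles),
            "summary": {
                k: dict(v) for k, v in bundle.uncertainty.summary.to_dict("index").items()
            },
        }
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(path)
    return written
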