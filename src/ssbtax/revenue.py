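"""Annual excise and VAT revenue effects of the tax.

Excise receipts are tau * p_ssb * Q_post, the ad valorem rate applied to the
pre-excise retail price on the post-tax quantity sold. The VAT change is the
VAT rate applied to the change in consumer expenditure across all three
beverages: SSB expenditure falls (demand is elastic), juice and milk
expenditure rise through substitution at unchanged prices. By default the
SSB VAT base is the pre-excise price, so the excise itself is not
VAT-cascaded and the excise figure stays a pure tau*p*Q term. Quantities use
the post-tax steady state, annualised over the consumer base (the share of
the population that consumes SSBs at all).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import BEVERAGES, BeverageConfig, TaxScenario
from .demand import ConsumptionDelta
from .population import PopulationTable

__all__ = [
    "RevenueLedger",
    "annual_servings",
    "excise_revenue",
    "vat_change",
    "compute_revenue",
]

_ZMW_PER_MILLION = 1e6


@dataclass(frozen=True)
class RevenueLedger:
    """Annual revenue deltas in ZMW, with USD-million conversions."""

    excise_zmw: float
    vat_zmw: float
    fx_rate: float

    @property
    def total_zmw(self) -> float:
        return self.excise_zmw + self.vat_zmw

    @property
    def excise_usd_m(self) -> float:
        return self.excise_zmw / self.fx_rate / _ZMW_PER_MILLION

    @property
    def vat_usd_m(self) -> float:
        return self.vat_zmw / self.fx_rate / _ZMW_PER_MILLION

    @property
    def total_usd_m(self) -> float:
        return self.excise_usd_m + self.vat_usd_m


def consumer_base(population: PopulationTable, base: str = "adult",
                  total_population: float | None = None) -> float:
    """Number of SSB consumers the revenue is annualised over."""
    if base == "adult":
        n = population.total_count
    elif base == "total":
        if total_population is None:
            raise ValueError("total_population required for consumer_base='total'")
        n = total_population
    else:
        raise ValueError(f"unknown consumer base '{base}'")
    return population.consumer_share * n


def annual_servings(
    population: PopulationTable,
    scenario: TaxScenario,
    weekly_per_capita: Mapping[str, float],
    base: str = "adult",
    total_population: float | None = None,
) -> dict[str, float]:
    """Annual servings sold per beverage over the consumer base."""
    consumers = consumer_base(population, base, total_population)
    out = {}
    for bev, weekly in weekly_per_capita.items():
        if weekly < 0:
            raise ValueError(f"negative weekly servings for '{bev}'")
        out[bev] = consumers * weekly * scenario.weeks_per_year
    return out


def excise_revenue(
    scenario: TaxScenario, ssb_servings_post_tax: float, ssb_price: float
) -> float:
    """Annual excise receipts in ZMW: tau * price * post-tax servings."""
    if ssb_servings_post_tax < 0:
        raise ValueError("servings must be >= 0")
    return scenario.tax_rate * ssb_price * ssb_servings_post_tax


def vat_change(
    scenario: TaxScenario,
    baseline_servings: Mapping[str, float],
    post_servings: Mapping[str, float],
    beverages: Mapping[str, BeverageConfig],
    vat_on_excise: bool = False,
) -> float:
    """Annual VAT change in ZMW across all beverages (signed).

    dVAT = v * sum_b price_b * (Q'_b - Q_b); the SSB price in the post-tax
    term includes the excise only when ``vat_on_excise`` is set.
    """
    v = scenario.vat_rate
    delta_expenditure = 0.0
    for bev in baseline_servings:
        price = beverages[bev].price_per_serving
        post_price = price
        if bev == "ssb" and vat_on_excise:
            post_price = price * (1.0 + scenario.tax_rate * scenario.pass_on)
        delta_expenditure += post_price * post_servings[bev] - price * baseline_servings[bev]
    return v * delta_expenditure


def compute_revenue(
    population: PopulationTable,
    scenario: TaxScenario,
    delta: ConsumptionDelta,
    beverages: Mapping[str, BeverageConfig],
    base: str = "adult",
    total_population: float | None = None,
    vat_on_excise: bool = False,
) -> RevenueLedger:
    """Assemble the annual revenue ledger from the post-tax consumption."""
    weekly_base = {b: delta.weighted_mean(population, b, "baseline") for b in BEVERAGES}
    weekly_post = {b: delta.weighted_mean(population, b, "post") for b in BEVERAGES}
    q0 = annual_servings(population, scenario, weekly_base, base, total_population)
    q1 = annual_servings(population, scenario, weekly_post, base, total_population)
    excise = excise_revenue(scenario, q1["ssb"], beverages["ssb"].price_per_serving)
    vat = vat_change(scenario, q0, q1, beverages, vat_on_excise=vat_on_excise)
    return RevenueLedger(excise_zmw=excise, vat_zmw=vat, fx_rate=scenario.fx_rate)
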