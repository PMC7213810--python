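"""Demand response: tax to price change, price change to consumption change.

An ad valorem excise at rate tau on the pre-tax retail price p raises the
consumer price by p * tau * rho, where rho is the pass-on (pass-through)
rate. The relative price change tau * rho then moves beverage demand through
price elasticities: SSBs through their own-price elasticity, fruit juice and
milk through cross-price elasticities with respect to the SSB price (their
own prices are unchanged by an SSB-only tax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import BEVERAGES, BeverageConfig, ElasticityConfig, TaxScenario
from .population import PopulationTable

__all__ = [
    "PriceChange",
    "ElasticityValues",
    "ConsumptionDelta",
    "price_after_tax",
    "consumption_change",
    "apply_tax_scenario",
]


@dataclass(frozen=True)
class PriceChange:
    baseline: float
    new_price: float
    increase: float


@dataclass(frozen=True)
class ElasticityValues:
    """One realisation of the three demand elasticities."""

    own_ssb: float
    cross_fruit_juice: float
    cross_milk: float

    @classmethod
    def from_config(cls, cfg: ElasticityConfig) -> "ElasticityValues":
        return cls(
            own_ssb=cfg.own_ssb.mean,
            cross_fruit_juice=cfg.cross_fruit_juice.mean,
            cross_milk=cfg.cross_milk.mean,
        )

    def for_beverage(self, beverage: str) -> float:
        return {
            "ssb": self.own_ssb,
            "fruit_juice": self.cross_fruit_juice,
            "milk": self.cross_milk,
        }[beverage]


@dataclass
class ConsumptionDelta:
    """Per-stratum, per-beverage consumption changes in weekly servings."""

    frame: pd.DataFrame  # columns: sex, age_group, beverage, baseline, delta, post
    rel_price_change: float

    def weighted_mean(
        self, population: PopulationTable, beverage: str, column: str = "delta"
    ) -> float:
        """Population-weighted mean of one column for one beverage."""
        sub = self.frame[self.frame["beverage"] == beverage]
        w = np.array(
            [population.stratum(r.sex, r.age_group).count for r in sub.itertuples()]
        )
        return float((w * sub[column].to_numpy()).sum() / w.sum())

    def stratum_delta(self, sex: str, age_group: str, beverage: str) -> float:
        sub = self.frame
        m = (
            (sub["sex"] == sex)
            & (sub["age_group"] == age_group)
            & (sub["beverage"] == beverage)
        )
        return float(sub.loc[m, "delta"].iloc[0])


def price_after_tax(price: float, tax_rate: float, pass_on: float) -> PriceChange:
    """Consumer price under an ad valorem excise with partial pass-through.

    new_price = price * (1 + tax_rate * pass_on); the increase is
    price * tax_rate * pass_on.
    """
    if price <= 0:
        raise ValueError(f"price must be positive, got {price}")
    if tax_rate < 0 or pass_on < 0:
        raise ValueError("tax_rate and pass_on must be non-negative")
    increase = price * tax_rate * pass_on
    return PriceChange(baseline=price, new_price=price + increase, increase=increase)


def consumption_change(q0: float, elasticity: float, rel_price_change: float) -> float:
    """Linear (arc) elasticity approximation: dq = q0 * e * dp/p."""
    if q0 < 0:
        raise ValueError("baseline quantity must be >= 0")
    if rel_price_change < -1:
        raise ValueError("relative price change cannot fall below -100%")
    return q0 * elasticity * rel_price_change


def apply_tax_scenario(
    population: PopulationTable,
    scenario: TaxScenario,
    elasticities: ElasticityValues,
    beverages: Mapping[str, BeverageConfig],
    functional_form: str = "linear",
) -> ConsumptionDelta:
    """Propagate the SSB price change into all beverage quantities.

    Post-change quantities are floored at zero (relevant only in extreme
    sensitivity draws); the reported delta is post - baseline so that floored
    strata stay internally consistent. A zero tax or zero pass-on leaves
    every quantity exactly unchanged.
    """
    for bev in BEVERAGES:
        if bev not in beverages:
            raise ValueError(f"missing beverage profile for '{bev}'")
    rel = scenario.tax_rate * scenario.pass_on

    rows = []
    for s in population.strata:
        for bev in BEVERAGES:
            q0 = s.weekly_servings[bev]
            e = elasticities.for_beverage(bev)
            if rel == 0.0:
                delta = 0.0
            elif functional_form == "power":
                delta = q0 * ((1.0 + rel) ** e - 1.0)
            elif functional_form == "linear":
                delta = consumption_change(q0, e, rel)
            else:
                raise ValueError(f"unknown functional_form '{functional_form}'")
            post = max(q0 + delta, 0.0)
            rows.append(
                {
                    "sex": s.sex,
                    "age_group": s.age_group,
                    "beverage": bev,
                    "baseline": q0,
                    "delta": post - q0,
                    "post": post,
                }
            )
    return ConsumptionDelta(frame=pd.DataFrame(rows), rel_price_change=rel)
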