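"""Per-pack and total program cost model.

Cost per pack decomposes into fixed components — procurement/manufacturing
M (35.0 RMB cents), implementation F (17.9 cents), advertisement A (16.7
cents) — plus province/group-specific transportation T:

* ``TM`` (manufacturer -> township hospital) decreases linearly with
  provincial road density R (km per 100 km² of land area), anchored at
  13.5 cents for R = 31 and 0.9 cents for R = 208:

      TM = 13.5 - (13.5 - 0.9) / (208 - 31) * (R - 31)

  and is clamped to the anchor values outside [31, 208] (the linear fit
  is only supported on its observed range and would go negative beyond
  it).
* Delivery Type 1: village doctors collect packs monthly from township
  hospitals (``TV``, 0.9 cents/pack, government-subsidized) and
  caregivers collect from village health posts (time cost ``TH``).
  T = TM + TV + TH.
* Delivery Type 2: caregivers travel monthly to the township hospital
  themselves (time cost ``TO``).  T = TM + TO.

Caregiver time is valued at provincial GDP per capita: monthly round
trips x one-way travel time, priced at annual GDP over a configurable
work-year, amortized over the packs of a 12-month one-pack-per-day
program.  PP = M + F + A + T; total cost = PP x POP x Cov x 365.
Monetary values are carried as RMB cents per pack (¥ for totals);
international dollars are a presentation conversion at the ¥19.4 ≡ $5.50
purchasing-power parity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

POVERTY_LINE_RMB = 19.4
POVERTY_LINE_INTL = 5.5


class CostParams(BaseModel):
    """Cost-model parameters, all per-pack values in RMB cents."""

    m_cents: float = Field(default=35.0, ge=0.0)
    f_cents: float = Field(default=17.9, ge=0.0)
    a_cents: float = Field(default=16.7, ge=0.0)
    tv_cents: float = Field(default=0.9, ge=0.0)
    tm_max_cents: float = Field(default=13.5, ge=0.0)
    tm_min_cents: float = Field(default=0.9, ge=0.0)
    r_min: float = Field(default=31.0, gt=0.0)
    r_max: float = Field(default=208.0, gt=0.0)
    packs_per_year: int = Field(default=365, ge=1)
    trips_per_year: int = Field(default=12, ge=0)
    hours_per_workyear: float = Field(default=2000.0, gt=0.0)
    ppp_rmb_per_intl_dollar: float = Field(default=POVERTY_LINE_RMB / POVERTY_LINE_INTL, gt=0.0)
    transport_multiplier: float = Field(default=1.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CostParams":
        if self.r_min >= self.r_max:
            raise ValueError(f"r_min={self.r_min} must be below r_max={self.r_max}")
        if self.tm_min_cents > self.tm_max_cents:
            raise ValueError("tm_min_cents must not exceed tm_max_cents")
        return self


@dataclass(frozen=True)
class PackCost:
    """Per-pack cost breakdown for one (province, wealth, delivery type).

    All values in RMB cents per pack; transport components already
    include any transport multiplier.  ``th``/``to`` are the caregiver
    time costs (Type 1 / Type 2 legs); the leg not used by the delivery
    type is recorded for reference but excluded from ``t_total``.
    """

    province: str
    wealth: str
    delivery_type: int
    tm: float
    tv: float
    th: float
    to: float
    t_total: float
    pp: float


def tm_from_density(road_density: float, params: CostParams | None = None) -> float:
    """Manufacturer-to-hospital transport cost (cents/pack) from road density.

    Linear between the anchors (cheapest at the densest network), clamped
    to the anchor costs outside the fitted density range.
    """
    params = params or CostParams()
    r = np.asarray(road_density, dtype=float)
    if (r <= 0).any():
        raise ValueError("road density must be positive")
    slope = (params.tm_max_cents - params.tm_min_cents) / (params.r_max - params.r_min)
    tm = params.tm_max_cents - slope * (np.clip(r, params.r_min, params.r_max) - params.r_min)
    return float(tm) if np.ndim(road_density) == 0 else tm


def time_cost_per_pack(
    travel_time_hours: float, gdp_per_capita_yr: float, params: CostParams | None = None
) -> float:
    """Caregiver time cost per pack (RMB cents).

    Monthly round trips (2 x one-way time), valued at GDP per capita per
    work-hour, spread over the packs delivered in a year.
    """
    params = params or CostParams()
    if travel_time_hours < 0 or gdp_per_capita_yr < 0:
        raise ValueError("travel time and GDP per capita must be non-negative")
    hourly_rmb = gdp_per_capita_yr / params.hours_per_workyear
    yuan_per_pack = (
        params.trips_per_year * 2.0 * travel_time_hours * hourly_rmb / params.packs_per_year
    )
    return yuan_per_pack * 100.0


def pack_cost(
    province_row,
    wealth: str,
    delivery_type: Literal[1, 2],
    mean_travel_times: tuple[float, float],
    params: CostParams | None = None,
) -> PackCost:
    """Assemble the per-pack cost for one province x wealth x delivery type.

    Parameters
    ----------
    province_row
        Mapping/Series with ``province``, ``road_density``,
        ``gdp_per_capita``.
    mean_travel_times
        Group-mean one-way travel times (health post, town) in hours;
        the group mean is used so the whole subgroup shares one per-pack
        cost.
    """
    params = params or CostParams()
    if delivery_type not in (1, 2):
        raise ValueError(f"unknown delivery type: {delivery_type!r}")
    t_hp, t_town = mean_travel_times
    mult = params.transport_multiplier
    tm = tm_from_density(province_row["road_density"], params) * mult
    tv = params.tv_cents * mult
    th = time_cost_per_pack(t_hp, province_row["gdp_per_capita"], params) * mult
    to = time_cost_per_pack(t_town, province_row["gdp_per_capita"], params) * mult
    t_total = tm + tv + th if delivery_type == 1 else tm + to
    return PackCost(
        province=str(province_row["province"]),
        wealth=wealth,
        delivery_type=int(delivery_type),
        tm=tm,
        tv=tv,
        th=th,
        to=to,
        t_total=t_total,
        pp=params.m_cents + params.f_cents + params.a_cents + t_total,
    )


def total_cost(pack: PackCost | float, pop: int, coverage: float, params: CostParams | None = None) -> float:
    """Total 12-month program cost in ¥ for one subgroup.

    pp (cents/pack) x population x coverage x packs per year, converted
    from cents to ¥.
    """
    params = params or CostParams()
    if pop < 0:
        raise ValueError("pop must be non-negative")
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    pp = pack.pp if isinstance(pack, PackCost) else float(pack)
    return pp * pop * coverage * params.packs_per_year / 100.0


def rmb_to_intl(amount_rmb: float, params: CostParams | None = None) -> float:
    """Convert RMB to international dollars at the configured PPP factor."""
    params = params or CostParams()
    return amount_rmb / params.ppp_rmb_per_intl_dollar


def intl_to_rmb(amount_intl: float, params: CostParams | None = None) -> float:
    params = params or CostParams()
    return amount_intl * params.ppp_rmb_per_intl_dollar
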