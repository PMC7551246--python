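"""Seeded synthetic microdata generator.

Produces province tables and child-level records with the statistical
structure the analysis assumes: per-child anthropometry whose HAZ
distribution differs by province and poverty status, household income per
capita relative to the ¥19.4/day poverty line, and log-normal travel
times to village health posts and to the nearest town.  It emulates the
*shape* of a large household panel survey (tens of provinces, rural
children aged 6-36 months), not any real survey's sampling design.

Children's heights are obtained by simulating HAZ directly from
Normal(mean, sd) per (province, wealth) group and inverting the growth
reference (height = median + HAZ x SD), which keeps the synthetic world
exactly consistent with the anthropometry module.

Wealth status is drawn Bernoulli(poverty fraction) per child and income
is then sampled from the matching side of a truncated log-normal, so the
realized below-line fraction is binomial around the configured fraction
and income classification agrees with group membership by construction.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .growth import AGE_MAX, AGE_MIN, GrowthReference

POVERTY_LINE_RMB_PER_DAY = 19.4  # international $5.50/day line, 2011 PPP
WEALTH_GROUPS = ("poor", "nonpoor")

PROVINCE_COLUMNS = [
    "province",
    "road_density",
    "gdp_per_capita",
    "pop_6_36m_poor",
    "pop_6_36m_nonpoor",
]
CHILD_COLUMNS = [
    "child_id",
    "province",
    "age_months",
    "sex",
    "height_cm",
    "income_per_capita",
    "travel_time_health_post",
    "travel_time_town",
    "survey_weight",
]


class SimConfig(BaseModel):
    """Parameters of the synthetic world.

    Defaults describe a 25-province rural setting: group mean HAZ around
    -1.1 SD for children below the poverty line and -0.5 SD above it
    (stunting prevalences of roughly 18% and 7% at unit HAZ SD), with a
    seeded per-province shift of up to ±0.4 SD; provincial road densities
    spanning 31-208 km per 100 km², GDP per capita ¥28,000-95,000 per
    year, and 100,000-1,500,000 children aged 6-36 months per province.
    """

    n_provinces: int = Field(default=25, ge=1)
    children_per_province: int = Field(default=400, ge=1)
    seed: int = 0

    # HAZ distribution per (province, wealth) group
    haz_mean_poor: float = -1.1
    haz_mean_nonpoor: float = -0.5
    haz_province_spread: float = Field(default=0.4, ge=0.0)
    haz_mean_by_group: Optional[dict[str, float]] = None  # "province:wealth" -> mean
    haz_sd: float = Field(default=1.0, ge=0.0)

    # income (¥/day, log-normal) and poverty
    poverty_fraction_by_province: Optional[dict[str, float]] = None
    poverty_fraction_range: tuple[float, float] = (0.2, 0.6)
    income_lognorm_mu: float = 3.4  # log ¥/day
    income_lognorm_sigma: float = Field(default=0.8, gt=0.0)
    poverty_line_rmb_per_day: float = Field(default=POVERTY_LINE_RMB_PER_DAY, gt=0.0)

    # one-way travel times (hours, log-normal): the village health post is
    # minutes away, the nearest town substantially farther
    travel_time_health_post_lognorm: tuple[float, float] = (-3.0, 0.6)
    travel_time_town_lognorm: tuple[float, float] = (-0.7, 0.6)

    # province-level characteristics
    road_density_range: tuple[float, float] = (31.0, 208.0)
    gdp_range: tuple[float, float] = (28_000.0, 95_000.0)
    pop_range: tuple[int, int] = (100_000, 1_500_000)

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimConfig":
        for name in ("poverty_fraction_range", "road_density_range", "gdp_range", "pop_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
        lo, hi = self.poverty_fraction_range
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("poverty_fraction_range must lie within [0, 1]")
        if self.poverty_fraction_by_province:
            bad = {k: v for k, v in self.poverty_fraction_by_province.items() if not 0 <= v <= 1}
            if bad:
                raise ValueError(f"poverty fractions outside [0, 1]: {bad}")
        if self.road_density_range[0] <= 0:
            raise ValueError("road densities must be positive")
        return self


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def province_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def generate_provinces(config: SimConfig) -> pd.DataFrame:
    """Generate the province-level table (one row per province).

    Road density, GDP per capita and the population aged 6-36 months are
    drawn uniformly over the configured ranges; the population is split
    into below/above-poverty-line counts using the province's poverty
    fraction.  Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, 0)
    ids = province_ids(config.n_provinces)
    lo, hi = config.road_density_range
    road = rng.uniform(lo, hi, size=config.n_provinces)
    gdp = rng.uniform(*config.gdp_range, size=config.n_provinces)
    pop_total = rng.integers(config.pop_range[0], config.pop_range[1] + 1, size=config.n_provinces)
    if config.poverty_fraction_by_province is not None:
        missing = [p for p in ids if p not in config.poverty_fraction_by_province]
        if missing:
            raise ValueError(f"poverty_fraction_by_province missing provinces: {missing}")
        pf = np.array([config.poverty_fraction_by_province[p] for p in ids])
    else:
        pf = rng.uniform(*config.poverty_fraction_range, size=config.n_provinces)
    pop_poor = np.rint(pop_total * pf).astype(int)
    return pd.DataFrame(
        {
            "province": ids,
            "road_density": road,
            "gdp_per_capita": gdp,
            "pop_6_36m_poor": pop_poor,
            "pop_6_36m_nonpoor": pop_total - pop_poor,
        }
    )


def poverty_fraction(provinces: pd.DataFrame) -> pd.Series:
    """Below-line population share per province, from the split counts."""
    total = provinces["pop_6_36m_poor"] + provinces["pop_6_36m_nonpoor"]
    return (provinces["pop_6_36m_poor"] / total).set_axis(provinces["province"])


def _group_haz_means(config: SimConfig, ids: list[str], rng: np.random.Generator) -> dict:
    """Resolve the (province, wealth) -> mean HAZ map."""
    offsets = rng.uniform(-config.haz_province_spread, config.haz_province_spread, size=len(ids))
    means = {}
    base = {"poor": config.haz_mean_poor, "nonpoor": config.haz_mean_nonpoor}
    for pid, off in zip(ids, offsets):
        for wealth in WEALTH_GROUPS:
            key = f"{pid}:{wealth}"
            if config.haz_mean_by_group and key in config.haz_mean_by_group:
                means[(pid, wealth)] = config.haz_mean_by_group[key]
            else:
                means[(pid, wealth)] = base[wealth] + off
    return means


def _truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, line: float, below: bool
) -> np.ndarray:
    """Sample a log-normal conditioned on lying below/above ``line``."""
    p_line = stats.norm.cdf((np.log(line) - mu) / sigma)
    # keep a sliver of mass on each side so conditioning is well defined
    p_line = min(max(p_line, 1e-12), 1 - 1e-12)
    u = rng.uniform(0.0, p_line, n) if below else rng.uniform(p_line, 1.0, n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def generate_children(
    config: SimConfig, provinces: pd.DataFrame, ref: GrowthReference | None = None
) -> pd.DataFrame:
    """Generate the child-level microdata table.

    One row per child: identifiers, age 6-36 months, sex, height (via the
    growth reference and the group's HAZ distribution), income per capita
    (¥/day), one-way travel times to the village health post and to the
    nearest town (hours) and a survey weight (1.0 by default; the paper
    trail for real surveys' weighting is outside the generator's scope).
    Deterministic given ``config.seed``.
    """
    if provinces.empty:
        raise ValueError("provinces table is empty")
    ref = ref or GrowthReference.bundled()
    rng = _rng(config.seed, 1)
    ids = provinces["province"].tolist()
    pf = poverty_fraction(provinces)
    means = _group_haz_means(config, ids, _rng(config.seed, 2))

    frames = []
    n = config.children_per_province
    for pid in ids:
        age = rng.integers(AGE_MIN, AGE_MAX + 1, size=n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        poor = rng.random(n) < pf[pid]
        mu = np.where(poor, means[(pid, "poor")], means[(pid, "nonpoor")])
        haz = rng.normal(mu, config.haz_sd)
        median, sd = ref.lookup_arrays(sex, age)
        height = median + haz * sd

        income = np.empty(n)
        for below in (True, False):
            mask = poor == below
            income[mask] = _truncated_lognormal(
                rng,
                int(mask.sum()),
                config.income_lognorm_mu,
                config.income_lognorm_sigma,
                config.poverty_line_rmb_per_day,
                below=below,
            )
        t_hp = rng.lognormal(*config.travel_time_health_post_lognorm, size=n)
        t_town = rng.lognormal(*config.travel_time_town_lognorm, size=n)

        frames.append(
            pd.DataFrame(
                {
                    "child_id": [f"{pid}-{i:05d}" for i in range(1, n + 1)],
                    "province": pid,
                    "age_months": age,
                    "sex": sex,
                    "height_cm": height,
                    "income_per_capita": income,
                    "travel_time_health_post": t_hp,
                    "travel_time_town": t_town,
                    "survey_weight": 1.0,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)[CHILD_COLUMNS]
    if not out["height_cm"].between(40, 120).all():
        # plausibility window: extreme tails indicate a mis-set HAZ config
        bad = out[~out["height_cm"].between(40, 120)]
        raise ValueError(f"{len(bad)} generated heights fall outside 40-120 cm")
    return out


def classify_wealth(income_per_capita, line: float = POVERTY_LINE_RMB_PER_DAY):
    """Map income per capita (¥/day) to 'poor'/'nonpoor' by the poverty line."""
    arr = np.asarray(income_per_capita, dtype=float)
    out = np.where(arr < line, "poor", "nonpoor")
    return str(out) if arr.ndim == 0 else out


def write_tables(children: pd.DataFrame, provinces: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children.to_csv(out / "children.csv", index=False)
    provinces.to_csv(out / "provinces.csv", index=False)


def read_children(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CHILD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"children table missing columns: {sorted(missing)}")
    return df[CHILD_COLUMNS]


def read_provinces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PROVINCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"provinces table missing columns: {sorted(missing)}")
    return df[PROVINCE_COLUMNS]
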