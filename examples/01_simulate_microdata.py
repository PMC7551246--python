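"""Generate a synthetic survey-like microdata set.

Builds a 25-province world of rural children aged 6-36 months: heights
consistent with per-group HAZ distributions, incomes relative to the
¥19.4/day poverty line, and travel times to the village health post and
the nearest town.
"""

from yyb_ecea import SimConfig, classify_wealth, generate_children, generate_provinces

cfg = SimConfig(seed=1)
provinces = generate_provinces(cfg)
children = generate_children(cfg, provinces)

print(provinces.head().round(1).to_string(index=False))
print(f"\n{len(children)} children across {len(provinces)} provinces")
poor = (classify_wealth(children["income_per_capita"]) == "poor").mean()
print(f"share below the ¥19.4/day poverty line: {poor:.1%}")
print(f"mean height: {children['height_cm'].mean():.1f} cm")
# Each province row carries its road density (drives pack transport cost),
# GDP per capita (values caregiver time) and child population by wealth
# group; the poor share is the fraction of children whose household income
# per capita falls below the international $5.50/day line.
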