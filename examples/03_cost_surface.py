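"""The per-pack cost model and its printed anchor points.

Per-pack cost = M (35.0 cents) + F (17.9) + A (16.7) + transport, where
the manufacturer-to-hospital leg TM falls linearly with road density and
caregiver time is valued at provincial GDP per capita.
"""

from yyb_ecea import CostParams, pack_cost, rmb_to_intl, tm_from_density

for density in (31.0, 119.5, 208.0):
    tm = tm_from_density(density)
    print(f"road density {density:6.1f} km/100km² -> TM {tm:4.1f} cents "
          f"(RMB; {rmb_to_intl(tm):.1f} cents ($))")

province = {"province": "demo", "road_density": 100.0, "gdp_per_capita": 50_000.0}
for dtype in (1, 2):
    pc = pack_cost(province, "poor", dtype, (0.05, 0.5), CostParams())
    print(f"delivery type {dtype}: transport {pc.t_total:5.1f} cents, "
          f"total {pc.pp:5.1f} cents/pack (¥{pc.pp / 100:.2f})")
# TM spans 13.5 cents (sparsest network) down to 0.9 (densest). Type 1
# (village doctors distribute; caregivers walk to the village post) is
# cheaper than Type 2 (caregivers travel to the township hospital) as
# long as the town trip dominates the short village trip.
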