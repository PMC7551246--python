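# Methods

## Scope and structure

The package models the distributional consequences of rolling out a daily
micronutrient supplement (Ying Yang Bao, YYB) to rural Chinese children
aged 6–36 months: health benefit as stunting cases averted, program cost
by delivery mode, and cost per case averted for every province × wealth
group. Five concerns map to five modules: `synthetic` (microdata
generation), `growth`/`anthropometry` (HAZ standardization and
prevalence), `intervention` (height-shift model), `costs` (per-pack and
total cost), `ecea` (orchestration, ICERs, sensitivity), with `io_cli`
and `cli` for configuration, validated CSV I/O and the shell interface.

## Anthropometry

HAZ = (height − median) / SD, with the (sex, age-month) → (median, SD)
map supplied as a CSV. Stunting is **strictly** HAZ < −2: a child at
exactly −2 is not stunted. The boundary rule matters only on a measure-
zero set for continuous heights but is fixed so that degenerate
configurations (e.g. zero HAZ variance at the threshold) are reproducible.

The bundled reference (`growth_reference_synthetic.csv`) is a
**synthetic simplified table**: monthly medians/SDs linearly interpolated
between standard anchor values (median height ≈ 67.6→96.1 cm for boys,
65.7→95.0 cm for girls over 6–36 months; SD ≈ 2.2→3.9 cm). It is *not*
the WHO LMS standard — skewness-corrected LMS standardization is out of
scope — but the file format accepts real WHO medians/SDs unchanged.
Validation at load rejects missing (sex, age) cells, non-positive SDs and
medians that decrease with age.

Prevalence is the survey-weighted stunted fraction; weights default to 1.
An empty subgroup has undefined prevalence and propagates as NA (never a
crash, never infinity), mirroring how zero-prevalence provinces appear in
published tables.

## Synthetic microdata generator

The generator emulates the *structure* of a large household panel survey,
not any real survey's sampling design:

- **HAZ is simulated directly** per (province, wealth) group from
  Normal(mean, sd) and converted to height by inverting the reference
  (height = median + HAZ × SD). This guarantees consistency between the
  generated world and the anthropometry module — the analysis consumes
  only HAZ-derived quantities.
- **Wealth and income.** Each child's group is Bernoulli(province
  poverty fraction); income per capita (¥/day) is then drawn from the
  matching side of a log-normal truncated at the ¥19.4/day line
  (log-scale location 3.4, scale 0.8). Classification by income therefore
  agrees with group assignment by construction and the realized poor
  share converges binomially to the configured fraction.
- **Defaults as study conditions.** 25 provinces × 400 children; group
  mean HAZ −1.1 (poor) and −0.5 (non-poor) with a seeded per-province
  shift of up to ±0.4 and unit SD — giving group stunting prevalences of
  roughly 18% and 7%, in the range observed for rural China; provincial
  poverty fractions uniform on [0.2, 0.6]; road density on [31, 208]
  km/100 km² (the cost model's anchor range); GDP per capita on
  [¥28,000, ¥95,000]/year (the observed provincial spread); population
  aged 6–36 months on [100,000, 1,500,000] per province. One-way travel
  times are log-normal with medians ≈ 0.05 h to the village health post
  and ≈ 0.5 h to the nearest town (σ_log = 0.6) — villages have a post
  minutes away, towns substantially farther.
- **What it does not emulate:** panel structure, cluster sampling and
  design weights, urban populations, measurement error in height, and
  real provincial identities. Passing tests show the pipeline's algebra
  and calibration behave correctly under known conditions, not that the
  synthetic world reproduces any province's actual estimates.

All randomness derives from one seed via separate `SeedSequence` spawn
keys per stage (provinces, children, group means), so tables are
bit-identical across runs with the same seed.

## Intervention model

Default mode `expected_shift` implements the expected-height model
literally: every child gains Eff × Cov cm, post-HAZ is recomputed, and
AVERT = POP × (S_pre − S_post) is carried as a real number (rounding only
at presentation). `bernoulli` mode covers each child with probability Cov
(seeded) and grants covered children the full Eff; its mean over seeds is
the coverage-weighted mixture Cov × [Φ(−2−μ) − Φ(−2−μ−Eff/s)], which is
*not* identical to the partial-uniform-shift result — the headline tables
follow the expected-shift form. Coverage is one scalar per scenario,
shared across wealth groups within a province.

Eff defaults to 2.46 cm (95% CI 0.96–3.97) from the meta-analysis of
supplementation trials; the estimate is an input parameter here, not
re-derived.

## Cost model

Per-pack cost (RMB cents) PP = M + F + A + T with M = 35.0, F = 17.9,
A = 16.7. Transport:

- **TM** (manufacturer → township hospital) is linear in road density
  between the anchors (13.5 cents at R = 31, 0.9 at R = 208) and
  **clamped** outside [31, 208]: the linear fit is supported only on its
  observed range and would extrapolate negative.
- **Type 1** adds TV = 0.9 cents (village doctors' monthly collection,
  government-subsidized) and caregiver time TH to the village post;
  **Type 2** adds caregiver time TO to the township hospital. Both
  caregiver legs are included in the societal total.
- **Caregiver time valuation.** The underlying costing rule — travel
  time × provincial GDP per capita — has no canonical unit basis, so the
  package makes it dimensionally explicit with named knobs: 12 round
  trips/year (monthly collection), hourly value = annual GDP per capita /
  2,000 work-hours, amortized over 365 packs. Each knob is configurable;
  alternative time bases simply rescale TH/TO.
- **TH/TO use group-mean travel times** per (province, wealth), so the
  whole subgroup shares one per-pack cost, matching the one-PP-per-group
  structure of the reported tables.
- `transport_multiplier` scales the entire T term (the sensitivity hook);
  a separate total-cost multiplier can be emulated by scaling M, F, A
  alongside it.

Total cost = PP × POP × Cov × 365 (¥). All values are carried internally
in RMB (cents per pack, ¥ for totals); international dollars are a pure
presentation conversion at PPP = 19.4/5.5 ¥ per $, reproducing the
printed component conversions (35.0→9.9¢, 17.9→5.1¢, 16.7→4.7¢,
13.5→3.8¢, 0.9→0.3¢) under 1-decimal rounding.

Because the time valuation here is explicit rather than calibrated to an
unstated convention, the caregiver legs come out larger relative to the
fixed components than in published per-pack averages; the *orderings*
the analysis relies on (Type 1 cheaper than Type 2 wherever the town trip
dominates; transport scaling moving total costs monotonically) are
preserved and tested.

## ECEA engine

`run_scenario` chains HAZ → effect → per-group prevalences → AVERT →
pack/total costs → ICER = total cost / AVERT. Zero-averted (or empty)
groups get an NA ICER, never infinity. National totals are sums over
groups (additivity is a tested invariant, as is ICER × AVERT = cost).
`sensitivity_suite` runs {base, eff_halved, eff_ci_lower = 0.96 cm,
transport_halved, transport_doubled} × {25%, 75% coverage} × {Type 1, 2}
under fixed labels so output files are diffable. `rank_groups` sorts
ascending by ICER with NA last and stable (province, wealth) tie-breaks.

The pro-poor result is emergent, not forced: poor groups are simulated
with lower mean HAZ, so more of their mass sits near the −2 threshold and
the same height shift averts more cases per yuan. A calibrated fixture
(poor mean −1.8, non-poor −0.2, SD 0.8) verifies the direction — the
poor-group ICER is lower in a majority of provinces.

## Numerical and design choices

- Strict `<` at the stunting threshold; NA (NaN) for undefined
  prevalences/ICERs, rendered as the string `NA` in CSV output.
- AVERT and ICERs kept as floats; rounding only in the human-readable
  report.
- Configuration is validated with pydantic; *all* violations are reported
  at once with field paths before any computation.
- Result files are written with a fixed column order, stable sort and
  `%.10g` floats, so identical inputs + seed give byte-identical output
  directories (tested).
- Problem sizes in tests and the acceptance script (10,000-child worlds,
  10,000-draw closed-form checks, 100 random oracle instances) were
  chosen to keep Monte-Carlo error well inside 3-SE bands while the whole
  suite runs in seconds.

## Limitations

- The cost surface is linear in road density with a flat multiplier;
  discontinuous mode-switching transport (trucks vs other means) is not
  modeled.
- No duration–response or age-dependent effect; Eff is one number for all
  children.
- No optimal-coverage search, no urban populations, no outcomes beyond
  stunting (anemia, cognition), no financial-risk-protection dimension.
- Synthetic-world magnitudes (total cases averted, total cost, ICER
  range) are illustrative: they depend on generator defaults, not on any
  real survey, and should not be read as provincial estimates.
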