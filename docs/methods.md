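# Methods

`circwood` is a dynamic, consequential greenhouse-gas accounting model of a
national (UK-style) forestry value chain. It simulates annual Scope 1–4
CO₂e trajectories over 2022–2050 for four wood-use scenarios — business as
usual (`bau`), enhanced `cascading` (more sawnwood, fewer panels from virgin
wood), `circular` (recycled MDF manufactured from recovered waste MDF), and
`cascading_circular` — and for a national afforestation programme. This note
records the model, its assumptions, the default parameters and the choices
made where the design was genuinely open.

## Model structure

A scenario is a mass-balanced directed network of annual wood flows (green
tonnes/yr) from the forest gate through sawmilling, panel manufacture,
woodfuel production and MDF recycling to product sinks. Networks are
normalised to a harvest of 100 and rescaled to the configured national
harvest (default 9.5 Mt green/yr, held constant through the horizon). Mass
balance at every processing node is enforced to 1×10⁻⁶ relative — losses
must appear as explicit flows — because only floating-point rounding should
ever create a residual.

Total national consumption of every product is held constant across
scenarios (the consequential convention): a change in domestic production is
mirrored by the opposite change in imports. The single exception is
woodfuel, where a configurable imported-woodfuel volume partially replaces
waste-MDF fuel diverted into recycling, leaving a real net reduction in
woodfuel consumption in the circular scenarios.

Annual accounting assembles eight components:

* Scope 1–3 process emissions for forestry operations, sawmilling, wood-panel
  production (including recycling) and woodfuel production: node throughput ×
  per-tonne factor × decarbonisation multiplier. Factors are
  pre-characterised GWP100 CO₂e values; no per-gas bookkeeping is done
  because only the CO₂e-expressed GWP category is evaluated.
* Change in import emissions: delta volumes versus BAU priced at per-unit
  processing factors equal to the domestic ones plus a transport factor.
  The BAU import burden itself is set to zero, so BAU carries no import
  term. Exporting regions decarbonise on the same schedule.
* Change in domestic HWP carbon storage (signed, biogenic).
* Avoided emissions from reduced harvest, product substitution — Scope 4.

The net Scope 1–3 series includes the HWP storage change (it is a
domestically attributed biogenic flux, not an avoided emission); the net
Scope 1–4 series adds the three avoided-emission components. Sign
convention: emissions positive, removals and avoided emissions negative.

## Industrial decarbonisation

Every emission factor carries a sector tag (`fossil_fuel`, `electricity`,
`chemicals`, `transport`, `energy_supply`, `minerals`). A step schedule
multiplies factors by a sector multiplier in [0, 1], constant within a
decade, 1 before the first step and non-increasing in time. The default
schedule steps at 2030/2040/2050 with electricity decarbonising fastest
(0.50/0.20/0.05) and process heat, chemicals and transport more slowly
(e.g. 0.65/0.35/0.10 for fossil fuel). These values are calibration — a
plausible national decarbonisation pathway — not measurements; a small
residual remains at 2050 because full industrial decarbonisation lies beyond
the horizon. Substitution credits are subject to the same multipliers (the
displaced gas and concrete sectors also decarbonise); the biogenic storage
credits are not.

## HWP carbon pools

Product pools follow the IPCC Tier-1 first-order decay recurrence with
k = ln2 / half-life:

    stock[t+1] = e^(−k)·stock[t] + (1 − e^(−k))/k · inflow[t]

which conserves carbon exactly (release = stock + inflow − next ≥ 0);
`expm1` keeps the inflow term accurate for very long-lived products.
Default half-lives: carcassing 35 y, panels (particleboard, MDF, recycled
MDF) 25 y, fencing/fence poles/other 15 y, packaging/pallets 2 y, woodfuel
immediate release. These follow common national HWP-reporting assumptions
and are configurable per run. Only domestically produced HWP are pooled;
imported-HWP storage is credited to the exporter and landfill is out of
scope. Green tonnes convert to carbon via moisture 0.5 and carbon fraction
0.5 of dry mass (both configurable).

The storage credit versus BAU is the annualised 50-year average stock gain,
applied as a constant annual entry from the implementation year:

    credit = −mean(Δstock over 50 y) × (44/12) / 50

Production beyond the horizon is held at its final value. The same
annualisation is used for the forest credit below; applying the mean gain
without the 1/window factor would overstate the credit by more than an
order of magnitude relative to every other term.

## Forest carbon

The stand model is deliberately transparent rather than a full forest
carbon-budget simulator: a Chapman–Richards (or tabulated) age→volume
curve per species/yield class, a fixed biomass-expansion × density × carbon
product (default 0.40 odt/m³ × 0.5 × 1.4 = 0.28 t C/m³ of stem volume), and
a single first-order soil/dead-organic-matter pool (decay 0.03/yr) fed by
stand turnover (1.5 %/yr of standing biomass C) and harvest residues (30 %
of felled biomass C). Clear-fell at rotation age resets standing volume;
harvested stem carbon leaves the stand for the HWP accounting. Mixed
stands use area-weighted mean yield classes. These soil parameters are
calibration; the regulated-estate *biomass* behaviour is exact (the
age-class closed form matches the cohort simulation to machine precision).

**Avoided harvest.** Recycling MDF lowers demand for virgin wood; the model
represents this as a reference fully regulated Sitka spruce estate
(710,000 ha) shifting from a 50- to a 54-year rotation. The estate
simulation gives (i) the annualised 28-year average carbon gain and (ii)
the mean annual harvest reduction. Their ratio defines a credit intensity
per green tonne of avoided harvest, which is scaled linearly by the
scenario's recycled-MDF volume. This mapping keeps the credit zero at zero
recycling and monotone in recycled volume while preserving the fixed
rotation-shift definition; the implied harvest reduction is also returned
so users can substitute their own mapping.

**Afforestation.** 20,000 ha/yr planted 2023–2050 (the later of the two
candidate start years was adopted; configurable), half commercial conifer
(Sitka-like, ~YC16) and half a 50:50 conifer:broadleaf mix (aggregate
~YC9). One cohort per planting year per mix component, superposed, with no
harvest inside the horizon (commercial felling starts 50 years after
planting). Cumulative sequestration therefore accelerates toward 2050.

## Substitution credits

Woodfuel displaces natural-gas energy on delivered energy: default
9,000 MJ delivered per tonne of fuel and 0.07 kg CO₂e/MJ of displaced gas.
Construction sawnwood converts to timber-framed wall area at 0.0175 m³ of
timber per m² (industry-standard design) using a timber density of
500 kg/m³ at 20 % moisture; each m² displaces a single-skin 140-mm concrete
block-and-mortar wall at a composed 12 kg CO₂e/m². The wall factor, density
and energy constants are calibration (composed offline from block, sand and
cement factors) and all overridable. Construction timber consumption is
constant across scenarios (imports balance), so the construction credit is
scenario-independent; the fuel credit follows each scenario's net woodfuel
use. Biogenic CO₂ from combustion is released through the fuelwood pool,
not added here, avoiding double counting. Timber-wall manufacturing
emissions live in the process-emission components, not inside the credit.

## Scenario runs

A run covers 2022–2050. Study year 1 is 2023, so "implement in year 5"
means the scenario flow table replaces BAU from 2027 (year 10 → 2032);
before that, every scenario runs on BAU flows. BAU has zero HWP-change,
import-change and avoided-harvest entries by construction. The annualised
credits are constant from the implementation year; the year-resolved pool
series are available through the library for inspection. Combining a
scenario with afforestation is exact addition (no interaction is
modelled).

Comparisons follow the reduction conventions: "X % lower Scope 1–3" is
(a − b)/a × 100, "X % larger reduction" is (|b| − |a|)/|a| × 100 with both
nets required to be negative; a zero or positive reference raises an error
rather than returning NaN.

## Synthetic inputs

`make_calibrated_fixture()` is deterministic and calibrated so that the
qualitative structure the model is designed to study emerges: wood panels
carry ~63 % of the BAU Scope 1–3 burden, resin (scope-3 chemicals rows on
the panel processes, kept as separate inventory rows so the share is
inspectable) ~40 % of the panel burden at unit multipliers, fuel and
construction credits of similar magnitude, BAU 2035 net Scope 1–4 on the
order of −2 Mt CO₂e at a 9.5 Mt harvest, and circular scenarios whose
avoided-harvest credit exceeds their Scope 1–3 total. The flow shares,
factor magnitudes and curve parameters are calibration, not reproductions
of any measured inventory.

`random_instance(SyntheticSpec(seed))` generates seeded random bundles —
Dirichlet-distributed flow shares balanced by construction, log-uniform
emission factors, half-lives in [2, 50] y, random Chapman–Richards curves —
used by the property suite (mass balance, carbon conservation, additivity,
determinism). Generation is a pure function of the seed.

Because the generators emulate structure rather than data, passing tests
demonstrate the accounting machinery (conservation laws, ordering,
crossing behaviour, dominance of early action) — not the absolute
magnitudes of any real value chain, which require a measured life-cycle
inventory and flow volumes as inputs.

## Numerical choices and degenerate inputs

* Balance tolerance 1×10⁻⁶ relative to the harvest; pure arithmetic.
* Empty flow specifications are valid and vacuously balanced.
* Zero half-life means immediate release; zero recycling means zero
  avoided-harvest credit; zero planting rate gives an all-zero programme.
* Yield curves extrapolate flat beyond their last tabulated age, capturing
  the declining increment of over-mature stands.
* Percentage comparisons raise on undefined references instead of NaN.
* All randomness flows through `numpy.random.default_rng(seed)`.

## Problem sizes

Default runs use 29 annual steps (2022–2050), a 50-year HWP credit window,
a 28-year forest credit window, 50–54 estate age classes and ≤56
afforestation cohorts; a full four-scenario run completes in well under a
second, and the shipped property sweeps use 20–100 seeded instances.

## Known limitations

* Flow volumes are fixture calibration; the published case study's exact
  per-edge volumes live in its supplementary materials and are not
  reproduced here.
* The forest model is a one-pool-soil, fixed-expansion simplification of a
  full carbon-budget model; absolute forest-carbon magnitudes should be
  treated as indicative.
* Intra-year dynamics, stochastic wood supply, landfill methane, BECCS,
  pulp and paper, steel/plastic substitution and non-GWP impact categories
  are out of scope.
* Emission factors are inputs; the package derives nothing from LCI
  databases and propagates no factor uncertainty.
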