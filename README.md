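# circwood

Dynamic consequential life-cycle assessment of cascading and circular wood
use in a national forestry value chain.

Forestry value chains can mitigate climate change far beyond their own
process emissions: wood stores carbon while in use, displaces
fossil-intensive products (natural-gas energy, concrete construction), and
recycling wood lowers demand for virgin harvest, leaving more carbon
standing in forests. `circwood` quantifies these effects together. It
simulates annual and cumulative Scope 1–4 CO₂e trajectories over 2022–2050
for four wood-use scenarios — business as usual (`bau`), enhanced
`cascading` (more sawnwood, fewer panels from virgin wood), `circular`
(recycled MDF manufactured from recovered waste MDF) and
`cascading_circular` — plus a national afforestation programme, under
stepwise decadal industrial decarbonisation.

It is written for LCA practitioners, forest-sector analysts and policy
modellers who want a transparent, fully testable implementation whose every
input (wood flows, emission factors, half-lives, yield curves,
decarbonisation schedule, substitution constants) is a plain text file.

## Model in brief

* **Wood flows** are mass-balanced directed networks (green tonnes/yr),
  normalised to a harvest of 100 and rescaled to the national harvest
  (default 9.5 Mt/yr). National consumption of each product is constant:
  domestic production changes are mirrored by import changes
  (consequential convention).
* **Process emissions** (Scopes 1–3): node throughput × factor ×
  sector/year decarbonisation multiplier.
* **HWP carbon pools** follow IPCC Tier-1 first-order decay,
  `S(t+1) = e^(−k) S(t) + (1−e^(−k))/k · I(t)`, `k = ln2/half-life`; the
  storage credit vs BAU is the annualised 50-year mean stock gain ×44/12.
* **Avoided harvest**: a 710,000-ha regulated Sitka estate shifting from a
  50- to a 54-year rotation defines a credit per green tonne of avoided
  harvest, scaled by the scenario's recycled-MDF volume.
* **Substitution** (Scope 4): woodfuel displaces natural gas on delivered
  energy; construction timber converts to wall area (0.0175 m³/m²) and
  displaces 140-mm concrete blockwork. Credits shrink as the displaced
  sectors decarbonise; the biogenic storage credits do not.

Sign convention: emissions positive, removals/avoided emissions negative.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import circwood as cw

bundle = cw.make_calibrated_fixture()          # calibrated synthetic inputs
results = cw.run_all_scenarios(bundle)         # implementation in 2027

for sid in ("bau", "cascading", "circular", "cascading_circular"):
    r = results[sid]
    print(f"{sid:20s} net S1-3 2035: {r.net_s13().loc[2035]/1e6:+.2f} Mt   "
          f"net S1-4 2035: {r.net_s14().loc[2035]/1e6:+.2f} Mt   "
          f"cumulative 2050: {r.cumulative_net_s14().iloc[-1]/1e6:+.1f} Mt")

pct = cw.compare_scenarios(results["bau"], results["cascading_circular"],
                           "s14_pct_larger_reduction", 2035)
print(f"cascading&circular 2035 reduction vs BAU: +{pct:.0f}%")

aff = cw.run_afforestation(bundle)
comb = cw.combine_with_afforestation(results["cascading_circular"], aff)
print(f"combined cumulative 2050:      "
      f"{comb['combined_cumulative_tco2e'].iloc[-1]/1e6:+.1f} Mt")
```

prints

```
bau                  net S1-3 2035: +0.36 Mt   net S1-4 2035: -1.57 Mt   cumulative 2050: -43.6 Mt
cascading            net S1-3 2035: +0.29 Mt   net S1-4 2035: -1.60 Mt   cumulative 2050: -44.4 Mt
circular             net S1-3 2035: +0.25 Mt   net S1-4 2035: -2.26 Mt   cumulative 2050: -60.6 Mt
cascading_circular   net S1-3 2035: +0.20 Mt   net S1-4 2035: -2.29 Mt   cumulative 2050: -61.2 Mt
cascading&circular 2035 reduction vs BAU: +46%
combined cumulative 2050:      -131.1 Mt
```

Reading: in 2035 every scenario is a net Scope 1–4 sink (negative Mt CO₂e),
avoided emissions outweighing process emissions. The circular scenarios
roughly halve the remaining Scope 1–3 burden and deliver ~45 % larger net
reductions than BAU, because recycling MDF both stores more carbon in
products and leaves harvest standing in forests; cascading alone is largely
offset by import rebalancing. By 2050 only the circular scenarios cross
Scope 1–3 net zero. Combining circular wood use with 20,000 ha/yr of
afforestation roughly doubles cumulative mitigation by 2050.

## Command line

```bash
circwood synth --seed 1 --out inputs/            # write synthetic input CSVs + run.yaml
circwood run --config inputs/run.yaml --scenario circular --out results/
circwood compare bau circular --config inputs/run.yaml \
    --metric s14_pct_larger_reduction --year 2035
circwood afforest --config inputs/run.yaml --out results/
```

`run` writes a tidy emissions CSV (year, component, scope, value_tco2e), a
summary JSON and a Sankey-ready flow JSON. All inputs are editable CSVs
documented in `docs/methods.md`.

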