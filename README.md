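# pacarbon

Counterfactual matching pipeline for quantifying the **carbon effectiveness
of protected areas** — how much aboveground carbon (AGC) protected status
itself preserves — from spaceborne-lidar style sampling.

Global lidar missions sample forest structure in ~25 m footprints along
orbital tracks. Aggregated to 1-km cells, those samples support a causal
question conservation scientists and climate-policy analysts keep asking:
*do protected areas (PAs) hold more carbon than the same land would have
held without protection?* Simply comparing PA cells with all unprotected
cells is badly confounded — parks sit preferentially on remote, wet,
carbon-rich land. `pacarbon` implements the matched-counterfactual design
used in global PA carbon accounting:

1. **Footprint processing** — keep shots with `quality_flag == 1` and
   sensitivity ≥ 0.95, convert biomass to carbon density
   (AGCD = 0.49 · AGBD), average shots per 1-km cell, and require ≥ 5 shots
   per cell.
2. **Matching** — pair each protected cell with one unprotected cell that
   agrees exactly on land cover, country, ecoregion and biome, lies > 10 km
   from any PA boundary, and has the nearest propensity score (logistic
   regression on elevation, slope, climate, accessibility and population
   covariates) within a caliper of 0.2 × SD(logit scores), 1:1 without
   replacement.
3. **Effect estimation** — paired differences d_i = AGCD(PA) − AGCD(match),
   pooled per country × biome, expanded by non-overlapping PA area into
   additional AGC (Gt) with cluster-robust standard errors, aggregated to
   country / continent / biome / globe; PAs without matches inherit their
   stratum mean (provenance recorded).
4. **Attribution** — each matched PA is classified from its biomass
   difference and 2000–2019 forest-loss fractions into five classes:
   avoided deforestation, enhanced stocks, no additionality, encroachment,
   degradation.
5. **Baseline check** — year-2000 carbon compared within pairs and
   regressed on PA age, testing whether PAs were simply sited on
   carbon-rich land.

A synthetic-landscape generator with known ground truth (confounded PA
placement, track-sampled footprints, loss rates and a year-2000 baseline)
makes every stage verifiable by parameter recovery; see `docs/methods.md`
for the model and its assumptions.

## Worked example

```bash
python examples/match_and_estimate.py
```

```
shots 195636 -> 138289 after quality filter; 8607 qualified 1-km cells
treated cells 553, control pool 1331, matched pairs 163

true protection effect:     4.90 Mg C/ha
matched paired estimate:    5.05 Mg C/ha
naive unmatched contrast:  14.81 Mg C/ha  (confounded)

global additional carbon: 0.00043 Gt +/- 0.00017 over 672 km^2 of PAs
```

On this 100 × 100 km synthetic world the generator installed a true
protection effect of 10 Mg/ha biomass (4.9 Mg C/ha carbon). The matched
estimate recovers it (5.05 ± reported SE), while the naive PA-minus-rest
contrast is three times too large because protection was preferentially
placed on carbon-rich land. The global total is the matched density
difference times the dissolved PA area — the same arithmetic that, at
planetary scale, turns ~28% higher carbon inside PAs into gigatonnes of
additionally preserved AGC.

Other examples: `simulate_landscape.py` (the synthetic world and its
WDPA-style GeoJSON), `attribute_effectiveness.py` (the five-class
partition), `baseline_placement_check.py` (the placement hypothesis test),
`published_shares.py` (share arithmetic on the published global summary
values).

A thin CLI wraps the same stages:

```bash
pacarbon simulate --seed 1 --out world/
pacarbon run-all  --seed 1 --out report/
```

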