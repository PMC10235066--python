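# Methods

`pacarbon` estimates the *additionally preserved aboveground carbon* of
protected areas (PAs): the difference between the carbon density observed
inside PAs and the density of ecologically similar unprotected
counterfactuals, multiplied by PA area. This note documents the model, the
estimator, the synthetic world used to validate both, and the numerical
choices that matter.

## The estimand and the matching design

Each 1-km cell carries mean lidar-derived structure metrics (RH98 height,
canopy cover, plant area index, aboveground biomass density AGBD in Mg/ha)
aggregated from quality-filtered footprints, with carbon density
AGCD = 0.49 · AGBD (the global average dry-wood carbon fraction). The causal
quantity of interest is the effect of protected status on AGCD.

Protection is not randomly assigned, so protected cells are matched 1:1
without replacement to unprotected counterfactual cells:

* **Exact strata.** A pair must agree exactly on land-cover class, country,
  ecoregion and biome.
* **Buffering.** No cell within 10 km of any PA boundary may serve as a
  control (mixed pixels, spillover, leakage); only cells entirely within a PA
  are treated.
* **Quality floor.** Footprints need `quality_flag == 1` and sensitivity
  ≥ 0.95; a cell needs ≥ 5 passing shots to enter matching at all.
* **Propensity score.** A maximum-likelihood logistic regression of
  protection on the ten z-scored quantitative covariates (elevation, slope,
  precipitation, min/max temperature, distances to city and road, travel
  time, population count and density), fitted by IRLS (tolerance 1e-8 on the
  coefficient step, ≤ 100 iterations; a ridge penalty of 1e-4 with a logged
  warning if the unpenalised fit diverges — the perfect-separation
  signature). The exactly-matched categoricals enter as dummy terms: they are
  balanced within pairs by construction, but omitting them would distort the
  quantitative coefficients whenever protection priority differs by class.
* **Caliper and support.** Candidates must lie in the overlap of the treated
  and control score ranges; the score-distance caliper is 0.2 × SD of the
  pooled logit scores, applied to logit-scale gaps (the scale the width is
  defined on). Treated cells are visited in descending score order, each
  taking the nearest-score eligible control (ties on the gap go to the lowest
  control cell id), which makes the greedy assignment deterministic.

## Effect estimation and uncertainty

Per pair, d_i = AGCD(protected) − AGCD(control). Matched pixels are pooled
per **country × biome** stratum; the stratum mean difference, multiplied by
the (dissolved, overlap-free) PA area in that stratum, gives additional
carbon, summed to country, continent, biome and global scales. A PA whose
country × biome stratum has no pairs inherits the continent × biome mean
(provenance recorded); a PA with neither contributes area but no carbon. The
per-PA *own*-pair mean is deliberately **not** used for totals — with a
handful of pairs it is noisy and selection-prone (we measured a −1.2 Mg C/ha
null bias when area-weighting own-pair means) — but it is retained for the
per-PA effectiveness classification, which is about the sign and magnitude
of each PA's own contrast.

The stratum SE is a PA-cluster-robust (CR1 sandwich) paired-difference
standard error: pairs inside one PA share fine-scale biomass anomalies, and
the iid sd(d)/√n understated the replicate-to-replicate spread by ~25% in
calibration runs. CR1 reduces exactly to sd(d)/√n when every pair is its own
cluster, so closed-form expectations for unclustered input still hold.
When aggregating, PAs that share a stratum estimate are perfectly correlated
(their SEs add linearly); independent strata combine in quadrature.

Total (not additional) PA carbon stock uses a hybrid variance: the sampling
variance of the 1-km cell means plus a relative model-error term
`(model_rel_se · mean)²` (default 0.02) standing in for footprint
biomass-model parameter error; the full hybrid estimator would require the
footprint model's parameter covariance, which is not available at desk
scale. The structure (sampling + model components, additive on the variance
scale) is preserved and each component is separately testable.

## Attribution and baseline stages

Each matched PA with loss data is classified from its own biomass difference
and the mean 2000–2019 forest-loss fractions on both sides: above +5 Mg/ha
it is *avoided deforestation* when loss is higher outside, else *enhanced
stocks* (optical loss products saturate and miss degradation, so "no loss
difference" does not rule out real carbon gains); within ±2.5 Mg/ha it is
*no additionality*; below −2.5 Mg/ha it is *encroachment* when loss is higher
inside, else *degradation*. The open band (2.5, 5] Mg/ha joins the positive
branch with `gap_band_flag` set; both thresholds are parameters.

The preferential-placement check compares a year-2000 baseline carbon map
between matched cells: per-PA mean baseline differences, a recent
(designated ≥ 2000) vs older contrast, and an ordinary least-squares
regression of the difference on PA age (2000 − status year, negative for
post-2000 designations) with a t-test on the slope, implemented from the
normal equations so the stage is self-contained. A positive age slope with
recent PAs near zero indicates carbon accrued *after* protection rather than
preferential siting.

## The synthetic world

The generator produces a flat equal-area plane of 1-km cells with known
ground truth; no geographic CRS is simulated. Design choices that matter:

* **Covariates** are Gaussian random fields mixing a coarse climate scale
  (σ ≈ grid/12) with a dominant fine texture (σ ≈ 0.8 cells). The fine share
  is deliberately large: it supplies close counterfactuals throughout the
  map and gives the propensity fit a large effective sample. Distances to
  cities and roads are genuinely geometric (point/line distance fields).
* **Suitability index.** A fixed linear combination of the z-scored
  covariates (wet, rugged, remote, low-pressure cells score high). It is an
  *exact* function of the observed covariates — conditioning on covariates
  removes all confounding, which is the assumption the matching design makes
  about the real data.
* **Placement.** PA seed cells are drawn with probability
  σ(confounding_strength · index + clustering · land-cover offset); shapes
  grow cell-by-cell preferring high-index frontier cells under dominant
  Gumbel noise (temperature 2.0). Protection probability therefore rises
  with suitability but keeps common support. The land-cover offset clusters
  PAs into park complexes (their buffers overlap instead of tiling the map)
  and, because land cover is exactly matched, cannot leak bias into pairs.
* **Biomass truth.** AGBD(cell) = clip(120 + 40·index + N(0, 15), 5, ∞)
  plus `pa_effect_delta` (default 10 Mg/ha) on protected cells. The
  unexplained heterogeneity is white at cell level; real landscapes also
  have spatially correlated unobserved variation, which matching cannot
  remove — passing tests therefore validate the estimator under
  selection-on-observables, not robustness to hidden confounding.
* **Footprints.** Parallel tracks at a random azimuth, 60 m along-track and
  600 m across-track spacing, with 30% of 5-km track segments dropped —
  this is what leaves some cells under the 5-shot minimum. Shot AGBD adds
  N(0, 25) truncated at zero; RH98, cover and PAI are saturating monotone
  transforms of AGBD with independent noise; quality flags fail at rate 0.1
  and sensitivity is Beta(30, 1).
* **Loss and baseline.** Per-cell loss fractions are Beta-distributed with
  mean 0.01 (protected) vs 0.05 (unprotected); the year-2000 baseline adds
  `baseline_growth_per_year` (default 0.25 Mg/ha AGBD) per pre-2000
  protected year, giving the placement check its age signal.

Placement strength (1.25) and clustering (1.5) were fixed by a 50-replicate
pilot grid chosen for common support and estimator calibration — the matched
estimator recovers the true effect within 2 SE in roughly 90–96% of
replicates (varying with the seed base), with the naive contrast
(≈ +10 Mg C/ha biased) essentially always worse. A small
positive residual bias (~+1 Mg C/ha) remains from greedy without-replacement
matching reaching down the control score distribution; it is well inside the
reported uncertainty at these problem sizes.

## Problem sizes and determinism

Validation studies use a 100 × 100 km world with 20 PAs (recovery, balance,
attribution; ~0.3 s per replicate) and a reduced 40 × 40 km world with
12 small PAs, two categories per exact-matching variable and a 3-km buffer
(coverage and null calibration; a 10-km buffer would exhaust so small a
control pool). Interval coverage of the nominal 95% global interval measures
0.93–0.97 across independent seed bases. All randomness flows from integer
seeds through `numpy` SeedSequence; identical configs reproduce bit-identical
worlds and reports.

## Known limitations

* Selection on observables is true by construction in the synthetic world;
  the method cannot detect hidden confounding in real data.
* The hybrid model-error term is a configurable stand-in, not a propagated
  footprint-model covariance.
* Greedy 1:1 nearest matching is not optimal assignment; the residual
  positive bias above is the price, and optimal/network-flow matching is out
  of scope.
* Loss fractions are generated at cell scale; the 30-m resampling path of
  real loss masks is not simulated.
* The five-class attribution depends on per-PA own-pair means and is only
  produced for PAs with at least one pair and loss data on both sides.
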