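# Methods

## Scope of the accounting

The package computes national, regional and global greenhouse-gas
emissions attributable to synthetic nitrogen fertilisers across the
whole product chain: manufacturing at the factory gate, transport from
the region of production to the region of consumption, direct soil N₂O
after application, indirect N₂O after volatilisation/redeposition and
after leaching/runoff, and the CO₂ released by urea hydrolysis. Stages
beyond this chain (farm machinery, irrigation, land-use change) are out
of scope, as is any spatially explicit treatment: all activity data are
national totals.

All internal arithmetic is in tonnes (N, product, CO₂e) and double
precision; reporting layers convert to Mt. The national total is by
construction the exact sum of the six components, and regional/global
figures are component-wise sums of national ones, so aggregation order
cannot change a result.

## Emission factors

Every multiplier is an `EFSpec`: name, mean, sd, optional min/max, and a
distribution family (normal or lognormal). Defaults carry provenance
labels — `paper` for values fixed by the accounting convention
(Tier 1 = 0.010 with range 0.001–0.018 and sd 0.009; wet 0.016 ± 0.003
in [0.013, 0.019]; dry 0.005 ± 0.006 in [−0.001, 0.011]; urea
hydrolysis 0.2 ± 0.1 t CO₂–C/t; GWP 265; manufacturing sd = 25% of the
mean, lognormal; transport sd = 50%, normal), `IPCC-2019-default` for
the indirect-emission factors, and `user` for config overrides. The
mass ratios 44/28 (N₂O–N → N₂O) and 44/12 (CO₂–C → CO₂) are constants,
not configuration.

The indirect factors are disaggregated by climate class:
FRAC_GASF = 0.11 (sd 0.05) for both classes, EF₄ = 0.014 (wet) / 0.005
(dry), FRAC_LEACH = 0.24 (wet) / 0 (dry), EF₅ = 0.011. Two deliberate
choices here:

* **Dry-climate leaching is identically zero.** The nominal convention
  would put sd 0.05 on every FRAC term, but a normal distribution
  centred at 0 and truncated to [0, 1] has a strictly positive mean, so
  a dry country would acquire leaching emissions from the uncertainty
  model alone. FRAC_LEACH(dry) therefore has sd 0: dry-climate leaching
  is zero both deterministically and under Monte Carlo.
* **EF₄/EF₅ dispersions** are set from the IPCC-style uncertainty
  ranges (EF₄ wet 0.011–0.017, dry 0.000–0.011; EF₅ 0.000–0.020) with
  sds of 0.003/0.005. They are explicit substitutes, configurable, and
  labelled as such in logs.

Countries without a known climate class fall back to "wet" with a
warning — the conservative (higher-EF) choice, which is also the
tie-break when wet and dry cropland areas are equal.

Manufacturing EFs resolve by (region of production, product); the
consuming country's own region is used, i.e. regional EFs are taken as
national. Ammonium-phosphate entries represent mono-ammonium phosphate
only. Transport EFs resolve by (origin region, destination region,
product) and are weighted by a sourcing mix (default: fully
intra-regional when no mix is supplied).

## Empirical direct EFs

A plot-level EF is the fertilised-minus-control cumulative flux divided
by the N applied. Although the underlying field convention reports the
bare flux difference, the division by N applied is required for the EF
to be the dimensionless fraction that the accounting (and every cited
EF value such as 0.010 or 0.016) expects. Plot EFs may be negative and
are retained: truncating them would bias country means upward, and even
the IPCC dry-climate range admits −0.001.

Aggregation conventions, where the procedure leaves latitude:

* country sd = sample sd (n−1) over plot EFs; a single-plot country
  gets sd 0 with a warning;
* regional mean = country means weighted by plots per country; regional
  sd = sd of the pooled plot EFs of member countries, reconstructed
  exactly from the per-country sufficient statistics (within-country
  sums of squares plus between-country deviations);
* global mean = regional means weighted by the number of countries
  contributing data per region (countries *with data*, not all
  countries of the region — flagged to the user as an interpretation);
  the global sd pools regional estimates with the same weights.

Empirical EFs are treated as lognormal downstream. When a Monte Carlo
run needs a country whose empirical sd is 0 (single plot), the regional
sd is substituted with a warning so the simulation does not treat that
country as certain.

Filtering of raw paired-plot tables keeps only synthetic-fertiliser
records with both fluxes and a positive N rate, drops exact duplicates
(same country, crop, rate and fluxes), and logs a per-reason count; an
empty result is an error, not an empty estimate.

## Activity data

Market-mix shares over the eight product groups (anhydrous ammonia, AN,
AS, CAN, urea, UAN, AP, NPK) may sum to less than 1; the uncovered
remainder is excluded from manufacturing/transport accounting (no
product detail exists for it) but included in all field components,
which therefore use total national N consumption. This asymmetry means
production/trade emissions are a mild underestimate by construction.
Nitrogen is conserved exactly in allocation: allocated + remainder =
consumption.

Urea-equivalent tonnage for the hydrolysis term is
`urea_N / 0.466 + 0.35 × (UAN_N / 0.30)`: nutrient-to-product
conversion by N content, plus the average urea fraction contained in
UAN solutions. N contents for the other product groups (needed to put
manufacturing/transport EFs on a product basis) are typical industry
values and configurable.

## Monte Carlo propagation

5,000 draws per EF by default. Design choices:

* **Correlation structure**: one draw per EF per iteration, shared by
  every country using that EF — full correlation within an EF,
  independence across EFs. This reflects uncertainty about the factor
  itself (not plot-to-plot noise) and produces the observed pattern
  that aggregate CVs sit below the largest component CV.
* **Lognormal parameterisation**: moment-matched so the natural-scale
  mean and sd of the draws equal the spec's (σ² = ln(1 + cv²),
  μ = ln(mean) − σ²/2). A lognormal with mean ≤ 0 is an error with an
  instruction to override the pdf.
* **Bounds by rejection**: out-of-range draws are redrawn, never
  clamped, because clamping creates probability atoms at the bounds and
  biases means. (Truncation does shift the mean of an asymmetric
  bounded spec slightly relative to its nominal mean; that is a
  property of the specified distribution, not an artefact.)
* **Summaries** are sample mean and sample sd (ddof 1) over draws; CV
  is 100·sd/mean, reported missing when the mean is 0. In the
  degenerate all-sds-zero case the summary short-circuits to the exact
  constant so Monte Carlo output equals the deterministic engine
  bit-for-bit.
* Draws are generated per EF in sorted-name order from one seeded
  generator, so results are reproducible from (inputs, n, seed) alone;
  the seed is recorded in every output row, and the CLI logs a random
  seed when none is given.

The engine's component functions broadcast over numpy arrays, so the
Monte Carlo pushes draw vectors through the *same* arithmetic as the
deterministic path rather than a re-implementation.

Uncertainty on activity data is deliberately not modelled (no
information to support it), and no variance decomposition is attempted.

## Indicators and trends

Carbon intensity (t CO₂e/t N), per-capita footprint (kg CO₂e/person)
and fertilisation rate (kg N/ha) are plain ratios with zero-denominator
errors. Component shares are percentages of the component sum and total
100 exactly. The growth rate is the two-point formula
(V₁/V₀ − 1) × 100 with a configurable lag (default 1 year, matching its
use on annual series); moving averages are centred with incomplete edge
windows dropped; series are never gap-filled, and a rate spanning a
missing year is reported missing. Where smoothing and rates combine,
the order is smooth first, then rate.

## Synthetic world generator

The generator emulates the *structure* of the real inputs, not their
values: 9 regions × 5 countries (default), world consumption 100 Mt N,
Dirichlet market mixes covering 96% of N, wet/dry classes with
region-specific probabilities, and regional true-EF medians spanning
0.003 (Africa, Russian Commonwealth) to 0.024 (Latin America) with a
lognormal country spread (log-sd 0.3). Paired-plot datasets default to
1,602 records allocated unevenly (North America + Europe > 50% of
plots, mimicking the documented coverage bias), with multiplicative
lognormal plot-level dispersion (log-sd 0.8, i.e. a plot-level CV near
1, realistic for cumulative flux experiments), N rates uniform in
50–250 kg N/ha and an independent positive control-plot baseline so the
paired subtraction is genuinely exercised. Manufacturing tables use
per-product baseline EFs (≈1.2–2.8 t CO₂e/t product) with regional
lognormal factors; transport lanes are cheap intra-regionally (~0.05
t CO₂e/t) and distance-like across regions; sourcing is ~79%
intra-regional. Historical series grow exponentially with a growth rate
decaying from 15%/yr to 2.5%/yr (time constant 12 y for N use).

All draws come from one master seed via named substreams (activity,
plots, EF tables, sourcing, trends), so changing one generator's
parameters leaves the others' draws untouched, and a bundle is
byte-for-byte reproducible from (spec, seed).

Because the generator is synthetic-by-construction, passing tests show
that the estimators and the accounting are correct *given* the model's
assumptions (mean-preserving lognormal plot noise, independent
controls, uniform regional mixes); they say nothing about real-world EF
heterogeneity across crops, soils or fertiliser regimes, which the
generator does not attempt to model.

## Problem sizes and numerical checks

The default test and acceptance workloads are sized for interactive
runs: the full synthetic world is 45 countries, Monte Carlo uses 5,000
draws where calibration is being checked (matching the method's own
draw count) and a few hundred draws for pure reproducibility checks;
oracle-equivalence uses twenty random ≤5-country inventories against an
independently written single-expression implementation at 1e-9 relative
tolerance; EF parameter recovery uses truth 0.012 with 200
plots/country over 20 seeds (observed mean absolute error ≈ 0.0006,
bound 0.002). Rejection sampling caps at 1,000 redraw rounds before
raising a numerical error.

## Known limitations

* Manufacturing/transport EF *values* are user- or
  synthetically-supplied; the registry defines slots and uncertainty
  conventions only.
* Country climate is a single predominant class; countries straddling
  zones are forced to one.
* The empirical EF estimator is a weighted mean — no covariate
  modelling (crop, rate, soil), no meta-analytic weighting by study
  precision.
* The 4% of N outside the eight product groups has no
  manufacturing/transport footprint in the accounting.
* Nitrogen-use-efficiency metrics are not computed.
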