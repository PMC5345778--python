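# Methods

## Model structure

`mpabioecon` simulates a single harvested stock (parameterized for Canadian
Atlantic cod) on a regular grid of 400 km² cells with one-year time steps.
The population is held as super-individuals — one real-valued count per
(cell, age, maturity-state) bucket — because at 2.5×10⁸ initial fish,
per-fish simulation adds nothing at cohort resolution: length and weight are
deterministic in age, and every stochastic process in the model acts at the
cell-year or cohort level.

The annual cycle runs: ageing/growth → spawning → larval mortality → larval
dispersal → Beverton–Holt recruitment → adult natural mortality → adult
migration → carrying-capacity enforcement → survey → moratorium check →
quota → harvest → economics. Natural mortality precedes harvest within the
year; the order is a documented choice (`mortality_before_harvest`) and can
be switched for exploration.

Recruits enter the population as age-1 fish: the egg → age-1 transition is
represented entirely by the larval-mortality draw plus the Beverton–Holt
map, so first-year mortality is not double-counted against the adult rate.
Maturation is implemented as deterministic cohort fractions — the immature
bucket of a cohort of new age *a* transfers the incremental probability
(P(a) − P(a−1)) / (1 − P(a−1)) to the mature bucket — which reproduces the
logistic ogive exactly and is the cohort-level rendering of per-individual
Bernoulli maturation. Fish never revert to immature. Ages are capped at 25
with a plus-group (annual survival ≈ 0.41 makes the truncated mass
negligible).

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| k (VB growth) | 0.13 | yr⁻¹ | growth coefficient |
| L∞, t₀ | 120, 0 | cm, yr | not printed in the source material; config values |
| length–weight a, b | 0.0085, 3.0 | g cm⁻ᵇ | standard cod-like allometry; config values |
| maturity midpoint | 4 | yr | steepness ln(99)/2 puts 1%/99% at ages 2/6 |
| fecundity | 5×10⁵ | eggs kg⁻¹ female | sex ratio fixed at 0.5 |
| larval mortality | Beta(1000, 1.2) | — | mean 99.88%, drawn per cell-year |
| adult mortality | N(0.5938, 0.0517) | yr⁻¹ | clipped to [0, 1], per cell-year |
| carrying capacity | N(0.43, 0.38) | t km⁻² | clipped at 0 (see below) |
| bh_slope | 0.03 | recruit per settler | see calibration below |
| larval e-fold | 156 | km | net scale of a 2 cm s⁻¹ × 90 d walk |
| adult e-fold | 272 | km | migration from age 6 |
| F_MSY, quota fraction | 0.28, 2/3 | yr⁻¹, — | quota = ⅔ F_MSY × estimate |
| survey fraction | 0.001 | of EEZ cells | minimum one cell |
| size/age limits | 38 cm, 4 yr | — | below either, never caught |
| moratorium threshold | 10 000 | t | strict `<`, true biomass |
| price | 1.24 | CAD kg⁻¹ | landed value |
| profitability ratio | 1.6 | — | landed value / operating cost at baseline |
| distance-variable cost share | 0.6 | — | fuel + labour share; unprinted, swept in sensitivity |
| SDR set | 1.5, 3, 6 | % | discount rates |

### Beverton–Holt anchoring and the bh_slope calibration

The recruitment asymptote is tied to habitat quality: R_max for a cell is
K·area divided by the equilibrium standing biomass sustained by one recruit
per year, Σₐ s^(a−1) w(a) with s = 1 − 0.5938. This is the only anchoring
under which sustained maximal recruitment actually holds a cell near its
carrying capacity. The low-density settler→recruit survival (`bh_slope`) is
not a published quantity. It was calibrated once so that the simulated
fishery sits in the depleted, moratorium-prone regime the study system
describes — Status-Quo biomass of order 10–15 kt drifting near the 10 kt
closure threshold, annual catch near 3 kt, moratorium probability of a few
percent, and NPVs of tens of millions of CAD — while the unfished stock
still persists and equilibrates at a large fraction of total K. The default
0.03 gives an unfished net reproductive rate modestly above replacement,
consistent with a stock that recovers only slowly when fishing stops.
Because Beverton–Holt regulation with a finite slope equilibrates below the
hard capacity cap, the unfished attractor is a stable fraction (roughly
one-third to one-half on the test domains) of ΣK·area, not ΣK itself; the
tests assert that band explicitly.

## The synthetic domain

The default domain is a cross-shelf transect: 80 × 7 cells (≈550 water
cells, all EEZ) with a contiguous, optionally irregular land margin along
the short western edge, giving ~1600 km of offshore extent — about ten
larval e-folds. This geometry preserves the scale relations of the real
system that the method depends on: the fleet's economic range covers only
part of the EEZ, dispersal kernels are local relative to the domain, and
closures can therefore reshape the spatial distribution of the stock rather
than merely displace effort. A compact square with the same cell count and
area compresses the seascape to ~2 e-folds and washes those mechanisms out.

Habitat suitability is smoothed uniform noise (Gaussian kernel, σ = 2 cells)
rescaled to [0, 1] over water; breeding sites are the top 5% of water cells
by suitability score, weighted toward shore by (1 − d/d_max)^bias with
bias = 2 (spawning grounds on the inner shelf). Carrying capacity is drawn
i.i.d. per water cell and clipped at zero rather than redrawn, which puts a
small atom at 0 and raises the field mean slightly above 0.43; the
untruncated mean is exactly 0.43 and is what the acceptance script reports.

What the generator does **not** emulate: real coastline geometry, bathymetry
or temperature structure, habitat–capacity correlation, ocean currents, and
directional or homing migration. Passing tests on this domain demonstrate
that the mechanisms (spillover, serial depletion, quota feedback,
discounting) interact as described — not that the model is calibrated to any
real stock's absolute numbers.

## Management and economics

The survey samples max(1, round(0.001 × EEZ cells)) cells uniformly without
replacement and scales the mean density to the EEZ — design-unbiased but
deliberately noisy at this sampling intensity, which propagates realistic
assessment error into the quota. The moratorium triggers on **true** total
biomass (strict `<` at 10 kt), re-evaluated annually; a config switch
triggers on the estimate instead. Harvest is distance-greedy: unprotected
cells in ascending distance-to-shore order (ties by cell id), each stripped
of fishable biomass until a proportional partial take closes the quota.
"Distance travelled" is operationalized as the fished cell's
distance-to-shore.

Operating cost is C = (R / 1.6) × [(1 − φ) + φ·d/d₀] with φ the
distance-variable share (0.6) and d₀ the Status-Quo catch-weighted mean
distance. In experiments d₀ is computed by pooling the Status-Quo replicates
and is then held fixed across scenarios; a single run without a configured
baseline uses its own mean distance. NPV is evaluated over years t = 1..50
of the 51-year run (both horizon conventions in the source material are
supported via `npv_start_t` / `npv_horizon`).

Scenario placement is greedy and sequential (farthest-point for
max-distance; |spacing − 75 km| minimization for fixed-distance; breeding
cells first, then spacing-constrained additions within suitable habitat for
targeted), with all ties broken by ascending cell id. MPA "location" for
spacing is the centroid of its cells. Scenarios are redrawn per replicate by
default (`redraw_scenarios=False` pins them), and replicate seeds are shared
across scenarios so all comparisons are paired.

## Numerical choices

* Deterministic kernel transport (expectation) is the default for both
  dispersal stages; multinomial sampling is available and its mean is tested
  against the deterministic mode. The per-particle random walk is kept as an
  independent oracle for the kernel scale.
* Carrying-capacity enforcement scales all of a cell's buckets uniformly, so
  the age structure is preserved under crowding.
* The maturation increment is set to 1 where the ogive saturates in floating
  point (P > 1 − 10⁻⁹).
* Seeds: every stochastic component derives from `numpy.random.SeedSequence`
  spawning, so a master seed fixes the domain, scenario draws, and all
  within-year draws bit-for-bit.

## Known limitations

Single species; no Allee effect, no species interactions, no size-dependent
natural mortality, no fleet dynamics, discards or compliance behaviour, and
no MPA establishment/enforcement costs. Habitat suitability influences only
targeted-scenario placement, not settlement or survival, so the targeted
design's advantage flows entirely through which cells it removes from the
fishery and the spillover they generate. Fishing distances on the synthetic
transect are larger than a realistic shelf fishery's because the domain is
one long corridor; distance enters the results only relative to the
Status-Quo baseline.
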