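# Methods

This note documents the models, assumptions, parameters and numerical
choices behind the package, and what the synthetic-world tests do and do
not establish about real data.

## Attribution model and its assumptions

The core object is a sensitivity field λ[receptor, species, cell]
(µg m⁻³ of the receptor's population-weighted PM2.5 exposure per
Tg yr⁻¹ emitted in the cell), the kind of product a reverse-mode
(adjoint) chemical transport model produces once per receptor country.
The package treats λ as a *data contract*: any provider with those units
and axes works. Exposure attribution is the exact linear contraction
ΔJ[m, I] = Σ_k λ[m, k, I] · ΔE[k, I], so it inherits the central
limitation of linearized source–receptor work: secondary inorganic
aerosol chemistry is nonlinear, and a linear response can understate the
benefit of large emission cuts. The package makes no attempt to model
second-order chemistry; the marginal-vs-joint non-additivity diagnostic
(below) quantifies only the *health-side* nonlinearity.

Emission deltas are scenario minus baseline in a fixed analysis year,
with the convention that reductions are negative ΔE and produce negative
ΔJ and positive deaths avoided.

## Emission processing

Emissions are stored as annual mass per cell (Tg yr⁻¹), never flux
density, which turns every conservation statement into a plain sum.
Sector aggregation defaults to the nine anthropogenic non-biomass-burning
sectors (agriculture, aviation, residential and commercial, power plants,
industry, international shipping, solvents, surface transportation,
waste); biomass-burning sectors are excluded by default but are ordinary
sectors if explicitly included — the exclusion is a default, not a rule.

Conservative regridding splits each source cell's mass among target cells
in proportion to fractional area overlap, with the latitude overlap
measured in sin(lat) so the split is areally exact on the sphere. Grids
are described by cell-edge arrays (latitude ascending, longitude in
[−180, 180]); cell membership is half-open (west/south edges inclusive) so
adjacent cells never double-count. An optional fractional country mask is
applied at the fine resolution *before* overlap weighting, mirroring a
per-country regrid of an inventory; a binary mask is the special case of
fractions in {0, 1}. Unmasked regridding conserves total mass to float
rounding whenever the target covers the source; the test suite checks
this against a brute-force rectangle-intersection oracle.

## Health model

Avoided deaths follow the attributable-fraction form
y0 · (1 − 1/RR(z)) · Pop per outcome × age group, summed after
evaluation (never on pre-aggregated rates). Choices:

- **RR interpolation** is linear in exposure between breakpoints and
  constant beyond the last breakpoint. The first breakpoint is the
  theoretical-minimum-risk exposure level (TMREL), where RR = 1; below it
  there is no excess risk. The TMREL is a configurable parameter
  (default 4.15 µg m⁻³, mid-range of published GBD 2019 draws).
- **Twice-evaluated differencing**: a cell's co-benefit is
  M(J_m) − M(J_m + ΔJ[m, I]) with J_m the receptor's baseline
  population-weighted exposure. J_m is an explicit input table (in real
  use, a satellite-constrained base-year exposure), held fixed for the
  analysis year; the package never recomputes it.
- **Marginal vs joint**: the per-cell marginal difference is the
  canonical co-benefit; summed over cells it differs from the joint
  removal M(J_m) − M(J_m + Σ_I ΔJ) by the curvature of the RR curve.
  `nonadditivity()` reports both and their residual. On a locally linear
  RR segment the two agree exactly; for perturbations below ~1% of
  baseline exposure the residual stays below 0.5% on the default worlds.
- **Uncertainty** runs the full calculation three times with
  bound-consistent RR curves and baseline rates (lower/central/upper).
  Ordered inputs give ordered outputs because the map is monotone in both.
  A missing bound falls back to central with a warning rather than
  failing, since partial GBD exports are common.
- **Clamping**: pathological perturbations that would push exposure below
  zero are clamped at zero with a logged warning; this caps a cell's
  benefit at the receptor's full attributable burden.

Baseline rates and population are taken as already projected to the
analysis year; demographic projection is out of scope.

## Inequality metrics

TF, EXC and TEC operate on per-cell deaths avoided by default (the
health-based reading used for reporting), and work identically on
exposure contributions if passed those instead. Conventions:

- Fractional border cells count toward "inside" in proportion to their
  mask fraction, which makes the decomposition exact: domestic + foreign
  exchanges + unattributed = receptor total (audited at 1e-10 relative
  on every pipeline run; exceeding it aborts with a nonzero exit).
- Cells claimed by no country form an explicit `__unattributed__`
  pseudo-source. It counts toward TF numerators (it is external to every
  country) but is excluded from pairwise EXC/TEC, which need two
  countries.
- For a group (region), "external" means outside the whole group:
  intra-group foreign contributions are internal. A group's TF is the
  weighted identity Σ external / Σ total over members — *not* the mean of
  member TFs, and not bounded by them unless member totals are equal.
  The global TF is the same identity over all countries; the unweighted
  all-country mean TF is reported as a separate statistic.
- Mixed-sign contributions (some emissions increase) are summed as
  signed values to preserve conservation; a metric whose ratio leaves
  [0, 1] carries an `out_of_range` flag instead of being silently
  clipped. Zero denominators flag `undefined` and are excluded from
  averages.
- TEC is computed once per unordered pair (the lexicographically smaller
  label gets the division, the partner its complement), a tie-break that
  makes tec(m, n) + tec(n, m) = 1 hold exactly in floating point rather
  than to rounding.
- Stratified summaries (e.g. bottom-k vs top-k countries by HDI) sort
  stably with the country id as tiebreak, so selections are
  deterministic.

## Synthetic worlds: what they emulate, and what they don't

The generator produces, from one integer seed, a world that is
byte-identical across reruns (each stage derives its RNG from the seed
plus a fixed stage salt, so stages can also be regenerated independently):

- **Grid**: default 9 × 12 global cells — a desk-scale stand-in for a
  2° × 2.5° transport-model grid (91 × 144, also supported). Cell areas
  use the spherical-rectangle formula and partition the sphere.
- **Countries**: seeded multi-source region growing (4-connected,
  wrapping in longitude on global grids) guarantees contiguity by
  construction; coastal cells get fractions in [0.5, 1) to exercise the
  fractional-mask paths. Default 10 countries in 3 longitude-banded
  regions, with synthetic HDI draws in [0.30, 0.95] and a GDP rank
  permutation.
- **Sensitivities**: per receptor, a Gaussian kernel in great-circle
  distance from the country's area-weighted centroid, with σ =
  `kernel_scale` (default 2) grid cells. The kernel center is displaced
  `wind_skew − 1` cells *west* of the centroid (default wind_skew 2), so
  sources upwind (west) of a receptor contribute more — the simplest
  mechanism that reproduces the prevailing-westerlies asymmetry in which
  pollution lands east of its source. wind_skew = 1 recovers an
  east–west symmetric kernel. Species amplitudes differ (primary
  carbonaceous aerosol more potent per Tg than secondary-inorganic
  precursors), scaled by a mild per-receptor lognormal factor.
- **Scenarios**: the baseline allocates realistic order-of-magnitude
  global species totals (e.g. ~110 Tg yr⁻¹ NOₓ, ~8 Tg yr⁻¹ BC) across
  claimed cells in proportion to coverage × lognormal noise; a mitigation
  scenario scales each cell by one minus the mask-weighted mean of its
  countries' reduction fractions. Demo scenarios use 25% ("moderate")
  and 60% ("strong") uniform cuts, spanning weak-to-deep mitigation.
- **Health tables**: RR curves are saturating exponentials
  1 + a(1 − exp(−(z − tmrel)/b)) sampled at fixed breakpoints — monotone,
  concave, RR(tmrel) = 1 — with a ∈ [0.3, 1.5] and b ∈ [30, 80] µg m⁻³
  per outcome × age, and lower/central/upper scaling of a by
  0.75/1/1.3. Baseline rates use order-of-magnitude cause-specific
  values (six outcomes: ischemic heart disease, stroke, COPD, lower
  respiratory infection, lung cancer, type-2 diabetes; three adult age
  bands) with 0.8×/1.25× bounds; baseline exposures are uniform in
  [15, 60] µg m⁻³, well above the TMREL.

Alongside the fields, `SyntheticTruth` stores quantities planted by
construction — kernel integrals and source × receptor sensitivity mass —
so recovery tests compare the pipeline against sums that never ran
through it.

**What passing tests show**: that the attribution algebra, conservation
identities, health differencing, metric definitions and their interfaces
are implemented correctly, at any grid size. **What they do not show**:
that real-world TF or exchange values are reproduced. Synthetic kernels
are isotropic-plus-shift Gaussians, emissions have no sectoral or
urban structure, populations and rates are draws, and the grid is
coarse; quantities like the global TF are therefore structurally similar
to, but numerically unrelated to, estimates from real adjoint
sensitivities and inventories.

## Numerical choices and degenerate inputs

- Conservation audit tolerance 1e-10 relative (pipeline aborts above it;
  CLI exit code 3).
- Attribution-vs-finite-difference agreement is checked at 1e-12
  relative around a zero emission baseline, where the linear forward map
  makes the comparison free of cancellation.
- Degenerate grids (single row/column, inverted bounds), non-monotone RR
  tables, reduction fractions outside [0, 1], mismatched grids/species
  and unknown labels all raise validation errors (CLI exit code 2)
  rather than propagating NaNs.
- Zero-total receptors yield TF = NaN with an `undefined` flag and are
  excluded from mean-TF statistics.

## Problem sizes

Default test and demo worlds use 9 × 12 grids with 8–10 countries, six
outcomes and three age groups; the conservation acceptance check runs 20
such worlds and the acceptance script five. These sizes make the full
suite and the acceptance script run in seconds while exercising every
code path, including fractional cells, unattributed territory, and all
three uncertainty bounds; the implementation is vectorized and has no
dimension limits beyond memory.

## Known limitations

- Linear chemistry: no second-order response of secondary inorganic
  aerosol; co-benefits of deep cuts are likely conservative in real use.
- Baseline exposure is static: the base-year cost-function exposure is
  reused for the analysis year.
- Health scope: mortality only, six outcomes; morbidity, demographic
  uncertainty and projection uncertainty are not modelled.
- The synthetic generator does not emulate sectoral emission structure,
  urbanization, or realistic demographics, and its HDI/GDP labels are
  synthetic ranks.
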