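# Methods

This note records the models implemented in `rootslope`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data can and cannot establish.

## Individual soil volume

The ISV envelope is built from three extents per plant: maximum rooting
radius upslope and downslope of the stem, and maximum rooting depth. For
radially spreading root systems the below-ground envelope is half an
ellipsoid of revolution (two horizontal semi-axes equal to the radius,
vertical semi-axis equal to the depth); splitting it at the vertical plane
through the stem gives one quarter-ellipsoid per slope sector,
`V = (1/3)πr²z`. Species rooting along a creeping or underground stem get a
quarter of an elliptic cylinder per sector instead: axis along the stem
(length `L`, which must be measured — it is never inferred), horizontal
semi-axis `r`, vertical semi-axis `z`, `V = (π/4)rzL`; for `r = z` this is
the classic quarter circular cylinder.

Per-layer volumes are obtained by *slab slicing*: the sector solid is cut
by horizontal planes at multiples of the layer height (default 0.10 m,
half-open layers `[0,10) cm, [10,20) cm, …` perpendicular to the soil
surface). Closed forms are used for both solids
(`(πr²/2)[(z₂−z₁) − (z₂³−z₁³)/3z²]` for the ellipsoid sector), and the
slices sum to the total exactly; tests additionally verify both solids
against Monte-Carlo volume integration at 10⁶ points (0.5% tolerance).
Proportional allocation of the total across layers was the alternative;
slab slicing was chosen because it follows from the geometry with no free
choices. `ISV/Dc` divides the total (m³) by the collar diameter (cm),
making differently sized individuals comparable.

## Root area ratio

RAR within a layer is computed as cumulated root volume over soil volume,
`Σ V_r/(A·h)`, which equals the cross-sectional-area formulation when roots
cross the layer perpendicularly (the assumption tests verify explicitly).
Segment volume defaults to the cylinder `π(d/2)²·ℓ` when not measured.
Diameter classes split at 2 mm; the boundary diameter goes to the coarse
class (the printed class intervals overlap at exactly 2 mm, and a closed
coarse class keeps the partition exhaustive and disjoint). The reference
area `A` is supplied by the caller; the pipeline's species-level trait uses
the plant's own ISV envelope as the soil volume (total root volume / ISV),
so no arbitrary footprint needs choosing; a fixed reference area can be
passed instead.

## Tensile analysis

`T_max = F_break/CSA` with CSA from the mean of three diameter readings
under a circular-section assumption (three readings are what tensile
protocols record; depth/width ellipticity is only measured for bending).
`ε_ult = 100·δ_break/L₀` uses the raw displacement origin (no toe
correction — the toe region is part of the recorded stretching phase).

**Break detection.** The break is the global force maximum, accepted only
if force subsequently drops by ≥ 30% of the peak; a record that ends still
ascending (or never shows the drop) is flagged `no_break_detected` and
excluded. The 30% drop is a conservative default separating failure from
load fluctuation; it is configurable.

**Elastic region.** The tensile (and bending) modulus comes from the
best-R² linear window among points with force between 10% and 40% of peak,
scanned over all window lengths ≥ 3 points (ties prefer longer windows so
exact lines use all points). The band bounds are configurable; they encode
"linear slope shortly after the start of the test" while skipping the toe.

**Validity.** A result is excluded from every downstream fit if the
specimen failed outside the middle third, slipped in the clamps, lacked a
detectable break, or had gauge length < 30 × mean diameter (the standard
span requirement for root tension).

**Power law.** `T_max = α·D^−β` is fitted by OLS on `(log D, log T_max)` —
not nonlinear least squares — so the reported R² is the log-log one
conventional in root-strength plots, and multiplicative (lognormal) stress
noise is homoskedastic in the fitting space. `β > 0` means strength
decreasing with diameter; negative values (strength increasing with
diameter) occur and are preserved.

## Bending analysis

`I = πwd³/64` about the neutral axis for an elliptical section (depth
diameter `d` along the load, width `w`); reduces to `πd⁴/64` for circular
roots, which tests check to machine precision. `E = k·L³/(48I)` from the
initial load–deflection stiffness `k` (same window selection as above);
`EI = E·I` reported in kN·mm². Spans shorter than 20 × depth diameter are
flagged (shear deformation contaminates short-beam flexure); 20 is standard
flexural-test practice — the tension threshold (30×) is protocol-printed,
the bending one is a package default and configurable.

## Soil physical traits

`w_i = 100(m_i−m_d)/m_d`, `w_s = 100(m_s−m_d)/m_d` (gravimetric, % of dry
mass), `ρ_d = m_d/v`. Mass-ordering violations (`m_s ≥ m_i ≥ m_d > 0`) are
rejected naming the offending pair. The Mohr–Coulomb envelope is fitted on
stresses (kPa), not forces, so outputs carry field-table units directly;
`σ = N/A_box`, `τ_peak = F_peak/A_box` with the 60 mm × 60 mm box default.
A negative fitted cohesion is reported as-is with a warning, never clipped:
clipping would bias site comparisons on very weak soils. In-situ vane and
penetrometer readings are passed through as mean ± s.e. only.

A statistical caveat the tests encode: with normal stresses at
55.6–138.9 kPa (the 200/300/500 N loads), the cohesion is the intercept of
an extrapolation to zero normal stress. Under 10% multiplicative shear
noise, a single 8-triplet set determines `c` only to roughly ±3–4 kPa
(Monte-Carlo), however the OLS estimator is unbiased: recovery tests
therefore assert exactness on noiseless sets per-set, and ensemble-mean
recovery within 10% over seeded replicate sets under noise, plus a
dispersion bound on the friction angle (which the design pins well).

## Score synthesis

Scores are 1 (poor), 2 (average), 3 (good) per trait, with one
lower-is-better trait (ultimate strain: short, mostly reversible
deformation is desirable; all others higher-is-better). Pairs combine via
the symmetric rule table `1⊗1=1, 3⊗3=3, 1⊗3=2, 1⊗2=1, 3⊗2=3`, extended
with `2⊗2=2` — not in the stated rule list but forced by the reference
scorecard's `2*2 = 2` cells, as is symmetry by its `1*2 = 1` / `2*1 = 1`
pair. The composite tension score is `fine-RAR ⊗ T_max`, composite bending
`coarse-RAR ⊗ EI`: the `×` in the trait definitions denotes rule
combination, not arithmetic product (the scorecard's `3*3 = 3` cells rule
the product out). An arithmetic-product mode is deliberately not offered.

The operator is non-associative (`fold(1,1,3) = 2` but `fold(1,3,1) = 1`),
so three-trait globals are ordered left folds and the fold order is part of
the configuration. Defaults:

* abundance: stems·m⁻², ISV/Dc, RAR (row order);
* mechanical: tension composite, bending composite, ε_ult (row order);
* physiological: **ε_ult, cellulose, nitrogen** — *not* the row order.

The physiological deviation is a derivation, reproducible with the shipped
fixture: folding in row order (ε_ult, N, CELL) yields 2 for both
*F. tikoua* (printed 1: fold(1,1,3)=2) and *P. stricta* (printed 3:
fold(3,3,1)=2), while (ε_ult, CELL, N) reproduces all nine printed globals;
the test suite pins both facts. The fixture ships the strain trait with two
score columns (mechanical and physiological roles) because the reference
scorecard assigns them independently; they are carried verbatim, without
reconciliation.

**Tertile mode.** The original study never states how raw trait values map
to 1/2/3, so tertile assignment (rank per trait respecting polarity, cut
into thirds, average-rank ties broken lexicographically by species name —
deterministic and seedless) is provided for new data. Tertile scores on
synthetic data are *not* claimed to match the reference assignments.

**Placement.** A species' placement on a hotspot follows a rule cascade
over its trait biases: upslope-biased desirable traits → top (those roots
cross the potential shear plane when the plant sits above it);
downslope-biased → toe; deep-concentrated without sector bias → middle
(reinforcing the shear zone at depth); shallow-concentrated → top or toe;
otherwise unclassified. Biases must cite at least one evidence statement.
The pipeline derives profiles from computed traits with thresholds (a
sector holding > 60% of ISV; > 50% of root volume below 30 cm; > 70% in the
top layer) that are package defaults, configurable, and intentionally
conservative — most species come out unclassified unless the bias is
pronounced.

## Synthetic data

The generator emulates the *statistical shape* of the field records, not
their values: per-species archetypes (growth form, radial/linear layout,
depth/radius ranges, lognormal diameter distribution, power-law strength
with exponent of either sign, mean strain, chemistry means) are qualitative
stand-ins parameterized from the nine described root-system morphologies.
Tensile curves are piecewise — toe (stretching), linear elastic, linear
plastic to break, then a post-break drop — with the peak placed exactly at
the drawn `(T_max, ε_ult)`; bending curves start exactly linear at
`k = 48EI/L³`; shear points sit on the Mohr–Coulomb line with additive
Gaussian noise `sd = cv·τ`; quadrat counts are Poisson; strength noise is
multiplicative lognormal with unit median. Segment lengths/branching have
no published distributional basis; gamma lengths and exponentially decaying
per-layer counts are explicitly arbitrary fixtures.

Consequences: noiseless outputs round-trip through the analysis exactly
(the tests' strongest lever), and parameter recovery under noise checks the
estimators, not the field biology. Passing tests show the pipeline is
correct and well-conditioned; they say nothing about how the real nine
species would score from re-measured data. Real curves' non-ideal features
— toe nonlinearity varying per root, partial breaks, load-cell drift,
non-elliptical sections — are not emulated.

Problem sizes used by the default suites: tensile recovery at n = 200
curves × 100 seeded replicates (cv = 0.2, within-10% in ≥ 95%); shear
ensembles of a few hundred 8-triplet sets; Monte-Carlo geometry oracles at
10⁶ points over a 5 × 5 extent grid. The stock simulation uses 6 plants,
50 tensile / 15 bending curves and 8 shear triplets per species-site, a
hotspot truth of c = 3 kPa, φ = 25°, and growth-form-dependent stem
densities (herbs ~6 m⁻², planted shrubs < 1 m⁻²).

## Known limitations

* No slope-stability (factor-of-safety) computation, no root-cohesion
  models; the outputs are trait scores, not reinforcement estimates.
* No elastic/plastic energy decomposition beyond modulus extraction; no
  clamp-slippage physics; no 3D root reconstruction or branching topology.
* Scoring offers no trait weighting or uncertainty propagation; globals
  inherit the rule table's non-associativity, so fold orders must be stated
  with any result.
* The shipped fixture encodes one study's assignments; applying the tertile
  mode to other data embeds that data's ranking only.
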