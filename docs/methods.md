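# Methods

## Scope and data model

The package analyses a fish THg survey held as a tidy table: one row per
specimen × organ with species, trophic guild (predator/omnivore), reservoir
(Kardzhali, Studen Kladenets, Ivaylovgrad), total length TL (cm), total
weight TW (g), organ, and total mercury in mg·kg⁻¹ wet weight. Nine organ
tokens are carried (muscle, liver, kidneys, spleen, gills, bones, gonads,
hearts, skin): the dissection protocol behind the emulated survey lists
seven tissues while its summaries report nine, and the broader set costs
nothing. Concentrations are mg·kg⁻¹ ww internally without exception;
µg·kg⁻¹ is accepted only at the I/O boundary through an explicit `unit`
column and converted on read, because a mixed-unit pipeline is the easiest
way to a silent 1000× error.

Values below the analytical detection limit (LOD = 0.00005 mg·kg⁻¹) are
stored as LOD/2 with a `below_lod` flag — the standard substitution; the
exact rule used to produce the emulated survey's printed 0.000 spleen
minimum is not recoverable, so LOD/2 is adopted as the package's own
convention.

Size classes split a species at its median TW: strictly above the median is
"large", everything else (including a specimen tied with the median) is
"small". Ties go to the small class deliberately: small fish carry less
mercury here, so the tie rule errs on the side of stricter advisories.

## Synthetic survey generator

The generator exists so that every downstream stage — statistics,
deterministic risk, Monte Carlo — is testable against known ground truth.
For a specimen of species *s* in reservoir *r*, organ *o*:

```
TL  = TLmed_s · exp(η),              η ~ N(0, σ_TL²),  σ_TL = 0.12
TW  = (TWmed_s / TLmed_s³) · TL³ · exp(ν),   ν ~ N(0, 0.05²)
ln C = loc_o + α_o (ln m_s − z̄) + ln g_r + β_{s,o}(TL − TLmed_s) + ε,
       ε ~ N(0, σ_o²)
```

Lognormal organ distributions were chosen because concentrations are
positive and right-skewed (every organ's published mean exceeds its
median). TW follows an isometric power law (exponent 3) through the
published species TL/TW medians; within-species spreads are not published,
so σ_TL = 0.12 (≈ ±12% length variation) is adopted once as a realistic
field value. Length–weight and size–Hg parameters, counts (49 specimens in
the 7 × 3 design), and all concentration targets are frozen constants in
`hgrisk.synthetic`.

### Calibration

`calibrate_defaults()` solves the parameter set deterministically (fixed
quadrature and root-finding; no randomness), with explicit priorities:

1. **Pooled muscle mean = 0.044 mg·kg⁻¹ exactly.** The muscle residual SD
   σ_muscle is solved from the grand-mean constraint given the species and
   reservoir structure (σ_muscle ≈ 0.41 on the natural-log scale),
   including the Gauss–Hermite-computed lift from size-effect slopes.
2. **Species marginal muscle medians match their published values** (perch
   0.107 > catfish 0.044 > vimba ≈ 0.042 > roach ≈ 0.023 > dace ≈ 0.022 >
   Prussian carp 0.018 > common carp 0.009). Medians for vimba, roach and
   dace are recovered from the published adult safe-weekly-intake column
   via C = TWI·BW·1000/SWI, an inversion that reproduces the four directly
   printed medians exactly.
3. **Reservoir ordering Kardzhali > Ivaylovgrad > Studen Kladenets.** The
   printed reservoir means (0.058/0.039/0.014) are *not* jointly attainable
   with priorities 1–2: catfish occurs only in Studen Kladenets with median
   0.044, so any cell model with mean ≥ median forces that reservoir's mean
   above 0.014; and the three reservoir means with the design's counts
   imply a grand mean of 0.0417, not 0.044. The multipliers are therefore
   solved under bounds (g ∈ [0.5, 1.6]) that preserve the cascade ordering
   and a realistic contrast; Kardzhali and Ivaylovgrad means land within
   ~2% of print, Studen Kladenets high.
4. **Every non-muscle organ matches both its published pooled mean and
   median** (to well within 10%) by solving, per organ, a species-contrast
   attenuation exponent α_o and residual SD σ_o (location profiled out of
   the mean equation; pooled mixture median by root-finding, with a weak
   pull of σ_o toward the muscle value to make the 2-parameter/1-constraint
   solve unique). The attenuation is needed because the full muscle species
   contrast alone forces a mixture mean/median ratio ≥ ~1.7, which would
   make the low-skew organs (skin 0.016/0.015, gonads, gills, bones)
   unreachable; biologically it says the species signal is strongest in
   muscle, consistent with muscle being the long-term MeHg depot.

Two published muscle quantities are knowingly not reproduced, because they
are mutually inconsistent with priorities 1–2 under any mixture model:
the pooled muscle *median* 0.032 (32 of 49 specimens belong to species with
medians ≤ 0.0231, capping any mixture median near 0.025; the generator's
implied value is ≈ 0.028) and the Studen Kladenets mean (see above). The
generator's pooled muscle SD (≈ 0.046) is also somewhat above the printed
0.034; the SD was not a calibration target.

Size-effect slopes default to the two published within-species signals:
Prussian carp muscle β = +0.115 per cm (giving r ≈ +0.6 within species and
a large/small-class median ratio near 1.8) and perch bone β = −0.18 per cm
(r ≈ −0.76). All other cells default to zero: the published pooled
correlation table mixes between-species composition with within-species
effects and does not identify per-cell slopes.

The species-effect centre z̄ is frozen at calibration time so that changing
cell counts (e.g. inflating to n = 100 per cell for parameter-recovery
tests) does not shift organ levels. A single `numpy` generator stream,
seeded from the config, drives all draws in a fixed order: same seed, same
survey, bit for bit.

**What the generator does not emulate:** organ × reservoir interactions
(organ datasets in the emulated survey were unbalanced across reservoirs),
seasonality, MeHg fraction, age structure, and any dependence between
intake and species choice. Passing tests therefore demonstrate that the
pipeline arithmetic and inference are correct under a known
lognormal-effects world — not that the original field data satisfy that
model.

## Statistical analysis

Normality is gated by Shapiro–Wilk at α = 0.05 with log₁₀ transformation on
rejection. Group contrasts use classical one-way ANOVA with Tukey HSD;
Levene's test (median-centred) is reported as a warning rather than an
abort, mirroring a verify-then-proceed protocol. Correlation matrices
(Pearson or Spearman) of TL or TW against organ THg are computed per
species × organ only where n ≥ 3; smaller cells are reported absent, never
as zero. Per-cell p-values are raw — no multiplicity correction across the
matrix — which matches the emulated survey's reporting and is deliberately
liberal; screening users should apply their own correction. Correlations
use raw concentrations by default with a `log_conc` switch, since the
emulated survey does not state its transform.

OLS size models regress organ THg on TL and TW jointly, with residual
Shapiro–Wilk, Breusch–Pagan and leverage diagnostics; designs collinear to
machine precision drop TW and report it. The Mann–Whitney size-class
contrast uses the exact null for combined n ≤ 20 without ties (the
published 4-vs-4 contrast demands the exact distribution), the normal
approximation otherwise, two-sided, reporting min(U₁, U₂). scipy and
statsmodels provide these primitives; the tests verify them against hand
sums of squares, normal-equation solutions, and a full enumeration of
label assignments.

## Risk engine

Constants live in one block (`hgrisk.defaults`): RfD = 0.0001
mg·kg⁻¹·day⁻¹, TWI = 0.0013 mg·kg⁻¹·week⁻¹, BW = 70/60/15 kg, baseline
intake 140 g·week⁻¹ (= 7.3 kg·year⁻¹ = exactly 0.02 kg·day⁻¹ after the
÷7 weekly-to-daily conversion), Tri(50, 140, 350) g·week⁻¹, traffic-light
bounds 140/300 g·week⁻¹. THg stands in for MeHg at fraction 1.0 by
default — conservative, since muscle mercury is typically 80–95%
methylated — with a `mehg_fraction` knob to explore speciation.

THQ is reported to three decimals and SWI to the nearest integer gram
(advisory-table convention); ±1-gram or ±0.002 disagreements with printed
advisory values can arise purely because published input medians are
themselves rounded. The exact identity SWI · C = TWI · BW · 1000 holds
pre-rounding, and consuming exactly SWI grams per week delivers a weekly
dose of exactly TWI · BW mg — both are property-tested. Hazard-index
baskets are user-supplied (single-species baskets by default); no canonical
menu composition is packaged.

## Monte Carlo engine

Per iteration, C is one empirical-bootstrap draw from the species' observed
muscle values (per-draw resampling, not a resampled mean — only this choice
propagates the raw right-skewed tails into THQ), and IR is one draw from
the triangular inverse CDF; the two come from independent uniform streams
of a single seeded generator; BW is fixed per group (a BW distribution is a
known limitation, not modelled). HI runs share one IR draw per iteration,
split by basket shares, with independent bootstraps per species. Summaries
are P50, P95 (linear interpolation between order statistics — stated
because tests need a fixed quantile rule, although P95 of 30,000 draws is
insensitive to it) and the empirical exceedance P(THQ > 1).

Correctness is anchored to closed forms rather than published simulation
outputs: with degenerate C the exceedance equals the triangular survival
function at the critical intake 7000·BW·RfD/C (e.g. C = 0.107, BW = 15 →
SF(98.13 g·week⁻¹) ≈ 0.914) within 3σ binomial error at N = 30,000, and
collapsing both C and IR reproduces the deterministic THQ exactly.
Published per-species simulation percentiles are *not* reproduction
targets: they depend on the unpublished per-fish concentration vectors.
Each species × group row of the summary table runs under a sub-seed
spawned deterministically from the master seed, so rows are independent
but the whole table is reproducible bit for bit.

## Problem sizes and numerics

Defaults: 49-specimen surveys; 30,000 Monte Carlo iterations; 200
replicate surveys for generator-calibration checks (standard error of the
replicate grand mean ≈ 0.00027 mg·kg⁻¹, i.e. a ±1.2% two-SE band).
Calibration root-finding uses Brent's method at xtol 1e−12 and bounded
least squares; Gauss–Hermite quadrature uses 41 nodes. Degenerate inputs
are first-class: single-value bootstrap samples, collapsed triangular
distributions (a = c = b), constant concentration samples, and exactly
collinear OLS designs all take defined paths rather than erroring.

## Known limitations

- The generator matches summary statistics, not mechanisms: no
  bioenergetics, no MeHg speciation, no seasonal or ontogenetic dynamics.
- Pooled muscle median/SD and the Studen Kladenets reservoir mean are
  knowingly off-target (mutually inconsistent published constraints; see
  Calibration).
- Raw per-cell correlation p-values are multiplicity-uncorrected.
- THQ treats THg as 100% MeHg unless told otherwise — conservative for
  advisories.
- Only THg is modelled; multi-element records (Pb/Zn/Cd) are out of scope.
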