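# Methods

`fallowfun` re-implements, as a tested pipeline over synthetic data, an
observational analysis of whether plant diversity or environmental
favorability better predicts ecosystem-service multifunctionality in two
types of smallholder fallows (grazed vs. improved, i.e. planted with
woody legumes).  This note records the models, the choices made where the
design was genuinely open, and what the synthetic data can and cannot show.

## Ecosystem functions

Four per-fallow functions indicate the services of wood production, forage
production and soil formation:

* **Wood biomass** (t/ha): woody-fraction aboveground biomass of trees and
  large shrubs.  Every stem with DBH ≥ 2.5 cm contributes whole-tree
  biomass via the general humid-region allometry `Y = exp(−2.134 + 2.53 ln
  DBH)` (DBH in cm, Y in kg); smaller stems and foliage flow through the
  biovolume path (visually estimated biovolume in m³ per 100 m² plot ×
  a species/growth-form conversion factor in kg/m³).  Only woody species
  with average height ≥ 0.7 m qualify on the biovolume path.  1 kg per
  100 m² plot = 0.1 t/ha.
* **Forage biomass** (t/ha): green-fraction biomass of herbaceous species
  and woody species < 0.7 m, restricted to higher-quality forage —
  crude protein (tissue N × 6.25) to lignin ratio ≥ 0.8 (inclusive).
* **Soil base cations** (meq/100 g): topsoil Mg + Ca + K, averaged over
  the two nested subplots.
* **Steady infiltration rate** (mm/hr): the lower asymptote `fc` of the
  Horton decay `f(t) = fc + (f0 − fc) e^(−kt)` fit to each ring-infiltrometer
  curve, averaged over subplots.

**Mixed-size species.**  When a species carries both measured stems and a
biovolume, the biovolume is assumed to exclude the large stems (split
biovolumes); the overlap risk is logged.  The field protocol underlying the
original data does not settle this, and the synthetic generator always
produces split records.

**Horton fitting.**  The original analysis pooled curves in a nonlinear
mixed model; this package fits each curve independently by bounded least
squares (`fc ∈ [0, max rate]`, `k ∈ (1e−5, 1]`, tolerances 1e−12),
self-started from the first/last rates and a log-linearised early decline.
Per-plot `fc` means are the quantity consumed downstream; the pooling only
shrinks per-curve estimates.  A two-stage pooled variant (median `k`
imposed, `fc`/`f0` re-fit linearly) is available via `shared_k=True`; on
default synthetic data it correlates > 0.97 with per-curve fits with a
mean shift of order 10%.  If the optimiser fails the fallback is the mean
of the final quartile of rates, flagged `converged=False`.

**Soil layer.**  Topsoil (1–20 cm) values enter the analysis; the layer is
a pipeline option (`soil_layer`).

## Diversity metrics

Richness counts species holding ≥ 1% (inclusive) of a fallow's standing
green biomass.  Functional diversity (FD) is the summed branch length of a
UPGMA (average-linkage) dendrogram over Euclidean distances among species
in the space of three ln-transformed tissue traits (N, lignins,
polyphenols), each standardised to unit SD **across the pooled species set
of the dataset** — per-plot scaling would make FD incomparable across
fallows.  Mean-centering is applied but is immaterial: Euclidean distances
are translation invariant, which also neutralises the ambiguity of
"re-scaled to a mean of 1" phrasings for this statistic.  Node height =
merge distance, leaves at height 0, branch length = height difference;
FD = 0 for ≤ 1 species.  Exactly identical trait rows are collapsed to one
leaf before clustering so that functionally identical species add nothing —
under literal UPGMA a duplicate would re-weight later average distances.
Merge-distance ties are resolved deterministically (sorted species labels).

Community-weighted means average ln-trait values weighted by standing green
biomass over all species by default (`cwm_on_filtered=True` restricts to
the ≥ 1% set); group-weighted means restrict weights to the wood ESP
(woody, ≥ 0.7 m) or the forage ESP (CP:lignin ≥ 0.8).  Empty scopes yield
NaN with a warning rather than aborting the pipeline.

## Multifunctionality indicators

Functions are variance-stabilised first: wood `ln(x+1)` (heavily grazed
fallows can carry zero wood, so a bare log is undefined; a strict-log
variant would need an arbitrary floor), forage and infiltration `√x`,
cations `arcsin(√(x/c))` with `c = 100` because the unit is meq per 100 g
(`c` is a pipeline option; indicators are recomputed, never rescaled, if it
changes).

Per fallow type and function, the **maximum** is the mean of the 3 highest
transformed values and the **mean** is the transformed-scale average,
pooled across sampling years.  Note the mean-of-top-3 is not
transform-equivariant, so the scale on which maxima are taken matters and
is fixed to the transformed scale here.

* **Proportion above half-maximum**: fraction of the 4 functions with
  `x_f ≥ τ·M_f`, τ ∈ {0.25, 0.50, 0.75}; comparisons are inclusive
  (boundary ties have probability zero on continuous data; inclusiveness
  makes integer-valued tests deterministic).  The arcsine-√ proportion is
  the modelling response.
* **Mean percentage excess**: `(1/4) Σ_f 100 (x_f − μ_f)/μ_f`.  Averaged
  over the fallows that define `μ_f` this is exactly 0 — an algebraic
  identity that the acceptance script verifies end-to-end through the full
  pipeline.  It requires all transformed means positive; `ln(x+1)` keeps
  the wood mean positive where a bare log of sub-1 t/ha values would not.

**Jointness** counts, per type and unordered function pair, the fallows
with both functions at/above half-maximum or above the type mean.

## Statistical stage

Per fallow type and indicator: univariate OLS on FD, richness, SOC and (in
grazed fallows) grazing intensity, plus additive bivariate models for each
diversity × environment combination — 8 models per indicator for grazed, 5
for improved; no interactions (small samples), raw two-sided P values (no
multiplicity correction, matching the reporting style of small
observational BEF studies), adjusted `R² = 1 − (1−R²)(n−1)/(n−p−1)`.
Grazing intensity is coded as the cover-class midpoint proportion
(0.025–0.825; an ordinal 1–5 coding is an option).  SOC enters as a
fraction (g/g) so coefficient magnitudes are comparable to percent-scale
responses.  Pearson correlations are reported with Fisher-z 95% CIs,
`tanh(atanh r ± 1.96/√(n−3))`, and d.f. (1, n−2); one-way ANOVA compares
types.  A subgroup fit re-tests the FD effect within one grazing class
(default: moderate, the largest usable group).

## Synthetic data generator

The generator emulates the study conditions: 18 grazed + 21 improved
100 m² fallow plots, two soil/infiltration subplots each, a species pool of
60.  Improved fallows draw 1–3 dominant planted woody legumes holding ≥ 80%
of green biomass (Dirichlet dominance mass) plus a small understory;
grazed fallows draw 5–15 species with uneven Dirichlet(0.5) abundances and
a graded grazing class (light/moderate/heavy with probabilities
0.22/0.56/0.22 — moderate over-represented, as in the field sample).
Trait chemistry is log-normal within field-plausible ranges (N 0.5–5%,
lignins 2–25%, polyphenols 0.5–10% of dry mass), whitened to zero sample
correlation so traits are mutually near-uncorrelated by construction.

Per-type raw-scale means of the four functions are calibrated to the
study's descriptive statistics (grazed: wood 3.0, forage 2.4 t/ha, cations
4.8 meq/100 g, infiltration 261.8 mm/hr; improved: 24.2, 1.7, 3.7, 371.0).
Effects are planted additively on the transformed scale:

    t_f = base_f + scale_f · (β · z + σ · ε)

with `z` the realized covariate (FD in grazed, SOC in improved)
standardised by its realized per-type moments, `β` the planted effect
(default 0.8 per covariate SD; per-SD coding keeps the signal scale-free —
FD is measured in branch-length units whose span depends on the pool),
`σ` the residual SD as a fraction of the calibration SD (default 0.7,
so total variance ≈ the calibration SD), and `base_f` solved so the
back-transformed raw mean equals the calibration target in expectation
(the back-transforms are curved; a naive `base = T(mean)` overshoots raw
wood means by ~80%).  Standardising on realized moments means the
calibration holds for *any* effect size, including the null.

Survey records, soil subplots and infiltration curves are then constructed
to *encode* the planted raw targets: stems are drawn (DBH 2.5 + Γ(2, 1.5)
cm) up to 80% of a species' wood share and the remainder assigned via the
biovolume path; quality-forage biovolumes encode the forage target; soil
subplot pairs are jittered symmetrically (±δ) so subplot means recover plot
values exactly; infiltration curves are 16-point Horton curves (~2.5 h)
around the planted steady rate with 8 mm/hr measurement noise.  In
improved fallows, understory green biomass is capped at 24% of dominant
green biomass, enforcing the dominance structure and inducing the
wood–forage trade-off characteristic of dense planted stands.  Forage is
floored at 0.05 t/ha so no plot ends with zero green biomass.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial layout and autocorrelation, multi-year
weather dynamics, NIR-spectroscopy measurement error structure,
grazing-induced suppression of wood (grazing class is independent of the
planted effects), and any nonlinearity or interaction in the
diversity–function relationship.  Realized green-biomass shares differ
slightly from the generated Dirichlet shares (the wood path fixes woody
species' green biomass), so pipeline-recomputed FD is a noisy version of
the generation-time FD used for planting; parameter-recovery tests on the
profile path are therefore exact, while full-pipeline recovery is
attenuated but clearly detectable at study-like sizes.

## Problem sizes and numerical choices

Monte-Carlo checks use the generator's profile path (communities,
covariates and planted function values without record/curve
construction): power is assessed at n = 200 grazed plots over 100
replicates, test size at n = 60 over 1000 replicates; calibration of raw
means is checked at 10× study size; the FD brute-force cross-check runs
500 random pools of ≤ 8 species at 1e−9 tolerance; Horton recovery uses
200 noisy curves.  All randomness flows from a single `numpy` seed per
entry point; ties and orderings are deterministic.

## Known limitations

* Per-curve Horton fits diverge from the original pooled mixed model by
  the amount of shrinkage pooling would apply (documented above).
* The `ln(x+1)` wood transform is a zero-safe divergence from a bare
  "natural log"; results change only via the wood function's scale.
* The arcsine-√ scaling constant for cations (c = 100) maps a
  non-proportion into [0, 1] by unit convention; the original scaling is
  not recorded.
* Group-weighted trait means are NaN for plots whose ESP scope is empty
  (e.g. no tall woody green biomass in heavily grazed fallows).
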