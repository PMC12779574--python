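# Methods

This note documents the models and procedures implemented in
`avistability`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Overview

The package quantifies how land-use change alters the functional structure
of bird assemblages, and how stable that structure would be under further
species loss. The chain is:

1. survey records → land-use classification → assemblages
   (per landscape × block × land use);
2. species morphometrics + diet → niche axes → per-landscape trait space;
3. trait space → grid-discretised trait probability densities (TPDs);
4. TPDs → functional richness, redundancy, per-species redundancy;
5. sensitivity scores → vulnerability and extinction-curve resistance;
6. assemblage metrics → hierarchical land-use effect models.

## Land-use classification and assemblages

Sites carry a vegetation class (primary, secondary, plantation, pasture,
cropland, urban), a use intensity (minimal / light / intense) and, for
secondary vegetation, an age class. The ten fine land-use types split
primary vegetation into pristine (minimal use) vs disturbed, urban into
minimal vs intense use, and secondary vegetation by age; indeterminate-age
secondary sites are rejected. The coarse 4-level factor groups these as
primary / secondary / agriculture (incl. plantation) / urban.

Sites sharing a block and fine land use are pooled additively into one
assemblage. Assemblages below a configurable richness minimum (default 4,
the smallest set a TPD can be built from) are flagged, not dropped, because
whole-assemblage and guild-level analyses apply different minima. Mixed
land-use sites are rejected rather than split. Abundances are accepted as
non-negative reals, since some surveys report effort-corrected densities.

Genus-only records become pseudo-species: arithmetic means of the supplied
congeners' morphometrics, hand-wing index and diet (diet re-normalised to
the simplex after averaging). Congener candidate lists must be supplied by
the caller; range-map intersection is out of scope.

## Niche axes (two-step PCA)

Avian linear morphometrics share a dominant body-size factor. Seven traits
(four beak, three locomotory: tail, tarsus, wing) are log-transformed and
z-scored, then decomposed in two groups. Each group's first component is
size-laden; the second components give a trophic (beak shape) and a
locomotory axis. A third PCA on the two first components yields the body
size axis. The fourth axis is centred log hand-wing index (dispersal).
Signs are fixed deterministically: size correlates positively with wing
length, second components with their largest-loading raw trait. Axes are
computed once over the full species pool, so scores are comparable across
landscapes; dissimilarity and embedding are per landscape.

## Mixed-trait dissimilarity and embedding

Within each landscape, species dissimilarity is Gower-type over five
groups: the four axes (range-normalised absolute differences) and the
nine-part diet composition as a single block (total-variation distance,
`0.5 * sum |p_i - q_i|`, naturally in [0, 1]). By default the five groups
carry equal weight (`weighting="equal"`); `weighting="balanced"`
iteratively re-weights groups until each correlates equally with the
combined matrix, for datasets where group variances are badly unbalanced.
Axes are z-scored before the Gower step by default (`zscore_axes`).
Zero-range groups are dropped with a warning.

Principal-coordinates analysis (double-centred squared dissimilarities,
eigendecomposition) embeds species into the first three positive axes,
scaled by sqrt-eigenvalues. When the third eigenvalue is not separated from
zero (tolerance 1e-10 relative), the Cailliez additive constant is applied
and the decomposition redone. `embedding_quality` reports the fraction of
positive-eigenvalue variance captured; on the synthetic data it is ~0.5,
typical for mixed-trait Gower matrices, and the embedded distances
rank-correlate > 0.9 with the input dissimilarities.

## Trait probability densities

Each species is a diagonal Gaussian in the 3-D embedded space, centred on
its coordinates, with a landscape-common intraspecific-variation (IV)
kernel: for every assemblage with ≥ 4 species a normal-reference diagonal
bandwidth is computed per dimension (`sd * (4 / ((d+2) n))^(1/(d+4))`,
d = 3); the kernel dimensions are the variance-scale entries (squared
bandwidths, as plug-in estimators report), and the common kernel is the
square root of their mean — i.e. the RMS of the per-assemblage bandwidths.
This keeps the kernel on the coordinate (SD) scale; taking the square root
of an SD-scale bandwidth instead would be dimensionally inconsistent and
badly over-smooths when coordinates have range < 1.

The landscape grid has 50 cells per dimension (125,000 cells), bounds
covering all species means ± 3 kernel SDs plus 2% padding, so ≥ 99% of
every species' mass is on-grid. Cell probabilities are exact Gaussian
masses (products of per-dimension CDF differences) — equivalent to
cell-centre density × cell volume once the kernel spans several cells, but
exact in the narrow-kernel limit. Cells outside the highest-density region
holding `trim_alpha` (default 0.99) of the mass are zeroed and the
remainder renormalised. Assemblage TPDs are abundance-weighted mixtures of
member TPDs on the same grid; the shared grid makes richness values
comparable across land uses within a landscape. Sparse storage uses
row-major linearised cell indices.

## Diversity metrics

* Functional richness (FD): number of occupied cells (probability > 0
  after trimming); abundance-free.
* Redundancy: `R = sum_c p_c * M_c - 1`, with `p_c` the assemblage
  probability and `M_c` the number of member species covering cell c
  (trimmed supports, matching richness semantics) — the average number of
  species removable per cell without shrinking occupied volume.
* Relative redundancy: `R / (N - 1)`; reported as 0 (flagged) for N = 1 so
  downstream models stay numeric.
* Species redundancy contribution: `R(full) - R(without focal)`, with
  abundance weights renormalised over the remainder so the reduced TPD
  stays a probability function (the source method is silent on this; stale
  weights would break the mixture). A closed form computes all
  contributions in O(N × support).

Guild subsets (granivore / frugivore / invertivore at > 60% of diet from
the focal resource, broadened variants at > 25%, generalists exceeding 60%
for no resource) reuse the all-species landscape embedding and grid, so
guild metrics live in the same space; a guild with ≤ 3 members across the
landscape is skipped.

## Sensitivity, vulnerability, resistance

Sensitivity scores (higher = more likely lost), centred and SD-scaled
within assemblage:

* general traits: mean of −z(log range size), +z(size axis),
  +z(diet specialism = max diet proportion), −z(log HWI);
* climate traits: +z(elevation midpoint), −z(temperature niche breadth),
  +z(generation length), −z(log HWI);
* rarity: standardised negative abundance.

Component weights are configurable (default equal); body size uses the
derived size axis for consistency with the trait space; an alternative
specialism measure (1 − diet evenness) would be a drop-in replacement.

Vulnerability is `−ρ_Spearman(sensitivity, redundancy contribution)`
(average ranks for ties; NaN with a warning for constant inputs): positive
when the most extinction-prone species provide the most unique function.

Active extinction curves remove species in descending score order; after
each removal, relative FD is the survivors' union-support richness over
the intact richness. Ties are broken uniformly at random over replicates
(default 100; a single exact pass when scores are unique). Curves are
anchored at (0, 1) and (1, 0); the x-axis is the proportion of original
species removed. Passive curves remove 0–2 species per time step, each
survivor with probability rank/(n+1) (scores are not probabilities; a
monotone rank map keeps the step well defined, and the map is
configurable via `prob_fn`); empty steps extend the time axis, replicate
step-curves are rescaled to unit time and averaged on a common lattice.
Resistance is the trapezoidal AUC; the half-life t½ is the smallest
proportion removed at which relative FD reaches 0.5 (linear interpolation;
1.0 if never reached before the terminal point).

## Inference

Responses are transformed by a signed square root (admitting negative
vulnerability values; the alternative shift-then-sqrt is noted but not
default) and scaled to unit SD, then fitted with a univariate linear mixed
model: fixed land-use factor (10 fine or 4 coarse levels; contrasts
against pristine primary / primary), random intercepts for study landscape
and block nested in landscape. Fitting is REML via statsmodels MixedLM
(block entered as a variance component with landscape-qualified labels);
p-values and 95% CIs are Wald. The fixed effects match lme4's REML fit to
1e-4 on test fixtures. Levels absent from the data are dropped with a
warning; near-zero variance components are flagged as singular.

## Synthetic data generator

The generator emulates a global land-use-gradient survey compilation with
known truth. Defaults (the study conditions): 400-species pool, 20
landscapes × 4 blocks × 6 land uses (pristine primary 0, disturbed primary
0.15, young secondary 0.35, plantation 0.55, cropland 0.75, intense urban
0.9 filter strength), regional pools of 30% of the species pool, two
survey sites per assemblage.

* Species complexes: the pool is organised into trait-conserved complexes
  of ~5 species (congeneric clusters; avian morphology and life history
  are strongly conserved within genera). A complex carries a shared guild,
  a size deviation (70% of latent-size variance), log-trait offsets
  (SD 0.12 vs 0.08 within-complex) and shared response attributes; member
  species scatter tightly around them. This packing structure is what lets
  redundancy per species respond to richness collapse: rich assemblages
  hold several near-redundant members of many complexes, species-poor
  assemblages mostly singletons — without it, trait filtering leaves
  converted-habitat survivors *more* mutually overlapping and the
  resistance decline is not a robust property of the data.
* Morphometrics: log-normal with a shared latent size factor (positive
  loadings ~0.3, so every raw trait correlates > 0.5 with size); small
  guild-specific beak shifts.
* Hand-wing index: log-normal, weakly size-correlated (target pooled
  r ≈ 0.2, the empirically observed decoupling of dispersal from size).
* Diets: Dirichlet; specialist guilds concentrate ~0.8 expected mass on
  the focal resource, generalists use a flat concentration of 2.
* Response attributes: log-normal range size (median ~2.7e5 km²),
  generation length (~3.7 y), temperature niche breadth (~10 °C); normal
  elevation midpoint — all with a dominant complex-level component.
* Latent sensitivity: standardised mean of −z(log range), +z(size),
  +z(max diet proportion), −z(log HWI) — mirroring the general
  response-trait basket so that trait-based removal orders are aligned
  with the truth used for filtering.
* Filtering: species survive with probability
  `sigmoid(0.85 − f · (2.0 + 3.2 · z))` (f = filter strength, z = latent
  sensitivity): no bias at f = 0, and at f = 1 a species at the
  top-decile sensitivity threshold survives with probability < 0.05.
* Colonists: disturbance-tolerant species (generalists/granivores of
  below-median sensitivity) that failed the filter may still join
  agriculture/urban assemblages (probability 0.25), emulating the influx
  of open-country and urban-tolerant species into converted landscapes.
* Abundances: log-normal (μ = 2, σ = 1), shifted down by 0.3·z so
  sensitive species are also rarer, as observed in field data.

All draws flow from one master seed through named substreams (pool,
landscapes, abundances, colonists), so each stage is independently
reproducible.

What the generator does *not* emulate: taxonomic or geographic structure,
detection error, within-species trait variation, temporal turnover, or
spatial autocorrelation among landscapes. Passing recovery tests therefore
demonstrate that the pipeline recovers known filtering structure from data
of this form — not that the field estimates themselves are unbiased.

## Problem sizes and numerical choices

The end-to-end experiments run at the default synthetic scale above
(~480 assemblages, 125,000-cell grids); one full run takes ~25 s on one
CPU, and the 25-run sign-recovery experiment ~10 min. Test fixtures use
smaller grids (≤ 30³) and pools (≤ 120 species) where the full scale adds
nothing. Numerical tie-breaks and degenerate cases: PCA signs fixed by
correlation with named raw traits; zero-variance z-scores return all-zero
scores; constant vulnerability inputs return NaN with a warning; N = 1
relative redundancy is 0 with a flag; TPD masses are validated to sum to
1 ± 1e-9.

## Known limitations

* Under the synthetic study conditions, functional *vulnerability*
  increases along the land-use gradient (sensitive survivors in converted
  assemblages tend to be the last members of their complexes, hence
  functionally unique). The generator is designed to reproduce the FD,
  redundancy and resistance responses; the direction of the vulnerability
  contrast is an emergent property of these conditions, not a calibration
  target, and field data need not share it.

* The exact aggregation of sensitivity components, the reference TPD
  trimming threshold, and the passive-removal probability map are not
  uniquely determined by the source methodology; all are configurable and
  the defaults are stated above.
* Guild metrics reuse the all-species embedding (shared trait space); a
  re-embedding per guild is a flagged alternative, not the default.
* statsmodels MixedLM occasionally reports near-singular variance
  components on small fixtures; fits are flagged rather than rejected.
* No spatial covariance structure is modelled.
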