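# Methods

This note documents the statistical models, the estimator choices, the
synthetic-data generator, and the design decisions taken where the
problem was genuinely open. It describes what the code computes; every
number quoted is produced by the test suite or the analysis scripts.

## Colour scoring

An observation is a list of patches, each a colour (wheel id or explicit
RGB) and a coverage fraction in 5% steps summing to 1. Lightness is the
coverage-weighted mean of the patch RGB channel means, on 0–255. Species
values are unweighted means over individuals; sexes and morphs are
pooled. The default 72-colour wheel is generated in HSV space (18
equally spaced hues × saturation 10/40/70/100%, value channel 1.0) and
is deliberately an *input*: any catalog with explicit RGBs can be
supplied as CSV.

A consequence of an 18×4 hue–saturation wheel at full value is that it
contains no near-black colours: its representable lightness span is
[85, 246.7] with a maximum gap of 28.3 between consecutive colours.
Quantising a value inside the span to a two-colour wheel mixture (5%
coverage steps) recovers it within half that gap (in practice within
~0.7, the coverage-rounding error); values outside the span clip to the
nearest wheel colour. The synthetic generator therefore clips true
lightness into [86, 242] rather than [0, 255] — the observation process
cannot express darker values, and feeding it unrepresentable targets
would only document the wheel's censoring, not the pipeline.

Inter-observer calibration is an OLS of observer B on observer A,
reported (slope, intercept, SE, R², n) and applied only on request; the
default analysis uses a single observer's data unchanged.

## Phylogenetic models

All comparative machinery works through the covariance matrix C with
C[i,j] = shared root-to-MRCA path length. Pagel's λ rescales
off-diagonals, C_λ = λC + (1−λ)diag(C); λ is estimated by maximising the
multivariate-normal likelihood with μ and σ² profiled analytically and
the scalar λ optimised on [0, 1] (boundary candidates always evaluated;
star phylogenies are reported unidentifiable). The likelihood is checked
in the tests against dense matrix-inversion evaluation.

The trait decomposition fits the phylogenetic mixed model
y = μ1 + a + e, a ~ N(0, σ²ₐC), e ~ N(0, σ²ₑI), by EM in the eigenbasis
of C (one O(n³) eigendecomposition, O(n) per iteration). μ is refreshed
by GLS each cycle, so the marginal log-likelihood is non-decreasing
(ECM). Convergence: relative log-likelihood change < 1e-8, max 10,000
iterations; variance components start at var(y)/2 each. P and S are the
BLUPs of a and e; additivity μ + Pᵢ + Sᵢ = yᵢ is exact because the two
predictors sum to the centred data. C may be rank-deficient (zero-length
terminal branches); V = σ²ₐC + σ²ₑI remains proper and the σ²ₐ M-step
averages over C's support only. On tiny problems the ML optimum often
sits on the σ²ₑ = 0 boundary, where EM converges only asymptotically —
the non-convergence flag reports this; the fit is still usable.

PGLS whitens y and X with the Cholesky factor of C_λ; λ can be fixed or
jointly profiled by ML. R² is reported on the whitened scale against the
whitened intercept-only fit (recorded in result metadata).

Species missing from the tree are grafted onto the terminal edge of a
random congeneric tip: the edge is split with the new internal branch
receiving 10% (configurable) of the host branch, and the new tip gets
the same depth, preserving ultrametricity. Successive grafts can attach
to earlier ones, randomly resolving intra-genus structure; the host
sequence is seeded. Stem-vs-crown placement within genera is not
specified by any convention we follow, so tip-edge grafting was chosen
for its exact prune-inverse: removing the grafted tips restores the
original covariance to machine precision.

## Assemblages and filters

The grid is planar with unit-area square cells, so "equal-area" holds by
construction and no projection code exists. Filters, with thresholds as
config keys: cells with water fraction strictly above 0.5 are excluded;
assemblages with colour data for less than 33% of their (mapped) species
are excluded, species without colour data counting in the denominator.
Grouped models exclude realms with ≤50 assemblages, families with <10
species, and (for severity) families with <9 species. Assemblage trait
means are unweighted over species with colour data, so the additive
identity mean_raw = μ + mean_P + mean_S carries over cell-wise.

## Colour diversity (SES-MPD)

MPD is the mean over unordered pairs of |xᵢ−xⱼ|, computed in O(k log k)
via the sorted-order identity. The null draws equally rich species sets
without replacement from the realm pool (all colour-scored species
occurring in ≥1 included cell of the realm); 1000 draws by default, with
exact enumeration replacing sampling whenever C(pool, k) ≤ 10,000.
SES = (obs − null mean)/null sd; null sd = 0 marks the result
degenerate. Each cell's draws are seeded by hashing (global seed,
cell id), so results are independent of evaluation order and
parallelisation. Calibration (tested): assemblages drawn randomly from
their own pool give SES mean ≈ 0, SD ≈ 1.

## Regressions

Predictors are z-scaled (mean 0, sd 1, ddof 0) with stored transforms.
OLS uses least squares with intercept, (XᵀX)⁻¹σ̂² standard errors and
two-sided t tests. 95% CIs are slope ± 1.96·SE. No multiple-testing
adjustment is applied by default (raw two-sided P values are reported);
a Holm option exists in the API surface via standard tooling.

The trend surface is a tensor product of cubic B-splines (default
10×10, open uniform knots on the scaled coordinates) with second-order
difference penalties on each axis, estimated jointly with the
unpenalized linear terms. The surface carries a sum-to-zero constraint
over the data so it cannot absorb the intercept; the remaining penalty
null space spans (near-)planar coordinate trends, which is the
infinite-smoothing limit (tested against the exact null-space OLS). The
smoothing parameter is selected on a 41-point log grid by GCV with a
one-SE-style rule: the *largest* smoothing whose GCV is within 10% of
the minimum. Plain GCV minimisation undersmooths here — the surface
chases cell-level noise and leaves *negative* mid-range residual
autocorrelation — and the 10% slack centres the residual correlogram on
the permutation null. Linear-term inference uses the penalized fit's
effective residual degrees of freedom n − tr(H); the frequentist
sandwich σ̂²·A⁻¹XᵀXA⁻¹ gives the standard errors. Because the penalized
model nests the no-surface model for every smoothing value, its R² never
falls below the plain LM's.

Hierarchical partitioning fits all 2^k subset models (guard k ≤ 8) and
assigns predictor j the level-weighted average of its incremental R²
over subsets — algebraically the mean over all k! entry orderings, which
the tests verify by brute force; contributions sum exactly to the full
R². Grouped interaction models use the full cell-means
parameterisation: per-group intercepts and one slope per (term, group);
whether main effects should instead be partialled out globally is not
determined by the analysis being mirrored, and the cell-means form keeps
each group's slope directly interpretable. Severity models regress
severity on the z(lightness)·z(EVI) product per family, with unaffected
co-occurring species as controls coded 0 (an assumption, documented
here) and an overall PGLS with λ estimated.

Moran's I uses binary weights within equal-width distance classes, with
expected value −1/(n−1); a permutation helper returns the first-class
null mean and sd for band checks.

## The synthetic world

The generator emulates, structurally, the inputs of a global
trait-macroecology study; all outputs are a pure function of (config,
master seed), with per-stage substreams.

Environment (50×50 grid): temperature has a flat tropical belt
(|lat| < 0.35 of the half-grid) declining linearly to the poles
(28 → 6 °C), minus a 1 °C/km elevation lapse, plus a smoothed Gaussian
field (kernel sd 3 cells, the scale of all fields). Elevation is an
independent smooth field (800 ± 600 m). EVI is a 0.35-weighted mixture
with z(MAT) plus independent smooth noise (realised corr(MAT, EVI)
within ±0.1 of 0.35). UVB declines with |latitude| and rises with
elevation plus independent noise. 8% of cells, on the two border rings,
are water-dominated. Realms are four blocks: two temperate bands
(|lat| > 0.5) and a west/east split of the tropics, giving every realm
>50 assemblages.

Phylogeny and trait: a birth–death tree (b = 1, d = 0.3, 300 tips),
height-normalised, with every terminal branch extended by 1% of tree
height because the simulator stops at a speciation event (zero terminal
branches would make C singular). Thermal niche centres are √0.75·BM +
√0.25·iid (sd 7 °C): strongly conserved, as in real amphibian climate
niches, but not clade-exclusive — with pure-BM niches, single clades
monopolise climate bands and their idiosyncratic colour deviations can
swamp the planted environmental signal at the assemblage level. The
productivity preference is the EVI at a random cell inside the species'
thermal band (phylogenetically independent by construction, which is
what routes the productivity effect into the S-component). Ranges are
the connected component, around that cell, of cells within ±3 °C of the
thermal niche and ±0.08 of the EVI preference (median ≈ 60–100 cells).
True lightness is 165 + 18·z(range MAT) + 2·z(range elev) −
10·z(range EVI) − 8·z(range UVB) + a + e with a ~ N(0, 18²·C_0.55) and
e ~ N(0, 4²), clipped to [86, 242] (<1% clipped at the default seed; the
clipping fraction is reported in the manifest). The deviation's λ of
0.55 was chosen so the *fitted* λ of scored colour lands near 0.5 — a
composite trait's λ is pulled up by the conserved niche effects and down
by the iid parts, so the configured and recovered values only align if
the whole budget is designed together.

Observations: individuals per species are 1 + Poisson(0.4) (mean 1.4);
each individual's value is truth + N(0, 5²), expressed as one or two
wheel patches by bracketing the target between the adjacent wheel
lightness values with coverages rounded to 5%. 15% of species are
unobserved (missingness). Severity: 20% of species are affected, with
severity 2 + 0.8·z(light)·z(EVI) + 0.3·z(light) + N(0, 0.8²) floored at
0.1; co-occurring unaffected species are controls coded 0. Activity is a
random three-class label (20/60/20), carrying no planted effect.

What the generator does *not* emulate: real geography and coastlines,
dispersal limitation beyond range contiguity, trait-dependent
diversification, colour plasticity, observation effort gradients, and
spatially structured missingness. Passing tests therefore demonstrate
the *estimators* recover planted structure under the stated assumptions,
not that real anuran data satisfies those assumptions.

## Problem sizes and numerical choices

The default world (300 species, 50×50 grid, ≈2,000 land assemblages) is
the study condition for the end-to-end tests; smoke and determinism
checks use a 20×20/50-species world. Recovery simulations for λ use
Yule trees (200 tips, 50 replicates per generating value) — random
split-height trees are comb-like and carry too little information about
λ to be a fair power check. Degenerate inputs are errors, not silent
results: constant traits, rank-deficient designs, pools smaller than the
assemblage, unresolvable colour ids. Ties in grouped models are avoided
by processing labels in sorted order; all resampling is seeded
(per-cell seeds by hashing, so partial reruns reproduce).

## Known limitations

- The trend surface is a P-spline with GCV, not a thin-plate REML
  smooth; it reproduces the statistical role (absorbing spatially
  structured latent variation), and coefficient-level equality with any
  particular GAM package is out of scope.
- Adjacent assemblages share most of their species, so their trait means
  are near-identical by construction; no smooth surface can fully
  whiten this short-range residual correlation. On the default world the
  first-distance-class Moran's I of trend-surface residuals sits inside
  the ±3 sd permutation band, but with |I| ≈ 0.01 rather than 0, and
  other seeds can land slightly outside; the correlogram tables let the
  user see the whole distance profile.
- λ̂ of a composite trait is not a variance-weighted average of its
  parts; recovery statements are calibrated for the default
  configuration, not arbitrary ones.
- The severity model's control coding (unaffected co-occurring species
  = 0) makes per-family interaction slopes noisy when controls dominate;
  the overall PGLS is the stabler summary.
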