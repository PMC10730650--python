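# melanoclime

Colour lightness of ectotherm assemblages and its environmental drivers —
a reusable, fully tested reimplementation of a global macroecological
analysis of anuran (frog and toad) dorsal colouration, exercised
end-to-end on a seeded synthetic world so that every stage is verifiable
without external downloads.

## The scientific problem

Dorsal colour lightness (0 = black, 255 = white) has competing
physiological functions in ectotherms:

- **thermal melanism (Bogert's rule)** — darker animals heat faster, so
  darker colours are favoured in cold environments: lightness should
  *increase* with temperature;
- **Gloger's rule** — melanised integument resists fungal and bacterial
  pathogens, which thrive in warm-wet, productive environments:
  lightness should *decrease* with productivity (EVI);
- **UVB protection** — melanin shields against UVB damage: lightness
  should *decrease* with UVB irradiance.

The pipeline tests these predictions at the assemblage level (grid-cell
communities) and the species level, while accounting for the fact that
related species resemble each other (phylogenetic autocorrelation) and
that neighbouring places resemble each other (spatial autocorrelation).

## What the package computes

- **Colour scoring** (`melanoclime.colour`). An individual's lightness is
  the coverage-weighted mean of its colour patches' RGB channel means,
  `L = Σᵢ covᵢ · (Rᵢ+Gᵢ+Bᵢ)/3`, with patches coded against a 72-colour
  wheel (18 hues × saturation 10/40/70/100%) and coverages in 5% steps.
  Species values are unweighted means over individuals. An OLS
  inter-observer calibration aligns second observers.
- **Phylogenetic machinery** (`melanoclime.phylo`). The tree covariance
  C (shared root-to-MRCA path lengths); Pagel's λ by profiled maximum
  likelihood on C_λ = λC + (1−λ)diag(C); the phylogenetic mixed model
  y = μ1 + a + e with a ~ N(0, σ²ₐC), e ~ N(0, σ²ₑI) fitted by EM,
  whose BLUPs split each species' colour into a phylogenetically
  predicted part P and a species-specific part S with μ + Pᵢ + Sᵢ = yᵢ
  exactly; PGLS regression with λ-structured errors; and seeded grafting
  of species missing from the tree into their genus's subtree.
- **Assemblages** (`melanoclime.grid`). Occupancy on a planar equal-area
  grid; cells with >50% water excluded; assemblages with colour data for
  <33% of species excluded; per-cell unweighted means of raw/P/S; per-
  species range-mean environments.
- **Colour diversity** (`melanoclime.diversity`). Mean pairwise lightness
  distance (MPD) per assemblage, standardised against 1000 equally rich
  random draws from the realm species pool:
  SES = (MPD_obs − mean_null)/sd_null. Negative SES = environmental
  filtering toward similar colour.
- **Regressions** (`melanoclime.regression`). z-scaled multiple linear
  models; penalized tensor-product spline trend surfaces over the cell
  coordinates (GCV-tuned) to absorb spatially structured latent
  variation; hierarchical partitioning of R² into independent predictor
  contributions (all-subsets, averaged over orderings); grouped
  full-interaction models for realms (>50 assemblages), families (≥10
  species) and activity classes; chytridiomycosis-severity models on the
  colour×productivity interaction (families ≥9 species, plus PGLS); and
  Moran's I correlograms of residuals.
- **Synthetic world** (`melanoclime.world`). A seeded generator with the
  statistical structure the analysis assumes: autocorrelated
  environmental fields with a latitudinal temperature gradient,
  a birth–death phylogeny, Brownian thermal niches, contiguous
  niche-filtered ranges, colour built from planted environmental effects
  (MAT +, EVI −, UVB −) plus a λ-damped phylogenetic deviation, wheel-
  quantised observations (≈1.4 individuals/species), and severity with a
  planted colour×EVI interaction.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic world and write their tables under `results/`:

```bash
python analysis/01_simulate_world.py
python analysis/02_score_colours.py
python analysis/03_decompose_colour.py
python analysis/04_build_assemblages.py
python analysis/05_colour_diversity.py
python analysis/06_assemblage_regressions.py
python analysis/07_species_level.py
```

Representative output (default master seed 0):

```
scored 251 species from 361 individuals (mean 1.44 per species)
Pagel's lambda (colour lightness): 0.45 (n = 251 species)
mixed model: mu 167.4, sigma2_phylo 273, sigma2_resid 310 (phylogenetic share 0.47)
assemblages: 1970 of 1988 retained
mean SES -0.83; 80% of assemblages under-dispersed
raw: LM R^2 0.65 -> GAM R^2 0.84; slopes (MAT, EVI, UVB) = (+13.2, -7.8, -1.7)
hierpart north_temperate: dominant MAT (R^2 0.58)
hierpart tropical_east:  dominant EVI (R^2 0.58)
PGLS (lambda 0.44, R^2 0.454): {'MAT': '+16.83', 'EVI': '-8.39', 'UVB': '-6.73'}
```

Reading this: the fitted phylogenetic signal (λ ≈ 0.45) matches the
generator's deviation structure; all three planted effect directions are
recovered with the right signs at the assemblage level; the trend
surface absorbs the spatially structured latent variation (R² 0.65 →
0.84); assemblages are colour-under-dispersed (negative SES,
environmental filtering); and the dominant driver per realm follows the
planted contrast — temperature in the temperate bands, productivity in
the tropics.

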