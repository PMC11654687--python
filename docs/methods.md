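# Methods

This note documents the models, numerical choices and limitations of the
`impactmodes` pipeline: what each stage computes, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely
open.

## Synthetic cohort generator

The generator produces every input a real imaging-genetics study would
supply, as a pure function of `(SimConfig, seed)`; the global seed is split
hierarchically so each generator (genotypes, covariates, truth, maps,
discovery cohort, kinship) draws from its own independent stream and can be
re-run in isolation.

**Genotypes.** Dosages are hard calls (0/1/2) from binomial sampling of two
alleles per subject.  Linkage disequilibrium is block-structured: variants
are organised in blocks of `ld_block_size`; the first variant of a block is
drawn fresh at a per-block MAF uniform in `maf_range`, and each later
variant copies its predecessor's alleles with per-allele flip probability
(1 − `ld_decay`)/2.  This gives an analytically controllable allele
correlation of `ld_decay` per step (dosage *r*² ≈ `ld_decay`^(2k) at lag k)
and exactly zero LD across block boundaries, which is what the clumping
tests need.  The trade-off is that flipping drifts within-block allele
frequencies toward 0.5 when the block MAF is below 0.5; the metadata records
the requested (block) MAF.  Variant positions place blocks 1 Mb apart
(beyond any clumping window) with 1 kb spacing inside a block.  Fractional
imputed dosages are accepted by every downstream consumer but not generated.

**Planted truth.** K spatial modes are smoothed sparse blobs: K
well-separated centers (greedy farthest-point sampling on the masked voxel
grid, or on a 1-D index for fixels), each mode a Gaussian-falloff bump
restricted to its center's Voronoi cell, so supports are disjoint by
construction and pairwise map correlations are near zero.  Variant loadings
are sparse Gaussian (`loading_sparsity` of variants per mode, disjoint
loader sets when the budget allows), and the per-variant effect maps are
exactly `loadings @ modes` — the rank-K structure the decomposition stage
must recover.  Liability weights for the discovery trait are proportional
to each variant's net map loading: the same allele that raises trait
liability drives that variant's brain effect, as in a real disposing-allele
convention.  Without this sign coupling the polygenic score's map
association would cancel across variants, which is a property of a
mis-specified simulation rather than of the method.

**Brain maps.** `map = 1.0 + centered-dosage · effect_maps +
covariates · slopes + N(0, noise_sd²)`.  Centering the dosage keeps the
baseline MAF-independent.  Covariate effects are global (one slope per
covariate across all elements), emulating whole-brain nuisance like age or
scanner drift.  Voxel maps live on a small 3-D grid (default 10³) with an
ellipsoidal "brain" mask; fixels are a flat element list with unit
direction vectors.  The default `noise_sd` (0.05 against per-variant
effects of SD 0.05 aggregated over ~36 loaders) is a high-SNR desk-scale
setting chosen so that planted effects are comfortably detectable at a few
hundred subjects; real effect sizes are far smaller and are not claimed
here.  What the generator does **not** emulate: realistic human LD panels,
population stratification beyond Gaussian PC stand-ins, registration or MRI
physics, spatially correlated noise, or missing data patterns.  Passing
tests therefore demonstrate correctness and calibration of the machinery,
not expected power on real cohorts.

**Discovery GWAS.** An independent cohort with the same variant structure
is simulated; liability = centered dosage · weights + N(0,1); per-variant
marginal OLS gives beta, SE and a two-sided t-test p-value.  p-values are
clipped to the smallest positive float to stay in (0, 1].

**Kinship.** Related pairs draw coefficients from {0.25, 0.125, 0.0625}
(1st–3rd degree); an equal number of sub-threshold pairs (0.001–0.04) is
added so pruning has to discriminate.

## Genetics

**Hardy–Weinberg test.** Pearson 1-df chi-square of observed genotype
counts against p², 2pq, q² at the estimated allele frequency — the standard
GWAS QC choice at cohort scale; an exact test is a non-goal.  Dosages are
rounded to hard calls for counting, since HWE is a genotype-count test.  A
monomorphic variant returns p = 1 (degenerate test).

**QC filter.** Keeps variants with MAF ≥ 0.01, info > 0.7 and HWE
p > 1e-7 (all thresholds configurable); counts removed per criterion are
logged and written to the run report.  An empty result is a warning, not an
error.

**Clumping.** Greedy: among variants below the p threshold, repeatedly take
the smallest-p unassigned variant as an index and discard unassigned
same-chromosome variants within ±window whose *r*² with it is at or above
the threshold.  Ties on p break by smaller position, then id, making the
output independent of input row order.  LD is computed in the target
genotypes themselves (no external reference panel); a zero-variance
neighbour counts as unlinked.  Window semantics: |Δpos| ≤ window_kb · 1000,
same chromosome, 1-based positions.

**Relatedness pruning.** Graph over pairs with kinship at or above the
threshold (default 0.044, the standard 3rd-degree cut-off); recursively
delete the maximum-degree vertex until edge-free.  Degree ties break by
lexicographically largest subject id — any fixed rule works, this one is
deterministic without extra state.  The output is verified edge-free on
every run.

**Polygenic scores.** Score = Σ aligned-dosage × weight, flipping dosage to
2 − d when the weight's effect allele is the genotype's ref allele; weights
whose variant is absent or whose allele matches neither are skipped with a
logged count.  Missing dosages are mean-imputed per variant (deterministic
and standard; per-subject rescaling is deliberately not applied).  The
clumping+thresholding family clumps once at p < 1 and thresholds the
surviving indices, using the discovery beta as weight.  `optimize_pgs`
fits every IDP on every candidate score (covariate-adjusted) and selects
the candidate with the largest single |t| — hyperparameter selection
against an IDP panel, standing in for shrinkage-model grid searches
(elastic-net/Bayesian shrinkage internals are out of scope).

## Association

**Design.** Intercept plus all covariate columns; head size and global mean
AFD are held out of the base model and enter only under their secondary-
model flags; a log-transform flag applies to (strictly positive) map values
before fitting.  Missing covariate values are an error that names the
subjects.

**GLM.** Per element, OLS of value on [predictor | design] computed via
Frisch–Waugh: both predictor and values are residualized on the design
(QR-based projection), then t = β̂/SE with df = n − p − 1 equals the
full-design OLS t to numerical precision (tested to 1e-8 against a
normal-equations oracle).  Elements with zero residual variance get t = 0
and a logged count; a predictor collinear with the design is an error.
Partial r² = t²/(t² + df) is reported per element and labelled as partial.

**Permutation FWE.**  Freedman–Lane: maps are residualized on the nuisance
design; each permutation rearranges those residual rows, re-residualizes on
the design, and refits the predictor; the maximum tail statistic over
elements per permutation forms the null, and
p_FWE = (1 + #{null maxima ≥ observed})/(n_perm + 1), which includes the
unpermuted statistic and hence guarantees validity.  Implementation note:
because the residualized predictor is orthogonal to the design, the
numerator is unaffected by re-residualization and only the residual sum of
squares needs the per-permutation design projection, so the whole null
distribution is computed with a handful of matrix products per chunk of
permutations.  Two-sided |t| is the default tail; left/right are flags.
Degenerate elements get p = 1.  No spatial statistics (cluster enhancement,
smoothing) are computed.  Calibration is verified by simulation: under a
global null with real covariate effects, the family-wise rejection rate at
α = 0.05 sits inside the Monte-Carlo band (see `analysis/06_validation.py`).

**IDPs.** Principal-component subject scores of the element-centered map
matrix at several dimensions, concatenated with provenance labels.
Probabilistic-ICA IDPs are a non-goal; PCA scores are a faithful stand-in
for the optimization role IDPs play here.

## Impact modes

The variant × element t-matrix is decomposed as follows, in line with how
t-maps should be treated (their mean and scale are signal, not nuisance):

1. **No mean removal, no variance normalization** of the t-matrix.
2. Uncentered SVD; the top-K right singular vectors, scaled to unit
   variance, are the whitened spatial coordinates.  K above the numerical
   rank is an error.
3. Fixed-point ICA (scikit-learn's FastICA core: logcosh contrast,
   symmetric decorrelation, tol 1e-6, max 1000 iterations) on the whitened
   coordinates, with up to 5 seeded restarts on non-convergence, then a
   hard error with diagnostics.  Whitening is done here rather than inside
   FastICA precisely to avoid its built-in centering.
4. Mixing by least squares, so `mixing @ sources` reproduces the rank-K
   projection of the input to 1e-8.
5. Sign convention: each component is oriented to positive spatial skewness
   (tie: largest-|z| element positive); components are ordered by variance
   explained.  Spatial maps are z-scored over elements for reporting.
6. Per-variant **weight z-scores**: each mixing column standardized over
   variants (population SD).  How such weights are best standardized is
   genuinely open (an ICA noise-model z is an alternative); within-mode
   standardization across variants is the simplest reportable choice and is
   what the weight histograms assume.

**Variance explained** uses the zero matrix as baseline (consistent with no
mean removal): total = 1 − ‖T − ÂŜ‖²_F / ‖T‖²_F; per-mode fractions are the
rank-1 term norms (these need not sum exactly to the total when sources are
not orthogonal, but in practice are close).  A column-mean baseline is
available as a flag-level alternative at the call site.

**Jacobian normalization** divides each subject's voxel values by their
in-mask mean (total-brain-volume normalization) before the t-maps that
enter ICA are computed, so modes reflect regional rather than global-size
effects.  Whether the t-maps entering ICA should come from the
head-size-adjusted model is left as a flag (default: unadjusted).

**Recovery matching** (for validation) greedily pairs recovered and planted
maps by maximum |correlation| and reports spatial |r|, loading |r| and sign
alignment, since ICA is identifiable only up to permutation and sign.

## Pipeline, formats, determinism

Stages read and write a run directory (TSV tables; 4-D NIfTI + mask for
voxel maps; fixel-geometry + AFD TSV pair for fixels; JSON manifests; YAML
config with exact round-trip).  The manifest records package version,
config hash, seed and per-stage counts/timings; a rerun with the same
config and seed reproduces every artifact bit-for-bit, including the ICA
(stochastic in initialization only, with the restart seed recorded).
Permutation and ICA seeds are derived from the run seed by fixed offsets.

## Problem sizes

Validation experiments run at desk scale, chosen to make the statistical
assertions sharp while keeping the whole suite fast: GLM oracle on 100
random 50 × 10 fixtures; permutation calibration over 500 replicate
100 × 200 null datasets at 200 permutations; mode recovery with K = 5, 500
variants, 2000 elements at component-SD : noise-SD = 5 over 10 seeds; the
polygenic-score experiment with a 10,000-subject discovery cohort, 2000
variants (30 causal at discovery z ≈ 5) and a 1000-subject target over 50
seeds; and 20 end-to-end pipeline runs at 300 subjects, 160 variants and a
10³ grid with 300 permutations.  The threshold grid in the PGS experiment
(1e-8, 1e-3, 1) is constructed so the middle threshold is best by design:
the tight one misses most causal variants (z ≈ 5 rarely reaches p < 1e-8),
and the loose one dilutes the score with ~2000 null weights.

## Known limitations

- Block-copy LD is not coalescent LD; clumping behaviour on real panels
  (long-range LD, variable block sizes) is untested.
- The HWE test is asymptotic; rare variants at small n would need an exact
  test.
- Permutation exchangeability assumes i.i.d. errors; heteroscedastic or
  family-structured data would need restricted permutation blocks.
- Impact-mode order selection (choice of K) is manual; the decomposition is
  fixed-K by design and automatic dimensionality is a non-goal.
- Variance-explained per-mode fractions are rank-1 contributions of
  non-orthogonal components and can over- or under-count slightly.
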