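# Methods

This note documents the models, estimators and numerical choices behind
`phenodict`, the defaults and their rationale, what the synthetic
generator does and does not emulate, and known limitations.

## Input model

The unit of data is a *cell table*: one row per segmented cell with its
position in microns, its phenotype label, and image/subject/class
metadata.  Each phenotype's rows form a spatial point pattern in a
rectangular observation window.  Only positions and binary phenotype
membership are used — no marker intensities, morphology or texture.

## Synthetic cohort generator

Real two-class mIF cohorts are emulated with a parametric generator:

- **Baseline:** per image, each phenotype is a homogeneous Poisson
  process with class-specific intensity (points/µm²).
- **Coupling:** for a configured pair (a, b) and fraction f ∈ [0, 1], a
  Bernoulli(f) subset of b-points is relocated to a uniformly chosen
  a-point plus an isotropic Gaussian offset (sd = dispersion, default
  20 µm), resampled until in-window so marginal counts are untouched.
  This is a Thomas-process-style construction: it plants cross-phenotype
  co-localization without changing either phenotype's expected count.
- **Subject heterogeneity:** an optional log-normal per-subject
  intensity multiplier (default off) for subject-level vs image-level
  evaluation contrasts.

Defaults (chosen once as a realistic operating point): window
1000 × 1400 µm so the default 70 × 50 grid has square 20 µm cells
(≈ the tissue-microarray pixel scale of 25 µm²/px used for pancreatic
cores); baseline intensity 5 × 10⁻⁴ cells/µm² per phenotype
(500/mm²/phenotype, ~2,500 cells/mm² total — a typical tissue cell
density); 20 subjects/class with one image each for the benchmark.

The generator verifies against two oracles: per-phenotype counts are
Poisson with mean λ·|W| (chi-square goodness of fit), and the planted
coupling is detectable and monotone in f through a normalized
parent-to-offspring neighbor count (a cross-K-style statistic whose
expectation is ≈ 1 + f·P(d ≤ r)/(λ_a π r²) under the construction).

**What it does not emulate:** staining artifacts, segmentation error,
phenotype misassignment, tissue architecture (glands, stroma),
inhomogeneous baseline intensity, or irregular window shapes.  Passing
tests on this generator demonstrate that the pipeline recovers planted
intensity and co-localization structure, not that it handles the full
messiness of clinical slides.

## Intensity surfaces

Each phenotype's pattern is smoothed onto the grid with an isotropic
Gaussian kernel (default σ = 1.5 × cell size = 30 µm), truncated at 4σ
(continuous truncation error 1 − e⁻⁸ ≈ 3×10⁻⁴), sampled at cell
centers, row 0 at the bottom edge.  With edge correction on (default),
each point's truncated, discretized kernel is renormalized to unit
in-window mass — a Diggle-style per-point correction under which
`sum(values) · cell_area` equals the point count *exactly*, removing the
downward bias near window borders.  Without correction the kernel is the
plain truncated Gaussian density.

No cross-channel normalization is applied by default; a per-image,
per-channel max-normalization flag exists because with strongly unequal
phenotype abundances the raw ℓ2 objective is dominated by the abundant
channels (a documented deviation when enabled — the benchmark cohorts
use equal abundances and do not need it).

## Patches

Overlapping n × n × c blocks (default 20 × 20 × 5) are taken on a stride
lattice (default stride 10, i.e. 50% overlap); blocks never straddle the
border (padding would inject zeros that interact with the filter).  A
block is dropped iff *strictly more than* 70% of its n²c values are
below 10⁻¹⁵; the filter applies identically before training and before
test-time scoring.  Vectorization is channel-slowest then row-major —
any fixed order works, this one keeps channels contiguous so atoms
reshape naturally into c-channel blocks.  Training matrices can be
subsampled proportionally to class sizes under a patch budget; with the
balanced benchmark cohorts all surviving patches are used.

## Discriminative dictionary learning

Per class, with own-class matrix Y (N columns) and out-class Ȳ:

    min_D (1/N)·min_{‖S‖₀≤L} ‖Y − DS‖²_F − (ρ/N)·min_{‖S̄‖₀≤L} ‖Ȳ − DS̄‖²_F

over unit-norm atoms.  Both terms are divided by N by default;
`normalize_by_own_N=True` divides the out-class term by its own column
count instead (the other convention in the discriminative
dictionary-learning literature) — the two differ only in the effective ρ
when class sizes are unequal.

- **Sparse coder:** orthogonal matching pursuit, implemented in the Gram
  domain and vectorized over columns: per iteration the atom with
  maximal |residual correlation| joins the support, a full least-squares
  refit runs on the support (batched Cholesky solve; minimum-norm pinv
  fallback for collinear supports), stopping at L atoms or residual norm
  < 10⁻¹⁰.  An ℓ1 (LASSO) coder is available behind the same interface
  (off by default).
- **Dictionary update:** with codes fixed, atom j is moved to the
  stationary point of the quadratic surrogate built from
  E = (1/N)(Y Sᵀ − ρ Ȳ S̄ᵀ) and F = (1/N)(S Sᵀ − ρ S̄ S̄ᵀ), then
  renormalized.  The discriminative term can make F indefinite, so an
  atom is only updated when its curvature F_jj exceeds 10⁻⁸.
- **Hygiene:** atoms never selected by any in-class code are re-seeded
  from the worst-reconstructed in-class patches (standard
  dictionary-learning practice, an addition to the bare objective).
- **Initialization/stopping:** k distinct in-class patch columns chosen
  by seed, normalized; stop at 30 iterations or relative objective
  change < 10⁻⁴.  Fully deterministic given inputs and config.

Defaults k = 50 atoms/class, L = 5, ρ = 0.1.  The atom count matches the
standard 100-atom combined dictionary; L and ρ are exposed as config
(ρ has no universal best value — small ρ favors own-class fidelity,
large ρ favors out-class rejection; an inner-validation grid
{0.01, 0.05, 0.1, 0.5} is a reasonable search space).

At ρ = 0 the alternation is classical alternating minimization and the
objective descends from initialization (tested); with ρ > 0 the
surrogate update is heuristic, as in the original discriminative
formulation, and monotonicity is not guaranteed.

## Classification and evaluation

A test patch y is coded once against D_combined = [D₁ | D₂] with
sparsity L; the code splits into class halves and ε_i = ‖y − D_i s_i‖²
(the squared ℓ2 norm of the residual *vector* — the standard scalar
reading).  Label = argmin ε, ties to class 1 (deterministic and
documented; exact ties essentially occur only for zero codes).

θ = fraction of an entity's patches labeled class 1; at subject level
all the subject's images pool their patches.  Entities whose patches are
all filtered are flagged unscorable, excluded from metrics, and logged.

Metrics: rank-based (Mann–Whitney) AUC with ties credited 0.5, and
sensitivity/specificity at θ ≥ 0.5 plus the Youden-optimal threshold
(no principled fixed threshold exists for θ; both are reported).
Cross-validation is stratified on entities (images, or subjects with
their images traveling together so no subject leaks across the split);
per fold, dictionaries are trained on training entities' patches only.
Per-fold metrics are reported with their min–max range across folds.
Image-level evaluation deliberately ignores subject grouping — it is the
more optimistic paradigm and is reported as such.

## Atom interpretability

1. **Activity.**  Every patch (train + test) is coded against
   D_combined; only the half matching the patch's true class is
   interpreted for enrichment.  Per atom, code values are normalized by
   their maximum absolute value across patches (sign-preserving), then
   binarized: A = 1 iff the coefficient is strictly positive.  Negative
   coefficients mark atoms used to *subtract* structure — poorly
   representative — and are excluded by the recode; zero is not positive.
2. **Significant atoms.**  Per atom, per-image activation proportions
   are compared between own-class and other-class images with a Welch
   two-sample t-test; selected iff p < 0.05 *and* the own-class mean is
   larger.  (A literally paired test is impossible — the two classes
   contain different images — so the comparison is two-sample with the
   sign-and-magnitude selection rule retained.)
3. **Weighted partial correlations.**  A selected atom reshaped to
   n × n × c is treated as c channel images over the n² pixel lattice.
   A Gaussian kernel k(x_i, x_j) = exp(−‖x_i − x_j‖²/σ²) (default
   σ = n/2 = 10 cells) supplies per-pixel weights w_i = Σ_j k(x_i, x_j)
   (row sums; this keeps the weighted covariance positive semidefinite,
   unlike a cross-pixel double weighting).  Weighted channel means and
   covariance give partial correlations through the normalized inverse
   covariance; a conditional ridge toward the diagonal is applied only
   when the covariance is near-singular (so the c = 2 identity with
   weighted Pearson correlation holds exactly on well-conditioned
   inputs).  Constant channels yield NaN sentinels and are excluded.
4. **Significance by restricted randomization.**  Atom channels are
   spatially smooth, so freely permuting pixels within channels would
   conflate within-channel autocorrelation with cross-channel
   association (the effective sample size is far below the pixel count).
   The default null therefore randomizes each channel by an independent
   toroidal shift — a restricted permutation of pixel assignments that
   preserves each channel's autocorrelation while destroying
   cross-channel alignment.  Unrestricted permutation is available via
   `permutation="independent"`.  Two-sided p = (1 + #{|pcor*| ≥
   |pcor|})/(P + 1), default P = 999, seeded.  On iid noise channels the
   test is calibrated (≤ 5% flags at α = 0.05, tested).
5. **Pair proportions and class comparison.**  Per class, the fraction
   of selected atoms whose pair p-value < 0.05; classes compared per
   pair with a pooled two-proportion z-test (two-sided).  No
   multiple-testing correction by default (raw p < 0.05 per pair);
   Benjamini–Hochberg can be applied downstream by the caller.

## Benchmark experiments and problem sizes

The packaged benchmark (`phenodict.experiments`) plants an
Epithelial→CTL coupling of 0.8 in class 1 only, 20 subjects/class, one
image/subject, 70 × 50 grid, 20 × 20 × 5 patches at stride 10, 50
atoms/class, L = 5, ρ = 0.1.  Subject-grouped 5-fold CV on this cohort
reaches mean subject-level AUC ≥ 0.9 across seeds, and the
interpretability stage assigns the planted pair a class-1 proportion
near 1 against a null-level class-2 proportion, flagged by the z-test.
These sizes (≈ 40 images, ≈ 960 patches, 100 atoms) run the full
benchmark in well under a minute per seed and were chosen as the
smallest cohort at which subject-level CV is statistically meaningful.

## Numerical notes and degenerate inputs

- OMP Gram-domain recursions can lose precision on highly coherent
  dictionaries; residuals for classification are recomputed explicitly
  from the class-half reconstruction, not from the recursion.
- Zero training columns cannot seed atoms and are replaced by random
  unit vectors at initialization; an all-zero patch codes to the zero
  vector (residual = its norm) and binarizes to all-zero activity.
- Empty point patterns give identically zero surfaces; all-zero images
  lose every patch to the filter and become unscorable entities.
- The low-intensity filter compares `count/size > 0.70` in floating
  point, making the boundary (exactly 70%) a kept patch per the strict
  "more than" rule.

## Limitations

- The residual-split classifier has no reject option and its θ
  threshold is data-dependent; AUC is the primary metric.
- Atom-level inference treats atoms as independent draws in the
  z-test, ignoring that they were learned from overlapping patches.
- Partial-correlation p-values are conditional on the learned atoms;
  they quantify structure *within* atoms, not a population-level effect
  size for the tissue.
- Lattice-only patch extraction (no random sampling), single-resolution
  dictionaries, and exactly two classes are supported.
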