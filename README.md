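# phenodict

Discriminative dictionary learning for interpretable two-class
classification of multiplexed immunofluorescence (mIF) tissue images,
operating purely on cell positions and phenotype labels.

## The problem

mIF imaging assigns every segmented cell an (x, y) position and a
phenotype (here: Epithelial, CTL, HelperT, Treg, APC).  Clinically
distinct tissues — e.g. a cancerous versus an inflammatory pathology, or
immunotherapy responders versus non-responders — can differ subtly in how
these cell types are spatially arranged and co-localized.  `phenodict`
classifies such cohorts while exposing *why*: the learned dictionary
atoms are small prototype patches whose cross-phenotype correlation
structure can be read off directly.

## The method

1. **Intensity surfaces.**  Each phenotype's point pattern becomes an
   isotropic Gaussian kernel intensity estimate λ(u) on an l × m grid
   (default 70 × 50), edge-corrected so the surface integrates to the
   cell count.  The c = 5 surfaces stack into an l × m × c composite.
2. **Patches.**  Overlapping n × n × c patches (default 20 × 20 × 5,
   stride 10) are extracted; patches with more than 70% of values below
   10⁻¹⁵ are dropped; survivors are vectorized to d = n²c columns.
3. **Discriminative dictionaries.**  For each class a dictionary D of k
   unit-norm atoms (default 50) is learned by alternating OMP sparse
   coding and atom-wise updates of

   D* = argmin_D (1/N) min_{‖S‖₀≤L} ‖Y − DS‖²_F − (ρ/N) min_{‖S̄‖₀≤L} ‖Ȳ − DS̄‖²_F,

   so atoms reconstruct own-class patches well (first term) and
   other-class patches poorly (second term, weighted by ρ).
4. **Classification.**  A test patch is coded against D_combined =
   [D₁ | D₂]; the code splits into class halves and the patch takes the
   class with the smaller squared reconstruction residual.  Per image or
   subject, θ = (# patches labeled class 1)/(# patches) is the
   entity-level score, evaluated by AUC / sensitivity / specificity
   under stratified, subject-grouped k-fold cross-validation.
5. **Atom interpretability.**  Every patch's sparse code is binarized
   (1 iff the coefficient is positive); atoms whose per-image activation
   proportion is significantly higher in their own class (t-test,
   p < 0.05) are *significant*.  Each significant atom, reshaped to its
   n × n × c block, is probed with spatially weighted partial
   correlations between phenotype channels (Gaussian kernel weights,
   toroidal-shift randomization test), and per-pair correlated-atom
   proportions are compared between classes with a two-proportion z-test.

Because clinical cohorts of this kind are not publicly deposited, the
package ships a first-class synthetic cohort generator: homogeneous
Poisson phenotypes per image with a configurable fraction of one
phenotype's points relocated into Gaussian clusters around another's
(a Thomas-style parent/offspring coupling), optional per-subject
intensity heterogeneity, and full seed determinism.

## Worked example

`examples/03_train_and_classify.py` runs subject-grouped 5-fold CV on a
benchmark cohort of 20 subjects per class in which class 1 carries a
planted Epithelial→CTL coupling of 0.8 and class 2 none:

```
 fold    auc  sensitivity  specificity
    0 0.8750         1.00         0.25
    1 1.0000         0.50         1.00
    2 1.0000         0.75         1.00
    3 0.8125         1.00         0.75
    4 1.0000         0.50         1.00

mean subject-level AUC: 0.9375 (fold range 0.8125-1.0000)
```

The AUC near 1 means θ separates the coupled class from the independent
class almost perfectly even though the two classes have *identical*
per-phenotype cell densities — the classifier is reading spatial
co-localization alone.  `examples/04_atom_interpretability.py` then
recovers the planted pair from the learned atoms:

```
significant atoms: 50 (class 1), 50 (class 2)
planted pair Epithelial-CTL: class-1 proportion 1.00 vs class-2 0.08, z-test p = 2.72e-20
```

Every class-1 atom couples the Epithelial and CTL channels while the
other nine phenotype pairs stay at null-level proportions (0.02–0.22) —
the interpretability stage pinpoints exactly the interaction that was
planted.

The other examples (`01_simulate_cohort.py`, `02_surfaces_and_patches.py`)
demonstrate the generator and the surface/patch stages; a thin CLI mirrors
the stages for batch runs:

```bash
phenodict run-all --config examples/run.yaml
```

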