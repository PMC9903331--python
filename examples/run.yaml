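# Small demo run: simulate -> surfaces -> patches -> train -> evaluate
# -> atoms -> report, all under ./phenodict_demo.
seed: 1
outdir: phenodict_demo
cohort:
  n_subjects_per_class: 6
  images_per_subject: 1
  base_intensity_um2: 5.0e-4
  coupling_class1:
    Epithelial->CTL: 0.8
grid:
  n_rows: 70
  n_cols: 50
  cell_size_um: 20.0
patch:
  n: 20
  stride: 10
dfdl:
  k_atoms_per_class: 20
  L: 5
  rho: 0.1
  max_iters: 20
corr:
  sigma_px: 10.0
  n_permutations: 199
  alpha: 0.05
cv:
  mode: subject
  k: 3
  threshold: 0.5
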