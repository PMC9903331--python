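"""Discriminative dictionary training and subject-level cross-validation.

Trains one 50-atom dictionary per class (sparsity L = 5, trade-off
rho = 0.1) inside each fold of a subject-grouped 5-fold CV on the
planted-coupling benchmark cohort, then scores held-out subjects by
theta voting (fraction of a subject's patches labeled class 1).
"""

from phenodict.experiments import run_discrimination

result = run_discrimination(seed=2, k=5, mode="subject")
print(result.folds[["fold", "auc", "sensitivity", "specificity"]].to_string(index=False))
summary = result.summary()
print(f"\nmean subject-level AUC: {summary['auc']['mean']:.4f} "
      f"(fold range {summary['auc']['min']:.4f}-{summary['auc']['max']:.4f})")
print("AUC near 1 means theta cleanly separates the coupled class "
      "from the independent class at the subject level.")
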