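"""Canned end-to-end experiments on the synthetic benchmark cohort.

The benchmark cohort plants a strong Epithelial->CTL spatial coupling
(fraction 0.8, dispersion 20 um) in class 1 and none in class 2, with 20
subjects per class, one image per subject, equal per-phenotype baseline
intensity in both classes, a 70 x 50 grid at 20 um cells, 20 x 20 x 5
patches at stride 10, and 50 atoms per class with L = 5 and rho = 0.1.
Class separation therefore rests purely on cross-phenotype spatial
structure, which is the signal the method is designed to recover — both
as classification performance and as the planted pair's correlated-atom
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .atoms import (
    WeightedCorrConfig,
    compare_pair_proportions,
    compute_activity,
    pair_proportions,
    select_significant_atoms,
)
from .classify import CVResult, cross_validate
from .dfdl import DFDLConfig, train_pair
from .patches import PatchMatrix, PatchSpec, extract_patches, filter_low_intensity
from .simulate import default_cohort_spec, simulate_cohort
from .surfaces import composite_from_table

PLANTED_PAIR = ("Epithelial", "CTL")


def benchmark_cohort(
    seed: int,
    n_subjects_per_class: int = 20,
    images_per_subject: int | tuple[int, int] = 1,
):
    """Simulate the benchmark cohort and build its composites."""
    spec = default_cohort_spec(
        n_subjects_per_class=n_subjects_per_class,
        images_per_subject=images_per_subject,
        coupling_class1={PLANTED_PAIR: 0.8},
        coupling_class2={},
        seed=seed,
    )
    return [composite_from_table(t) for t in simulate_cohort(spec)]


def benchmark_configs(seed: int):
    return (
        PatchSpec(n=20, stride=10),
        DFDLConfig(k_atoms_per_class=50, L=5, rho=0.1, seed=seed),
        WeightedCorrConfig(seed=seed),
    )


def run_discrimination(
    seed: int,
    k: int = 5,
    mode: str = "subject",
    images_per_subject: int | tuple[int, int] = 1,
) -> CVResult:
    """Grouped k-fold CV of the classifier on the benchmark cohort."""
    composites = benchmark_cohort(seed, images_per_subject=images_per_subject)
    patch_spec, dfdl_cfg, _ = benchmark_configs(seed)
    return cross_validate(
        composites, patch_spec, dfdl_cfg, mode=mode, k=k, seed=seed
    )


@dataclass
class InterpretabilityResult:
    significance: pd.DataFrame
    proportions: pd.DataFrame  # includes z / p_value columns
    planted: pd.Series  # the planted pair's row

    @property
    def n_selected(self) -> tuple[int, int]:
        s = self.significance
        return (
            int(((s["class"] == 1) & s["selected"]).sum()),
            int(((s["class"] == 2) & s["selected"]).sum()),
        )


def run_interpretability(seed: int) -> InterpretabilityResult:
    """Train on the full benchmark cohort, then run the atom analysis."""
    composites = benchmark_cohort(seed)
    patch_spec, dfdl_cfg, corr_cfg = benchmark_configs(seed)
    pool = []
    for img in composites:
        pool.extend(filter_low_intensity(extract_patches(img, patch_spec), patch_spec))
    pm = PatchMatrix.from_patches(pool)
    split = pm.class_split()
    _, _, D = train_pair(split[1], split[2], dfdl_cfg)
    activity = compute_activity(pm, D, dfdl_cfg.L)
    sig = select_significant_atoms(activity, corr_cfg.alpha)
    channels = composites[0].channel_order
    table = pair_proportions(D, sig, patch_spec.n, channels, corr_cfg)
    table = compare_pair_proportions(table)
    a, b = PLANTED_PAIR
    planted = table[
        (table["phenotype_a"] == a) & (table["phenotype_b"] == b)
    ].iloc[0]
    return InterpretabilityResult(sig, table, planted)
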