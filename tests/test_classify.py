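"""Residual-split patch labels, theta voting, metrics and grouped CV."""

import logging

import numpy as np
import pandas as pd
import pytest

from phenodict import (
    CombinedDictionary,
    CompositeImage,
    DFDLConfig,
    GridSpec,
    PatchSpec,
    aggregate_theta,
    auc,
    classify_patch,
    classify_patches,
    cross_validate,
    sens_spec,
    youden_threshold,
)


def orthonormal_dictionary(k_per_class=2, d=8):
    atoms = np.eye(d)[:, : 2 * k_per_class]
    return CombinedDictionary(atoms, k_per_class)


def test_patch_matching_class1_atom_gets_label_1():
    D = orthonormal_dictionary()
    pred = classify_patch(D.atoms[:, 0], D, L=2)
    assert pred["eps1"] <= 1e-20
    assert pred["eps2"] > 0
    assert pred["label"] == 1


def test_patch_matching_class2_atom_gets_label_2():
    D = orthonormal_dictionary()
    pred = classify_patch(D.atoms[:, 3], D, L=2)
    assert pred["label"] == 2


def test_exact_tie_breaks_to_class_1():
    D = orthonormal_dictionary()
    y = np.zeros(8)
    y[7] = 1.0  # orthogonal to every atom: eps1 == eps2 == ||y||^2
    pred = classify_patch(y, D, L=2)
    assert np.isclose(pred["eps1"], pred["eps2"])
    assert pred["label"] == 1


def test_dimension_mismatch_raises():
    D = orthonormal_dictionary()
    with pytest.raises(ValueError, match="dimension"):
        classify_patch(np.zeros(5), D, L=2)


def _pred_frame(labels, image_id="img1"):
    return pd.DataFrame(
        {"image_id": image_id, "label": labels, "class": 1}
    )


@pytest.mark.parametrize(
    "labels, theta",
    [
        ([1] * 3 + [2] * 21, 0.125),
        ([1] * 24, 1.0),
        ([2] * 24, 0.0),
    ],
)
def test_theta_worked_examples(labels, theta):
    scored = aggregate_theta(_pred_frame(labels))
    assert scored.loc[0, "theta"] == theta
    assert scored.loc[0, "n_patches"] == 24


def test_theta_pools_images_at_subject_level():
    df = pd.DataFrame(
        {
            "subject_id": ["s1"] * 4 + ["s1"] * 4,
            "image_id": ["i1"] * 4 + ["i2"] * 4,
            "label": [1, 1, 1, 1, 2, 2, 2, 2],
            "class": 1,
        }
    )
    scored = aggregate_theta(df, by="subject_id")
    assert len(scored) == 1
    assert scored.loc[0, "theta"] == 0.5
    assert scored.loc[0, "n_patches"] == 8


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) != 1]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example_with_tie():
    scores = [0.9, 0.8, 0.8, 0.1]
    labels = [1, 1, 2, 2]
    assert np.isclose(auc(scores, labels), 0.875)
    assert np.isclose(brute_force_auc(scores, labels), 0.875)


def test_auc_matches_brute_force_pair_counting():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(4, 30))
        scores = rng.choice(np.linspace(0, 1, 9), size=n)
        labels = rng.choice([1, 2], size=n)
        if len(np.unique(labels)) < 2:
            continue
        assert np.isclose(auc(scores, labels), brute_force_auc(scores, labels))


def test_auc_is_half_under_label_shuffling():
    rng = np.random.default_rng(1)
    scores = rng.random(2000)
    labels = rng.permutation(np.repeat([1, 2], 1000))
    assert abs(auc(scores, labels) - 0.5) < 0.05


def test_auc_perfect_separation_and_symmetry():
    scores = [0.9, 0.8, 0.2, 0.1]
    labels = [1, 1, 2, 2]
    assert auc(scores, labels) == 1.0
    # Swapping class roles maps AUC to 1 - AUC.
    assert np.isclose(auc(scores, labels, reference_class=2), 0.0)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.random(50)
    labels = rng.choice([1, 2], size=50)
    a = auc(scores, labels)
    assert np.isclose(auc(np.exp(3 * scores), labels), a)


def test_auc_single_class_raises():
    with pytest.raises(ValueError, match="both classes"):
        auc([0.1, 0.2], [1, 1])


def test_sens_spec_threshold_extremes():
    scores = np.array([1.0, 0.6, 0.4, 0.0])
    labels = np.array([1, 1, 2, 2])
    assert sens_spec(scores, labels, 0.0) == (1.0, 0.0)
    assert sens_spec(scores, labels, 1.1) == (0.0, 1.0)
    assert sens_spec(scores, labels, 0.5) == (1.0, 1.0)


def test_sens_spec_swaps_under_class_role_swap():
    scores = np.array([0.9, 0.6, 0.3, 0.2, 0.8])
    labels = np.array([1, 1, 2, 2, 2])
    se, sp = sens_spec(scores, labels, 0.55)
    se2, sp2 = sens_spec(1.0 - scores, 3 - labels, 0.55)
    assert (se2, sp2) == (sp, se)


def test_youden_threshold_maximizes_j():
    scores = np.array([0.9, 0.7, 0.65, 0.3, 0.2])
    labels = np.array([1, 1, 1, 2, 2])
    t = youden_threshold(scores, labels)
    se, sp = sens_spec(scores, labels, t)
    assert se + sp - 1.0 == 1.0  # perfectly separable


def _toy_composites(n_subjects=8, images_per_subject=2, seed=0):
    """Class signal in disjoint channels; small grid for fast CV."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(n_rows=30, n_cols=30, cell_size_um=10.0)
    comps = []
    for cls in (1, 2):
        for s in range(n_subjects):
            sid = f"c{cls}s{s}"
            for i in range(images_per_subject):
                stack = rng.random((30, 30, 4)) * 0.05
                ch = 0 if cls == 1 else 3
                stack[:, :, ch] += rng.random((30, 30))
                comps.append(
                    CompositeImage(stack, ("a", "b", "c", "d"), grid, f"{sid}i{i}", sid, cls)
                )
    return comps


FAST_CFG = DFDLConfig(k_atoms_per_class=6, L=2, rho=0.1, max_iters=8, seed=0)
FAST_PATCH = PatchSpec(n=10, stride=10, low_frac=0.7, low_tol=1e-15)


def test_cross_validate_subject_mode_has_no_subject_leakage():
    comps = _toy_composites()
    res = cross_validate(comps, FAST_PATCH, FAST_CFG, mode="subject", k=4, seed=1)
    # Every subject is scored exactly once across folds => it was in exactly
    # one test side, hence never in both train and test of the same fold.
    counts = res.predictions.groupby("entity").size()
    assert (counts == 1).all()
    assert set(res.predictions["entity"]) == {c.subject_id for c in comps}
    assert res.folds["auc"].mean() > 0.9  # disjoint channels are easy


def test_cross_validate_fold_sizes_balanced():
    comps = _toy_composites(n_subjects=10, images_per_subject=1)
    res = cross_validate(comps, FAST_PATCH, FAST_CFG, mode="subject", k=4, seed=2)
    per_fold = res.predictions.groupby(["fold"]).apply(
        lambda df: df.groupby("class").size(), include_groups=False
    )
    for cls in (1, 2):
        sizes = per_fold[cls].to_numpy()
        assert sizes.max() - sizes.min() <= 1


def test_cross_validate_image_mode_treats_images_independently():
    comps = _toy_composites(n_subjects=5, images_per_subject=2)
    res = cross_validate(comps, FAST_PATCH, FAST_CFG, mode="image", k=4, seed=3)
    assert set(res.predictions["entity"]) == {c.image_id for c in comps}


def test_cross_validate_rejects_too_many_folds():
    comps = _toy_composites(n_subjects=3, images_per_subject=1)
    with pytest.raises(ValueError, match="smaller k"):
        cross_validate(comps, FAST_PATCH, FAST_CFG, mode="subject", k=5)


def test_unscorable_image_is_excluded_with_warning(caplog):
    comps = _toy_composites(n_subjects=4, images_per_subject=1)
    dead = comps[0]
    comps.append(
        CompositeImage(
            np.zeros_like(dead.stack), dead.channel_order, dead.grid, "deadimg", "deads", 1
        )
    )
    with caplog.at_level(logging.WARNING):
        res = cross_validate(comps, FAST_PATCH, FAST_CFG, mode="image", k=3, seed=4)
    assert "deadimg" not in set(res.predictions["entity"])
    assert any("zero surviving patches" in r.message for r in caplog.records)


def test_patch_discriminability_increases_with_coupling_difference():
    """Held-out patch accuracy rises monotonically with the planted
    coupling difference between the classes."""
    from scipy.stats import spearmanr

    from phenodict import (
        PatchMatrix,
        default_cohort_spec,
        composite_from_table,
        extract_patches,
        filter_low_intensity,
        simulate_cohort,
        train_pair,
        classify_patches,
    )

    levels = [0.0, 0.2, 0.4, 0.6, 0.8]
    patch_spec = PatchSpec(n=20, stride=10)
    cfg = DFDLConfig(k_atoms_per_class=20, L=3, rho=0.1, max_iters=15, seed=0)
    mean_acc = []
    for level in levels:
        accs = []
        for seed in (1, 2, 3):
            spec = default_cohort_spec(
                n_subjects_per_class=8,
                coupling_class1={("Epithelial", "CTL"): level},
                seed=seed,
            )
            comps = [composite_from_table(t) for t in simulate_cohort(spec)]
            train_pool = {1: [], 2: []}
            test_pool = []
            for img in comps:
                kept = filter_low_intensity(extract_patches(img, patch_spec), patch_spec)
                subj_idx = int(img.subject_id[-3:])
                if subj_idx < 6:
                    train_pool[img.class_label].extend(kept)
                else:
                    test_pool.extend(kept)
            _, _, D = train_pair(
                PatchMatrix.from_patches(train_pool[1]),
                PatchMatrix.from_patches(train_pool[2]),
                cfg,
            )
            preds = classify_patches(PatchMatrix.from_patches(test_pool), D, cfg.L)
            accs.append((preds["label"] == preds["class"]).mean())
        mean_acc.append(np.mean(accs))
    rho, _ = spearmanr(levels, mean_acc)
    assert rho > 0.8
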