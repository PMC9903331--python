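"""Atom activity binarization, significance selection, weighted partial
correlations and between-class proportion comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodict import (
    CombinedDictionary,
    PatchMatrix,
    WeightedCorrConfig,
    atom_to_patch,
    compare_pair_proportions,
    compute_activity,
    pair_proportions,
    select_significant_atoms,
    weighted_partial_correlation,
)
from phenodict.atoms import ActivityRecord, _pixel_weights


def _meta(n, cls=1, image_id="i1", subject_id="s1"):
    return pd.DataFrame(
        {
            "image_id": [image_id] * n,
            "subject_id": [subject_id] * n,
            "class": [cls] * n,
        }
    )


def identity_dictionary(d=4):
    return CombinedDictionary(np.eye(d)[:, :4], 2)


def test_recode_positive_value_is_one_zero_is_zero():
    D = identity_dictionary()
    # Patch columns aligned with atoms: +0.3 on atom0, -0.5 on atom1, none.
    cols = np.stack(
        [0.3 * D.atoms[:, 0], -0.5 * D.atoms[:, 1], np.zeros(4)], axis=1
    )
    meta = pd.concat([_meta(2, 1), _meta(1, 2, "i2", "s2")], ignore_index=True)
    act = compute_activity(PatchMatrix(cols, meta), D, L=2)
    assert act.binary[0, 0] == 1  # A_o = 0.3 > 0
    assert act.binary[1, 1] == 0  # negative coefficient excluded
    assert (act.binary[:, 2] == 0).all()  # zero code


def test_atom_with_no_positive_codes_has_zero_activity_column():
    D = identity_dictionary()
    cols = np.stack([-1.0 * D.atoms[:, 3], -0.2 * D.atoms[:, 3]], axis=1)
    meta = pd.concat([_meta(1, 1), _meta(1, 2, "i2", "s2")], ignore_index=True)
    act = compute_activity(PatchMatrix(cols, meta), D, L=1)
    assert (act.binary[3, :] == 0).all()


def test_normalization_is_sign_preserving():
    D = identity_dictionary()
    cols = np.stack([5.0 * D.atoms[:, 0], -3.0 * D.atoms[:, 0]], axis=1)
    meta = pd.concat([_meta(1, 1), _meta(1, 2, "i2", "s2")], ignore_index=True)
    act = compute_activity(PatchMatrix(cols, meta), D, L=1)
    assert np.isclose(np.abs(act.values[0]).max(), 1.0)
    np.testing.assert_array_equal(act.binary[0], [1, 0])


def test_binarization_is_idempotent():
    rng = np.random.default_rng(0)
    binary = (rng.random((6, 40)) > 0.5).astype(np.int8)
    np.testing.assert_array_equal((binary > 0).astype(np.int8), binary)


def _planted_activity(p_own=0.9, p_other=0.05, n_images=20, n_patches=20, seed=0):
    """Activity record with atom 0 (class 1) active mostly in class-1 images."""
    rng = np.random.default_rng(seed)
    k = 2  # atoms per class -> 4 total
    D = identity_dictionary()
    metas, cols = [], []
    for cls in (1, 2):
        for i in range(n_images):
            metas.append(_meta(n_patches, cls, f"c{cls}i{i}", f"c{cls}s{i}"))
    meta = pd.concat(metas, ignore_index=True)
    n_total = len(meta)
    binary = np.zeros((4, n_total), dtype=np.int8)
    is_c1 = (meta["class"] == 1).to_numpy()
    binary[0, is_c1] = rng.random(is_c1.sum()) < p_own
    binary[0, ~is_c1] = rng.random((~is_c1).sum()) < p_other
    # Remaining atoms: same moderate rate in both classes.
    for j in (1, 2, 3):
        binary[j] = rng.random(n_total) < 0.3
    return ActivityRecord(binary.astype(float), binary, meta, D)


def test_planted_discriminative_atom_is_selected_with_positive_t():
    sig = select_significant_atoms(_planted_activity(), alpha=0.05)
    row = sig[sig["atom"] == 0].iloc[0]
    assert row["selected"]
    assert row["t_value"] > 0
    # Oracle: direct Welch t on per-image proportions.
    act = _planted_activity()
    props = (
        pd.DataFrame({"img": act.meta["image_id"], "act": act.binary[0]})
        .groupby("img")["act"].mean()
    )
    cls = act.meta.groupby("image_id")["class"].first()
    t_ref, _ = stats.ttest_ind(props[cls == 1], props[cls == 2], equal_var=False)
    assert np.isclose(row["t_value"], t_ref)


def test_identical_activation_selects_nothing():
    act = _planted_activity(p_own=0.3, p_other=0.3, seed=1)
    # Force exact equality: constant activation everywhere.
    act.binary[:] = 1
    sig = select_significant_atoms(act, alpha=0.05)
    assert not sig["selected"].any()


def test_alpha_zero_selects_nothing():
    sig = select_significant_atoms(_planted_activity(), alpha=0.0)
    assert not sig["selected"].any()


def test_select_requires_two_images_per_class():
    act = _planted_activity(n_images=1)
    with pytest.raises(ValueError, match="at least 2 images"):
        select_significant_atoms(act)


def test_atom_to_patch_roundtrip_and_onehot():
    rng = np.random.default_rng(2)
    block = rng.random((6, 6, 3))
    from phenodict import vectorize

    np.testing.assert_array_equal(atom_to_patch(vectorize(block), 6, 3), block)
    one_hot = np.zeros(6 * 6 * 3)
    one_hot[2 * 36 + 1 * 6 + 4] = 1.0  # channel 2, row 1, col 4
    assert atom_to_patch(one_hot, 6, 3)[1, 4, 2] == 1.0
    with pytest.raises(ValueError, match="length"):
        atom_to_patch(np.zeros(10), 6, 3)


def weighted_pearson(za, zb, w):
    ma = np.sum(w * za) / w.sum()
    mb = np.sum(w * zb) / w.sum()
    cov = np.sum(w * (za - ma) * (zb - mb))
    return cov / np.sqrt(np.sum(w * (za - ma) ** 2) * np.sum(w * (zb - mb) ** 2))


def test_c2_partial_correlation_equals_weighted_pearson():
    rng = np.random.default_rng(3)
    cfg = WeightedCorrConfig(sigma_px=4.0, n_permutations=1, seed=0)
    for _ in range(100):
        block = rng.random((8, 8, 2))
        pcor, _ = weighted_partial_correlation(block, cfg)
        w = _pixel_weights(8, 4.0)
        ref = weighted_pearson(block[:, :, 0].ravel(), block[:, :, 1].ravel(), w)
        assert abs(pcor[0, 1] - ref) < 1e-10
        assert np.isclose(pcor[0, 1], pcor[1, 0])
        assert pcor[0, 0] == 1.0 and pcor[1, 1] == 1.0


def test_duplicated_channel_has_near_unit_partial_correlation():
    rng = np.random.default_rng(4)
    block = np.empty((10, 10, 3))
    block[:, :, 0] = rng.random((10, 10))
    block[:, :, 1] = block[:, :, 0]  # exact copy
    block[:, :, 2] = rng.random((10, 10))
    cfg = WeightedCorrConfig(sigma_px=5.0, n_permutations=9, shrinkage=True, seed=1)
    pcor, _ = weighted_partial_correlation(block, cfg)
    assert pcor[0, 1] >= 0.99


def test_null_channels_have_small_pcor_and_controlled_flag_rate():
    rng = np.random.default_rng(5)
    cfg = WeightedCorrConfig(sigma_px=10.0, n_permutations=199, seed=6)
    medians, flags, n_pairs = [], 0, 0
    for _ in range(100):
        block = rng.standard_normal((20, 20, 5))
        pcor, pvals = weighted_partial_correlation(block, cfg)
        iu = np.triu_indices(5, 1)
        medians.append(np.median(np.abs(pcor[iu])))
        flags += int((pvals[iu] < 0.05).sum())
        n_pairs += len(iu[0])
    assert np.median(medians) < 0.1
    assert flags / n_pairs <= 0.10


def test_partial_correlation_matrix_symmetric_unit_diagonal():
    rng = np.random.default_rng(7)
    block = rng.random((9, 9, 4))
    cfg = WeightedCorrConfig(sigma_px=4.0, n_permutations=19, seed=2)
    pcor, pvals = weighted_partial_correlation(block, cfg)
    np.testing.assert_allclose(pcor, pcor.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(pcor), 1.0)
    np.testing.assert_allclose(pvals, pvals.T, atol=1e-12)


def test_constant_channel_yields_nan_sentinels():
    rng = np.random.default_rng(8)
    block = rng.random((8, 8, 3))
    block[:, :, 1] = 0.7
    cfg = WeightedCorrConfig(sigma_px=4.0, n_permutations=9, seed=3)
    pcor, pvals = weighted_partial_correlation(block, cfg)
    assert np.isnan(pcor[0, 1]) and np.isnan(pvals[1, 2])
    assert np.isfinite(pcor[0, 2])


def _significance_frame():
    return pd.DataFrame(
        {
            "atom": [0, 1, 2, 3],
            "class": [1, 1, 2, 2],
            "t_value": [3.0, 3.0, 3.0, 3.0],
            "p_value": [0.01] * 4,
            "selected": [True] * 4,
        }
    )


def test_pair_proportions_perfectly_correlated_pair_is_one():
    # Atoms whose channels 0 and 1 are identical fields.  The block is
    # large enough that a chance identical toroidal shift of both
    # channels (which would realign the duplicates under the null) is
    # rare: probability 1/n^2 per draw.
    rng = np.random.default_rng(9)
    n, c = 12, 3
    atom_blocks = []
    for _ in range(4):
        base = rng.random((n, n))
        block = np.stack([base, base, rng.random((n, n))], axis=-1)
        atom_blocks.append(block)
    from phenodict import vectorize

    atoms = np.stack([vectorize(b) for b in atom_blocks], axis=1)
    atoms /= np.linalg.norm(atoms, axis=0)
    D = CombinedDictionary(atoms, 2)
    cfg = WeightedCorrConfig(sigma_px=6.0, n_permutations=199, seed=4)
    table = pair_proportions(D, _significance_frame(), n, ("a", "b", "c"), cfg)
    row = table[(table["phenotype_a"] == "a") & (table["phenotype_b"] == "b")].iloc[0]
    assert row["proportion_class1"] == 1.0
    assert row["proportion_class2"] == 1.0


def test_pair_proportions_constant_channels_count_zero():
    n, c = 6, 3
    rng = np.random.default_rng(10)
    blocks = [
        np.stack([np.full((n, n), 0.5), rng.random((n, n)), np.full((n, n), 0.2)], axis=-1)
        for _ in range(4)
    ]
    from phenodict import vectorize

    atoms = np.stack([vectorize(b) for b in blocks], axis=1)
    atoms /= np.linalg.norm(atoms, axis=0)
    D = CombinedDictionary(atoms, 2)
    cfg = WeightedCorrConfig(sigma_px=3.0, n_permutations=49, seed=5)
    table = pair_proportions(D, _significance_frame(), n, ("a", "b", "c"), cfg)
    row = table[(table["phenotype_a"] == "a") & (table["phenotype_b"] == "c")].iloc[0]
    assert row["proportion_class1"] == 0.0 and row["proportion_class2"] == 0.0


def closed_form_two_proportion_z(x1, n1, x2, n2):
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return z, 2 * stats.norm.sf(abs(z))


def _proportion_table(x1, n1, x2, n2):
    return pd.DataFrame(
        {
            "phenotype_a": ["a"],
            "phenotype_b": ["b"],
            "n_atoms_class1": [n1],
            "n_correlated_class1": [x1],
            "proportion_class1": [x1 / n1],
            "n_atoms_class2": [n2],
            "n_correlated_class2": [x2],
            "proportion_class2": [x2 / n2 if n2 else np.nan],
        }
    )


def test_equal_proportions_give_z_zero_p_one():
    out = compare_pair_proportions(_proportion_table(10, 30, 10, 30))
    assert out.loc[0, "z"] == 0.0 and out.loc[0, "p_value"] == 1.0


def test_z_test_matches_closed_form_pooled_oracle():
    out = compare_pair_proportions(_proportion_table(24, 30, 15, 30))
    z_ref, p_ref = closed_form_two_proportion_z(24, 30, 15, 30)
    assert np.isclose(out.loc[0, "z"], z_ref)
    assert np.isclose(out.loc[0, "p_value"], p_ref)
    assert np.isclose(abs(z_ref), 2.4360, atol=1e-4)  # frozen oracle value


def test_extreme_proportions_are_highly_significant():
    out = compare_pair_proportions(_proportion_table(30, 30, 0, 30))
    assert out.loc[0, "p_value"] < 0.001


def test_zero_selected_atoms_class_skips_pair(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        out = compare_pair_proportions(_proportion_table(5, 10, 0, 0))
    assert np.isnan(out.loc[0, "z"])
    assert any("zero selected atoms" in r.message for r in caplog.records)
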