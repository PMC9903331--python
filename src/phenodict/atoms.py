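"""Dictionary-atom interpretability analysis.

After training, every patch is sparse-coded against the combined
dictionary and the code values are binarized (1 for a strictly positive
coefficient, 0 otherwise; negative coefficients mark poorly represented
atoms and are excluded by the recode).  Atoms whose per-image activation
proportion is significantly higher in their own class than in the other
class (two-sample t-test, p < alpha) are deemed class-representative.

Each significant atom, reshaped back into its n x n x c block, is then
probed for cross-phenotype structure: a spatially weighted partial
correlation between every pair of channels, with a Gaussian kernel over
pixel positions supplying the weights, and significance assessed by a
seeded randomization test.  Per class, the fraction of significant atoms
in which a phenotype pair is correlated is reported, and a pooled
two-proportion z-test compares the two classes per pair.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .dfdl import CombinedDictionary, omp_batch
from .patches import PatchMatrix, unvectorize

logger = logging.getLogger(__name__)


@dataclass
class ActivityRecord:
    """Binarized sparse-code activity of every patch against every atom.

    ``values`` holds the per-atom max-|value| normalized codes (2k x N),
    ``binary`` the recode ``A_i = 1 iff A_o > 0``; ``meta`` aligns columns
    with patch provenance (image, subject, class).
    """

    values: np.ndarray
    binary: np.ndarray
    meta: pd.DataFrame
    dictionary: CombinedDictionary

    def own_class_mask(self) -> np.ndarray:
        """(2k, N) bool: atom half matches the patch's true class."""
        atom_cls = np.array(
            [self.dictionary.atom_class(j) for j in range(self.dictionary.n_atoms)]
        )
        patch_cls = self.meta["class"].to_numpy(int)
        return atom_cls[:, None] == patch_cls[None, :]


def compute_activity(
    Y: PatchMatrix, D: CombinedDictionary, L: int
) -> ActivityRecord:
    """Code every patch against [D1 | D2] and binarize per-atom activity.

    Each atom's code values are normalized to unit maximum absolute value
    across all patches before recoding (sign-preserving, so the recode is
    unaffected by the normalization).
    """
    for cls in D.class_labels:
        if not (Y.meta["class"] == cls).any():
            raise ValueError(f"class {cls} has zero patches")
    codes, _ = omp_batch(Y.columns, D.atoms, L)
    peak = np.abs(codes).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    values = codes / peak
    binary = (values > 0).astype(np.int8)
    return ActivityRecord(values, binary, Y.meta.reset_index(drop=True), D)


def select_significant_atoms(
    activity: ActivityRecord, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sample t-test on per-image activation proportions, per atom.

    For each atom, the fraction of active patches is computed per image;
    own-class images are compared with other-class images (whose patches
    were coded against the same combined dictionary).  An atom is
    ``selected`` iff p < alpha and its own-class mean proportion is the
    larger one (the sign of t identifies the enriched class).
    """
    D = activity.dictionary
    meta = activity.meta
    img_class = meta.groupby("image_id")["class"].first()
    for cls in D.class_labels:
        if (img_class == cls).sum() < 2:
            raise ValueError(f"need at least 2 images of class {cls}")
    # Per-image mean activation of every atom (proportion of active patches).
    image_ids = img_class.index.to_numpy()
    col_img = meta["image_id"].to_numpy()
    props = np.empty((D.n_atoms, len(image_ids)))
    for i, img in enumerate(image_ids):
        cols = col_img == img
        props[:, i] = activity.binary[:, cols].mean(axis=1)
    img_labels = img_class.to_numpy(int)
    rows = []
    for j in range(D.n_atoms):
        own_cls = D.atom_class(j)
        own = props[j, img_labels == own_cls]
        other = props[j, img_labels != own_cls]
        if np.ptp(own) == 0 and np.ptp(other) == 0 and own.mean() == other.mean():
            t_val, p_val = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t_val, p_val = stats.ttest_ind(own, other, equal_var=False)
            if np.isnan(p_val):
                t_val, p_val = 0.0, 1.0
        rows.append(
            {
                "atom": j,
                "class": own_cls,
                "t_value": float(t_val),
                "p_value": float(p_val),
                "own_mean": float(own.mean()),
                "other_mean": float(other.mean()),
                "selected": bool(p_val < alpha and own.mean() > other.mean()),
            }
        )
    return pd.DataFrame(rows)


def atom_to_patch(atom: np.ndarray, n: int, c: int) -> np.ndarray:
    """Reshape a dictionary atom back into its n x n x c block."""
    return unvectorize(atom, n, c)


@dataclass(frozen=True)
class WeightedCorrConfig:
    """Spatially weighted partial-correlation settings.

    ``sigma_px`` is the Gaussian kernel bandwidth in patch cells (the
    kernel is ``exp(-||xi - xj||^2 / sigma^2)``); significance is by a
    seeded randomization test with ``n_permutations`` draws.  The default
    ``permutation="shift"`` randomizes channels by toroidal shifts, which
    preserves each channel's spatial autocorrelation under the null;
    ``"independent"`` permutes pixels freely instead.
    """

    sigma_px: float = 10.0
    n_permutations: int = 999
    shrinkage: bool = True
    alpha: float = 0.05
    permutation: str = "shift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.permutation not in ("shift", "independent"):
            raise ValueError("permutation must be 'shift' or 'independent'")


def _pixel_weights(n: int, sigma: float) -> np.ndarray:
    """Per-pixel weights: row sums of the Gaussian kernel matrix."""
    r, c = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    coords = np.stack([r.ravel(), c.ravel()], axis=1).astype(float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    W = np.exp(-d2 / sigma**2)
    return W.sum(axis=1)


def _weighted_cov(Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted covariance over pixels; Z is (..., n_px, c), w is (n_px,)."""
    wsum = w.sum()
    mean = np.einsum("i,...ic->...c", w, Z) / wsum
    Zc = Z - mean[..., None, :]
    return np.einsum("...ic,i,...id->...cd", Zc, w, Zc) / wsum


def _partial_corr_from_cov(cov: np.ndarray, shrinkage: bool) -> np.ndarray:
    """Batched partial correlations from covariance matrices (..., c, c)."""
    cov = np.array(cov, dtype=float, copy=True)
    c = cov.shape[-1]
    scale = np.trace(cov, axis1=-2, axis2=-1) / c
    scale = np.where(scale <= 0, 1.0, scale)
    if shrinkage:
        # Conditional ridge toward the diagonal, applied only when the
        # matrix is near-singular relative to its average variance.
        ev_min = np.linalg.eigvalsh(cov)[..., 0]
        ridge = np.clip(1e-6 * scale - ev_min, 0.0, None)
        cov += ridge[..., None, None] * np.eye(c)
    prec = np.linalg.pinv(cov)
    diag = np.sqrt(np.einsum("...ii->...i", prec))
    pcor = -prec / (diag[..., :, None] * diag[..., None, :])
    idx = np.arange(c)
    pcor[..., idx, idx] = 1.0
    return pcor


def weighted_partial_correlation(
    block: np.ndarray, cfg: WeightedCorrConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially weighted partial correlations between the block's channels.

    Returns ``(pcor, pvals)``, both c x c and symmetric; entries involving
    a constant channel are NaN and should be excluded downstream.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 3 or block.shape[2] < 2:
        raise ValueError("block must be n x n x c with c >= 2")
    if not np.isfinite(block).all():
        raise ValueError("block contains non-finite values")
    n, n2, c = block.shape
    if n != n2:
        raise ValueError("block must be square in its spatial dimensions")
    Z = block.reshape(n * n, c)
    w = _pixel_weights(n, cfg.sigma_px)
    constant = np.ptp(Z, axis=0) == 0
    cov = _weighted_cov(Z, w)
    pcor = _partial_corr_from_cov(cov, cfg.shrinkage)

    rng = np.random.default_rng(cfg.seed)
    P = cfg.n_permutations
    if cfg.permutation == "independent":
        perm_idx = np.stack(
            [np.stack([rng.permutation(n * n) for _ in range(c)], axis=1) for _ in range(P)]
        )  # (P, n_px, c)
    else:
        # Toroidal shifts: one random (dr, dc) per channel per draw.
        r, col = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        shifts = rng.integers(0, n, size=(P, c, 2))
        rr = (r.ravel()[None, None, :] + shifts[:, :, 0, None]) % n
        cc = (col.ravel()[None, None, :] + shifts[:, :, 1, None]) % n
        perm_idx = (rr * n + cc).transpose(0, 2, 1)  # (P, n_px, c)
    Zp = np.take_along_axis(Z[None, :, :], perm_idx, axis=1)
    pcor_null = _partial_corr_from_cov(_weighted_cov(Zp, w), cfg.shrinkage)
    exceed = (np.abs(pcor_null) >= np.abs(pcor)[None, :, :] - 1e-12).sum(axis=0)
    pvals = (1.0 + exceed) / (P + 1.0)
    idx = np.arange(c)
    pvals[idx, idx] = 0.0
    if constant.any():
        pcor[constant, :] = np.nan
        pcor[:, constant] = np.nan
        pvals[constant, :] = np.nan
        pvals[:, constant] = np.nan
        pcor[idx, idx] = np.where(constant, np.nan, 1.0)
    return pcor, pvals


def pair_proportions(
    D: CombinedDictionary,
    significance: pd.DataFrame,
    n: int,
    channel_names: tuple[str, ...],
    cfg: WeightedCorrConfig,
) -> pd.DataFrame:
    """Per phenotype pair and class: fraction of selected atoms correlated.

    An atom counts as correlated for a pair iff the pair's weighted
    partial-correlation p-value is below ``cfg.alpha``.
    """
    c = len(channel_names)
    selected = significance[significance["selected"]]
    for cls in D.class_labels:
        if not (selected["class"] == cls).any():
            raise ValueError(f"class {cls} has no selected atoms")
    pairs = list(itertools.combinations(range(c), 2))
    counts = {(cls, pr): 0 for cls in D.class_labels for pr in pairs}
    totals = {cls: 0 for cls in D.class_labels}
    for _, row in selected.iterrows():
        j, cls = int(row["atom"]), int(row["class"])
        block = atom_to_patch(D.atoms[:, j], n, c)
        _, pvals = weighted_partial_correlation(block, cfg)
        totals[cls] += 1
        for a, b in pairs:
            p = pvals[a, b]
            if np.isfinite(p) and p < cfg.alpha:
                counts[(cls, (a, b))] += 1
    rows = []
    for a, b in pairs:
        row = {"phenotype_a": channel_names[a], "phenotype_b": channel_names[b]}
        for cls in D.class_labels:
            row[f"n_atoms_class{cls}"] = totals[cls]
            row[f"n_correlated_class{cls}"] = counts[(cls, (a, b))]
            row[f"proportion_class{cls}"] = counts[(cls, (a, b))] / totals[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_pair_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Pooled two-proportion z-test (two-sided) between classes, per pair."""
    out = table.copy()
    zs, ps = [], []
    for _, row in table.iterrows():
        n1, n2 = int(row["n_atoms_class1"]), int(row["n_atoms_class2"])
        if n1 == 0 or n2 == 0:
            logger.warning(
                "pair %s-%s skipped: a class has zero selected atoms",
                row["phenotype_a"], row["phenotype_b"],
            )
            zs.append(np.nan)
            ps.append(np.nan)
            continue
        x1, x2 = int(row["n_correlated_class1"]), int(row["n_correlated_class2"])
        if x1 == x2 and n1 == n2:
            zs.append(0.0)
            ps.append(1.0)
            continue
        pooled = (x1 + x2) / (n1 + n2)
        if pooled in (0.0, 1.0):
            zs.append(0.0)
            ps.append(1.0)
            continue
        z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        zs.append(float(z))
        ps.append(float(p))
    out["z"] = zs
    out["p_value"] = ps
    return out
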