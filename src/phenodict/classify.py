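"""Residual-based patch classification, theta voting and grouped CV.

A test patch is coded against the combined dictionary [D1 | D2]; the
code is split into its class halves and the patch is assigned to the
class whose half reconstructs it with the smaller squared l2 residual
(ties go to class 1).  Patch labels are aggregated per image or per
subject into theta, the fraction of patches labeled class 1, which acts
as the entity-level class-1 score for AUC/sensitivity/specificity.

Cross-validation is stratified on entities; in subject mode all of a
subject's images travel together between folds, so no subject appears
in both the training and test side of any fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dfdl import CombinedDictionary, DFDLConfig, omp_batch, train_pair
from .patches import PatchMatrix, PatchSpec, extract_patches, filter_low_intensity
from .surfaces import CompositeImage

logger = logging.getLogger(__name__)


def classify_patches(
    Y: PatchMatrix | np.ndarray, D: CombinedDictionary, L: int
) -> pd.DataFrame:
    """Residual-split classification of every column of ``Y``.

    Returns a frame with ``eps1``, ``eps2`` (squared residual norms
    against each class half of the combined code) and ``label``.
    """
    mat = Y.columns if isinstance(Y, PatchMatrix) else np.asarray(Y, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] != D.atoms.shape[0]:
        raise ValueError("patch dimension does not match dictionary")
    codes, _ = omp_batch(mat, D.atoms, L)
    out = {}
    for cls in D.class_labels:
        half = D.half(cls)
        sub = codes[D.half_slice(cls), :]
        resid = mat - half @ sub
        out[cls] = np.einsum("ij,ij->j", resid, resid)
    eps1, eps2 = out[D.class_labels[0]], out[D.class_labels[1]]
    label = np.where(eps1 <= eps2, D.class_labels[0], D.class_labels[1])
    df = pd.DataFrame({"eps1": eps1, "eps2": eps2, "label": label})
    if isinstance(Y, PatchMatrix):
        df = pd.concat([Y.meta.reset_index(drop=True), df], axis=1)
    return df


def classify_patch(y: np.ndarray, D: CombinedDictionary, L: int) -> pd.Series:
    """Single-patch version of :func:`classify_patches`."""
    return classify_patches(np.asarray(y, dtype=float).reshape(-1, 1), D, L).iloc[0]


def aggregate_theta(
    predictions: pd.DataFrame, by: str = "image_id", reference_class: int = 1
) -> pd.DataFrame:
    """Per-entity theta: fraction of patches labeled with the reference class.

    ``by`` is ``"image_id"`` or ``"subject_id"``; at subject level all
    patches from all the subject's images are pooled.
    """
    if by not in predictions.columns:
        raise ValueError(f"predictions lack an entity column {by!r}")
    rows = []
    for entity, sub in predictions.groupby(by, sort=True):
        n = len(sub)
        theta = float((sub["label"] == reference_class).sum() / n)
        row = {"entity": entity, "theta": theta, "n_patches": n}
        if "class" in sub.columns:
            row["class"] = int(sub["class"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


def auc(scores: np.ndarray, labels: np.ndarray, reference_class: int = 1) -> float:
    """Rank-based (Mann-Whitney) AUC of theta as the class-1 score; ties 0.5."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels == reference_class, scores))


def sens_spec(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    reference_class: int = 1,
) -> tuple[float, float]:
    """Sensitivity/specificity labeling class 1 iff theta >= threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("sensitivity/specificity require both classes present")
    pos = labels == reference_class
    pred_pos = scores >= threshold
    sensitivity = float(np.mean(pred_pos[pos]))
    specificity = float(np.mean(~pred_pos[~pos]))
    return sensitivity, specificity


def youden_threshold(
    scores: np.ndarray, labels: np.ndarray, reference_class: int = 1
) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(scores):
        se, sp = sens_spec(scores, labels, t, reference_class)
        j = se + sp - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


@dataclass
class CVResult:
    """Per-fold metrics of a grouped cross-validation run."""

    folds: pd.DataFrame  # fold, auc, sensitivity, specificity, youden_*
    predictions: pd.DataFrame  # entity, fold, class, theta, label
    mode: str
    k: int
    threshold: float
    seed: int

    def summary(self) -> dict:
        out = {"mode": self.mode, "k": self.k, "threshold": self.threshold}
        for col in ("auc", "sensitivity", "specificity"):
            vals = self.folds[col].to_numpy(float)
            out[col] = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        return out


def _image_patches(
    composites: list[CompositeImage], patch_spec: PatchSpec
) -> dict[str, list]:
    """Extract + filter once per image; keyed by image id."""
    out = {}
    for img in composites:
        kept = filter_low_intensity(extract_patches(img, patch_spec), patch_spec)
        out[img.image_id] = kept
        if not kept:
            logger.warning("image %s has zero surviving patches", img.image_id)
    return out


def cross_validate(
    composites: list[CompositeImage],
    patch_spec: PatchSpec,
    cfg: DFDLConfig,
    mode: str = "subject",
    k: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV at image or subject level.

    In subject mode the fold units are subjects and every image of a
    subject stays on the subject's side of the split; in image mode each
    image is an independent unit.  Per fold the dictionaries are trained
    from the training entities' surviving patches only and the held-out
    entities are scored by theta voting.
    """
    if mode not in ("image", "subject"):
        raise ValueError("mode must be 'image' or 'subject'")
    if k < 2:
        raise ValueError("k must be >= 2")
    entity_key = "image_id" if mode == "image" else "subject_id"
    entity_of_image = {img.image_id: getattr(img, entity_key) for img in composites}
    entity_class: dict[str, int] = {}
    for img in composites:
        ent = entity_of_image[img.image_id]
        entity_class.setdefault(ent, img.class_label)
        if entity_class[ent] != img.class_label:
            raise ValueError(f"entity {ent!r} has inconsistent class labels")
    entities = sorted(entity_class)
    ent_labels = np.array([entity_class[e] for e in entities])
    if np.unique(ent_labels).size < 2:
        raise ValueError("cross-validation requires both classes present")
    min_class = min(np.bincount(ent_labels)[1:].min(), len(entities))
    if min_class < k:
        raise ValueError(
            f"smallest class has {min_class} entities, not enough for {k} folds "
            "with both classes; use a smaller k"
        )
    pool = _image_patches(composites, patch_spec)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_rows, pred_rows = [], []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(entities, ent_labels)):
        train_entities = {entities[i] for i in tr_idx}
        test_entities = {entities[i] for i in te_idx}
        if np.unique(ent_labels[tr_idx]).size < 2 or np.unique(ent_labels[te_idx]).size < 2:
            raise ValueError(
                f"fold {fold} contains a single class; use a smaller k"
            )
        by_class: dict[int, list] = {1: [], 2: []}
        for img in composites:
            if entity_of_image[img.image_id] in train_entities:
                by_class[img.class_label].extend(pool[img.image_id])
        for cls, pts in by_class.items():
            if not pts:
                raise ValueError(f"fold {fold}: class {cls} has zero surviving patches")
        _, _, D = train_pair(
            PatchMatrix.from_patches(by_class[1]),
            PatchMatrix.from_patches(by_class[2]),
            cfg,
        )
        test_patches = [
            p
            for img in composites
            if entity_of_image[img.image_id] in test_entities
            for p in pool[img.image_id]
        ]
        preds = classify_patches(PatchMatrix.from_patches(test_patches), D, cfg.L)
        scored = aggregate_theta(preds, by=entity_key)
        unscored = test_entities - set(scored["entity"])
        if unscored:
            logger.warning("fold %d: unscorable entities excluded: %s", fold, sorted(unscored))
        scored["fold"] = fold
        pred_rows.append(scored)
        theta = scored["theta"].to_numpy(float)
        lab = scored["class"].to_numpy(int)
        se, sp = sens_spec(theta, lab, threshold)
        yt = youden_threshold(theta, lab)
        yse, ysp = sens_spec(theta, lab, yt)
        fold_rows.append(
            {
                "fold": fold,
                "auc": auc(theta, lab),
                "sensitivity": se,
                "specificity": sp,
                "youden_threshold": yt,
                "youden_sensitivity": yse,
                "youden_specificity": ysp,
                "n_train_entities": len(train_entities),
                "n_test_entities": len(test_entities),
            }
        )
    return CVResult(
        folds=pd.DataFrame(fold_rows),
        predictions=pd.concat(pred_rows, ignore_index=True),
        mode=mode,
        k=k,
        threshold=threshold,
        seed=seed,
    )
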