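"""Patch extraction, low-intensity filtering and vectorization.

Overlapping ``n x n x c`` blocks are taken from each composite on a
stride lattice (no border padding), near-empty blocks are dropped, and
survivors are vectorized into the ``d x N`` column matrix consumed by
the dictionary learner (``d = n^2 * c``).

Vectorization order is fixed: channel slowest, then rows, then columns
(``block.transpose(2, 0, 1).ravel()``).  Any fixed order works for
classification; this one keeps each channel's pixels contiguous, which
is convenient when reshaping atoms back into blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surfaces import CompositeImage


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry and the low-intensity drop rule.

    A patch is dropped iff strictly more than ``low_frac`` of its values
    are below ``low_tol``.
    """

    n: int = 20
    stride: int = 10
    low_frac: float = 0.70
    low_tol: float = 1e-15

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("patch side n must be >= 1")
        if not (1 <= self.stride <= self.n):
            raise ValueError("stride must be in [1, n]")
        if not (0.0 < self.low_frac < 1.0):
            raise ValueError("low_frac must be in (0, 1)")
        if self.low_tol <= 0:
            raise ValueError("low_tol must be positive")


@dataclass
class Patch:
    """One n x n x c block with its provenance."""

    block: np.ndarray
    origin: tuple[int, int]  # (row, col) of the top-left cell
    image_id: str
    subject_id: str
    class_label: int

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=float)
        if self.block.ndim != 3:
            raise ValueError("patch block must be 3-dimensional")
        if not np.isfinite(self.block).all():
            raise ValueError("patch block contains non-finite values")


def extract_patches(img: CompositeImage, spec: PatchSpec) -> list[Patch]:
    """All fully-contained patches with origins on the stride lattice.

    Raster order: row-major over origins.  The number of patches is
    ``(floor((l - n) / stride) + 1) * (floor((m - n) / stride) + 1)``.
    """
    l, m, _ = img.shape
    if spec.n > l or spec.n > m:
        raise ValueError(f"patch side {spec.n} exceeds image dimensions {l}x{m}")
    out = []
    for r in range(0, l - spec.n + 1, spec.stride):
        for c in range(0, m - spec.n + 1, spec.stride):
            out.append(
                Patch(
                    block=img.stack[r : r + spec.n, c : c + spec.n, :].copy(),
                    origin=(r, c),
                    image_id=img.image_id,
                    subject_id=img.subject_id,
                    class_label=img.class_label,
                )
            )
    return out


def is_low_intensity(block: np.ndarray, spec: PatchSpec) -> bool:
    frac_below = np.count_nonzero(block < spec.low_tol) / block.size
    return frac_below > spec.low_frac


def filter_low_intensity(patches: list[Patch], spec: PatchSpec) -> list[Patch]:
    """Drop patches with strictly more than ``low_frac`` of values < ``low_tol``."""
    return [p for p in patches if not is_low_intensity(p.block, spec)]


def vectorize(patch: Patch | np.ndarray) -> np.ndarray:
    """Vectorize an n x n x c block to length n^2*c (channel slowest)."""
    block = patch.block if isinstance(patch, Patch) else np.asarray(patch, dtype=float)
    return block.transpose(2, 0, 1).ravel().copy()


def unvectorize(vec: np.ndarray, n: int, c: int) -> np.ndarray:
    """Exact inverse of :func:`vectorize`."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != n * n * c:
        raise ValueError(f"vector length {vec.size} != n^2*c = {n * n * c}")
    return vec.reshape(c, n, n).transpose(1, 2, 0).copy()


@dataclass
class PatchMatrix:
    """Column-stacked vectorized patches with aligned per-column metadata."""

    columns: np.ndarray  # d x N
    meta: pd.DataFrame  # N rows: image_id, subject_id, class, origin_row, origin_col

    def __post_init__(self) -> None:
        if self.columns.ndim != 2:
            raise ValueError("columns must be a d x N matrix")
        if len(self.meta) != self.columns.shape[1]:
            raise ValueError("metadata length does not match column count")

    @classmethod
    def from_patches(cls, patches: list[Patch]) -> "PatchMatrix":
        if not patches:
            raise ValueError("cannot build a PatchMatrix from zero patches")
        cols = np.stack([vectorize(p) for p in patches], axis=1)
        meta = pd.DataFrame(
            {
                "image_id": [p.image_id for p in patches],
                "subject_id": [p.subject_id for p in patches],
                "class": [p.class_label for p in patches],
                "origin_row": [p.origin[0] for p in patches],
                "origin_col": [p.origin[1] for p in patches],
            }
        )
        return cls(cols, meta)

    @property
    def d(self) -> int:
        return self.columns.shape[0]

    @property
    def n_patches(self) -> int:
        return self.columns.shape[1]

    def subset(self, mask: np.ndarray) -> "PatchMatrix":
        mask = np.asarray(mask)
        return PatchMatrix(self.columns[:, mask], self.meta[mask].reset_index(drop=True))

    def class_split(self) -> dict[int, "PatchMatrix"]:
        return {
            cls: self.subset((self.meta["class"] == cls).to_numpy())
            for cls in sorted(self.meta["class"].unique())
        }


def assemble_training(
    patches_by_class: dict[int, list[Patch]],
    proportional_sampling: bool = False,
    class_sizes: dict[int, int] | None = None,
    budget: int | None = None,
    seed: int = 0,
) -> tuple[PatchMatrix, PatchMatrix]:
    """Build the two training matrices (Y, Ybar) from per-class patch pools.

    With ``proportional_sampling`` the per-class patch counts are made
    proportional to ``class_sizes`` (e.g. subject counts) within a total
    ``budget``; otherwise every surviving patch is used.
    """
    classes = sorted(patches_by_class)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    for cls in classes:
        if not patches_by_class[cls]:
            raise ValueError(f"class {cls} has zero surviving patches")
    rng = np.random.default_rng(seed)
    matrices = {}
    for cls in classes:
        pool = patches_by_class[cls]
        if proportional_sampling:
            if class_sizes is None or budget is None:
                raise ValueError("proportional_sampling requires class_sizes and budget")
            total = sum(class_sizes[c] for c in classes)
            target = int(round(budget * class_sizes[cls] / total))
            target = min(target, len(pool))
            idx = rng.choice(len(pool), size=target, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        matrices[cls] = PatchMatrix.from_patches(pool)
    return matrices[classes[0]], matrices[classes[1]]
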