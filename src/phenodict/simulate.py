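"""Synthetic two-class cohorts of multi-phenotype spatial point patterns.

Real multiplexed-immunofluorescence (mIF) cohorts give, per image, the
(x, y) position and phenotype label of every segmented cell.  This module
emulates that input: each image is a rectangular observation window in
which every phenotype is a homogeneous Poisson point process, and
cross-phenotype spatial coupling is planted by relocating a configurable
fraction of one phenotype's points into Gaussian clusters around the
points of another phenotype (a Thomas-process-style parent/offspring
construction).  The two classes of subjects may differ in per-phenotype
intensity and/or in which phenotype pairs are coupled, which is exactly
the structure the downstream classifier is meant to detect.

All randomness flows from ``CohortSpec.seed``; identical specs produce
identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_PHENOTYPES: tuple[str, ...] = ("Epithelial", "CTL", "HelperT", "Treg", "APC")

CLASS_LABELS = (1, 2)


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, origin at (0, 0), sizes in microns."""

    width_um: float
    height_um: float

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= 0) & (x <= self.width_um) & (y >= 0) & (y <= self.height_um)


@dataclass
class CellTable:
    """Point pattern of phenotyped cells for one image.

    ``cells`` has columns ``phenotype, x_um, y_um``; every position lies
    inside ``window`` and every phenotype is one of ``phenotypes``.
    """

    cells: pd.DataFrame
    image_id: str
    subject_id: str
    class_label: int
    window: Window
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES

    def __post_init__(self) -> None:
        required = {"phenotype", "x_um", "y_um"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be in {CLASS_LABELS}, got {self.class_label}")
        bad = set(self.cells["phenotype"]) - set(self.phenotypes)
        if bad:
            raise ValueError(f"undeclared phenotypes in cell table: {sorted(bad)}")
        x = self.cells["x_um"].to_numpy(float)
        y = self.cells["y_um"].to_numpy(float)
        if len(x) and not self.window.contains(x, y).all():
            raise ValueError("cell positions fall outside the observation window")

    def positions(self, phenotype: str) -> np.ndarray:
        """(k, 2) array of x/y positions of one phenotype."""
        if phenotype not in self.phenotypes:
            raise ValueError(f"phenotype {phenotype!r} not declared for this table")
        sub = self.cells[self.cells["phenotype"] == phenotype]
        return sub[["x_um", "y_um"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class CohortSpec:
    """Generative specification of a two-class cohort.

    Parameters
    ----------
    n_subjects_per_class
        Single count applied to both classes, or an explicit ``(n1, n2)``.
    images_per_subject
        Fixed count, or an inclusive ``(lo, hi)`` range sampled per subject.
    base_intensity
        ``{class_label: {phenotype: points per um^2}}``.  Phenotypes absent
        from a class's mapping default to 0.
    coupling
        ``{class_label: {(parent, offspring): fraction}}``; the fraction of
        offspring-phenotype points relocated into Gaussian clusters (sd
        ``offspring_dispersion_um``) around uniformly chosen parent points.
    subject_sigma_log
        Sd of an optional per-subject log-normal intensity multiplier
        (0 disables subject heterogeneity).
    """

    n_subjects_per_class: int | tuple[int, int] = 20
    images_per_subject: int | tuple[int, int] = 1
    window: Window = field(default_factory=lambda: Window(1000.0, 1400.0))
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    base_intensity: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    coupling: Mapping[int, Mapping[tuple[str, str], float]] = field(default_factory=dict)
    offspring_dispersion_um: float = 20.0
    subject_sigma_log: float = 0.0
    seed: int = 0

    def n_subjects(self, class_label: int) -> int:
        n = self.n_subjects_per_class
        if isinstance(n, tuple):
            return n[class_label - 1]
        return n

    def validate(self) -> None:
        if not self.phenotypes:
            raise ValueError("phenotypes: list must be non-empty")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ValueError("phenotypes: duplicate labels")
        if self.window.width_um <= 0 or self.window.height_um <= 0:
            raise ValueError("window: dimensions must be positive")
        for cls in CLASS_LABELS:
            if self.n_subjects(cls) < 1:
                raise ValueError("n_subjects_per_class: must be >= 1")
        ips = self.images_per_subject
        if isinstance(ips, tuple):
            if not (1 <= ips[0] <= ips[1]):
                raise ValueError("images_per_subject: invalid range")
        elif ips < 1:
            raise ValueError("images_per_subject: must be >= 1")
        for cls, mapping in self.base_intensity.items():
            for phen, lam in mapping.items():
                if phen not in self.phenotypes:
                    raise ValueError(f"base_intensity: undeclared phenotype {phen!r}")
                if lam < 0:
                    raise ValueError(f"base_intensity: negative intensity for {phen!r}")
        for cls, mapping in self.coupling.items():
            for (a, b), frac in mapping.items():
                if a not in self.phenotypes or b not in self.phenotypes:
                    raise ValueError(f"coupling: undeclared phenotype in pair {(a, b)!r}")
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(f"coupling: fraction for {(a, b)!r} outside [0, 1]")
        if self.offspring_dispersion_um <= 0:
            raise ValueError("offspring_dispersion_um: must be positive")
        if self.subject_sigma_log < 0:
            raise ValueError("subject_sigma_log: must be >= 0")

    def intensity(self, class_label: int, phenotype: str) -> float:
        return float(self.base_intensity.get(class_label, {}).get(phenotype, 0.0))


def default_cohort_spec(
    n_subjects_per_class: int | tuple[int, int] = 20,
    images_per_subject: int | tuple[int, int] = 1,
    base_intensity_um2: float = 5e-4,
    coupling_class1: Mapping[tuple[str, str], float] | None = None,
    coupling_class2: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
    **kwargs,
) -> CohortSpec:
    """Cohort with equal baseline intensity for all phenotypes in both classes.

    The default intensity of 5e-4 points/um^2 (500 cells/mm^2 per phenotype)
    is a realistic tissue cell density for mIF panels; by default class 1
    carries an Epithelial->CTL coupling of 0.8 and class 2 none, so the
    classes differ only in cross-phenotype spatial structure.
    """
    if coupling_class1 is None:
        coupling_class1 = {("Epithelial", "CTL"): 0.8}
    if coupling_class2 is None:
        coupling_class2 = {}
    phenotypes = kwargs.pop("phenotypes", DEFAULT_PHENOTYPES)
    intensity = {cls: {p: base_intensity_um2 for p in phenotypes} for cls in CLASS_LABELS}
    return CohortSpec(
        n_subjects_per_class=n_subjects_per_class,
        images_per_subject=images_per_subject,
        phenotypes=phenotypes,
        base_intensity=intensity,
        coupling={1: dict(coupling_class1), 2: dict(coupling_class2)},
        seed=seed,
        **kwargs,
    )


def _simulate_image(
    spec: CohortSpec,
    class_label: int,
    subject_mult: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    win = spec.window
    frames: dict[str, np.ndarray] = {}
    for phen in spec.phenotypes:
        lam = spec.intensity(class_label, phen) * subject_mult
        n = rng.poisson(lam * win.area_um2)
        xy = rng.uniform([0.0, 0.0], [win.width_um, win.height_um], size=(n, 2))
        frames[phen] = xy
    # Relocate a fraction of offspring points around uniformly chosen parents.
    for (parent, offspring), frac in spec.coupling.get(class_label, {}).items():
        par = frames[parent]
        off = frames[offspring]
        if len(par) == 0 or len(off) == 0 or frac == 0.0:
            continue
        move = rng.random(len(off)) < frac
        idx = np.flatnonzero(move)
        if idx.size == 0:
            continue
        parents = par[rng.integers(0, len(par), size=idx.size)]
        pos = parents + rng.normal(0.0, spec.offspring_dispersion_um, size=(idx.size, 2))
        # Resample out-of-window offsets so planted counts stay exact.
        bad = ~win.contains(pos[:, 0], pos[:, 1])
        while bad.any():
            pos[bad] = parents[bad] + rng.normal(
                0.0, spec.offspring_dispersion_um, size=(int(bad.sum()), 2)
            )
            bad = ~win.contains(pos[:, 0], pos[:, 1])
        off[idx] = pos
        frames[offspring] = off
    parts = [
        pd.DataFrame({"phenotype": phen, "x_um": xy[:, 0], "y_um": xy[:, 1]})
        for phen, xy in frames.items()
    ]
    return pd.concat(parts, ignore_index=True)


def simulate_cohort(spec: CohortSpec) -> list[CellTable]:
    """Simulate the full cohort described by ``spec``, deterministically."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tables: list[CellTable] = []
    for cls in CLASS_LABELS:
        for s in range(spec.n_subjects(cls)):
            subject_id = f"c{cls}s{s:03d}"
            if spec.subject_sigma_log > 0:
                mult = float(np.exp(rng.normal(0.0, spec.subject_sigma_log)))
            else:
                mult = 1.0
            ips = spec.images_per_subject
            n_img = int(rng.integers(ips[0], ips[1] + 1)) if isinstance(ips, tuple) else ips
            for i in range(n_img):
                cells = _simulate_image(spec, cls, mult, rng)
                tables.append(
                    CellTable(
                        cells=cells,
                        image_id=f"{subject_id}i{i:02d}",
                        subject_id=subject_id,
                        class_label=cls,
                        window=spec.window,
                        phenotypes=spec.phenotypes,
                    )
                )
    return tables


def empirical_cross_coupling(
    table: CellTable, pair: tuple[str, str], radius_um: float
) -> float:
    """Normalized parent-to-offspring neighbor count (a cross-K-style statistic).

    Mean number of ``b`` points within ``radius_um`` of each ``a`` point,
    divided by the expectation ``lambda_b * pi * r^2`` under independence.
    Approximately 1 for independent patterns, > 1 under planted coupling.
    Returns NaN if either phenotype has no points.
    """
    a, b = pair
    pa = table.positions(a)
    pb = table.positions(b)
    if len(pa) == 0 or len(pb) == 0:
        return float("nan")
    tree = cKDTree(pb)
    counts = tree.query_ball_point(pa, r=radius_um, return_length=True)
    lam_b = len(pb) / table.window.area_um2
    expected = lam_b * np.pi * radius_um**2
    return float(np.mean(counts) / expected)


# ---------------------------------------------------------------------------
# Cohort I/O: a flat CSV of cells plus a JSON manifest.

def write_cohort(tables: Sequence[CellTable], csv_path: str | Path, spec: CohortSpec | None = None) -> None:
    csv_path = Path(csv_path)
    rows = []
    for t in tables:
        df = t.cells.copy()
        df.insert(0, "image_id", t.image_id)
        df.insert(1, "subject_id", t.subject_id)
        df.insert(2, "class", t.class_label)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False)
    first = tables[0]
    manifest = {
        "window": {"width_um": first.window.width_um, "height_um": first.window.height_um},
        "phenotypes": list(first.phenotypes),
        "n_images": len(tables),
        "seed": spec.seed if spec is not None else None,
    }
    if spec is not None:
        manifest["spec"] = {
            "n_subjects_per_class": spec.n_subjects_per_class
            if not isinstance(spec.n_subjects_per_class, tuple)
            else list(spec.n_subjects_per_class),
            "images_per_subject": spec.images_per_subject
            if not isinstance(spec.images_per_subject, tuple)
            else list(spec.images_per_subject),
            "offspring_dispersion_um": spec.offspring_dispersion_um,
            "subject_sigma_log": spec.subject_sigma_log,
            "base_intensity": {str(k): dict(v) for k, v in spec.base_intensity.items()},
            "coupling": {
                str(k): {f"{a}->{b}": f for (a, b), f in v.items()}
                for k, v in spec.coupling.items()
            },
        }
    csv_path.with_suffix(".json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_cohort(csv_path: str | Path) -> list[CellTable]:
    csv_path = Path(csv_path)
    manifest = json.loads(csv_path.with_suffix(".json").read_text())
    window = Window(manifest["window"]["width_um"], manifest["window"]["height_um"])
    phenotypes = tuple(manifest["phenotypes"])
    df = pd.read_csv(csv_path)
    tables = []
    for image_id, sub in df.groupby("image_id", sort=False):
        tables.append(
            CellTable(
                cells=sub[["phenotype", "x_um", "y_um"]].reset_index(drop=True),
                image_id=str(image_id),
                subject_id=str(sub["subject_id"].iloc[0]),
                class_label=int(sub["class"].iloc[0]),
                window=window,
                phenotypes=phenotypes,
            )
        )
    return tables
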