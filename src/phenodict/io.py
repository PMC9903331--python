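"""HDF5/CSV/PNG persistence for pipeline artifacts.

HDF5 datasets are written with ``track_times=False`` so that re-running
a pipeline with the same configuration produces byte-identical files
(the run manifest hashes outputs to verify reproducibility).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dfdl import ClassDictionary, CombinedDictionary, DFDLConfig
from .patches import PatchMatrix
from .surfaces import CompositeImage, GridSpec

_H5 = dict(track_times=False)


def save_composites(path: str | Path, composites: list[CompositeImage]) -> None:
    with h5py.File(path, "w") as f:
        for img in composites:
            ds = f.create_dataset(img.image_id, data=img.stack, **_H5)
            ds.attrs["channel_order"] = list(img.channel_order)
            ds.attrs["subject_id"] = img.subject_id
            ds.attrs["class"] = img.class_label
            ds.attrs["n_rows"] = img.grid.n_rows
            ds.attrs["n_cols"] = img.grid.n_cols
            ds.attrs["cell_size_um"] = img.grid.cell_size_um


def load_composites(path: str | Path) -> list[CompositeImage]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            ds = f[name]
            grid = GridSpec(
                n_rows=int(ds.attrs["n_rows"]),
                n_cols=int(ds.attrs["n_cols"]),
                cell_size_um=float(ds.attrs["cell_size_um"]),
            )
            out.append(
                CompositeImage(
                    stack=ds[()],
                    channel_order=tuple(str(x) for x in ds.attrs["channel_order"]),
                    grid=grid,
                    image_id=name,
                    subject_id=str(ds.attrs["subject_id"]),
                    class_label=int(ds.attrs["class"]),
                )
            )
    return out


def export_composite_tiff(path: str | Path, img: CompositeImage) -> None:
    """Optional multi-channel TIFF export for visual inspection."""
    import tifffile

    tifffile.imwrite(path, img.stack.transpose(2, 0, 1).astype(np.float32))


def save_patch_matrix(path: str | Path, pm: PatchMatrix, patch_n: int, c: int) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("columns", data=pm.columns, **_H5)
        f.attrs["patch_n"] = patch_n
        f.attrs["n_channels"] = c
        meta = f.create_group("meta")
        for col in pm.meta.columns:
            vals = pm.meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            meta.create_dataset(col, data=vals, **_H5)


def load_patch_matrix(path: str | Path) -> tuple[PatchMatrix, int, int]:
    with h5py.File(path, "r") as f:
        cols = f["columns"][()]
        meta = {}
        for key in f["meta"]:
            vals = f["meta"][key][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            meta[key] = vals
        order = ["image_id", "subject_id", "class", "origin_row", "origin_col"]
        df = pd.DataFrame({k: meta[k] for k in order if k in meta})
        df["class"] = df["class"].astype(int)
        return PatchMatrix(cols, df), int(f.attrs["patch_n"]), int(f.attrs["n_channels"])


def save_dictionary(path: str | Path, d1: ClassDictionary, d2: ClassDictionary) -> None:
    with h5py.File(path, "w") as f:
        for d in (d1, d2):
            ds = f.create_dataset(f"class{d.class_label}", data=d.atoms, **_H5)
            if d.config is not None:
                ds.attrs["config"] = json.dumps(d.config.__dict__, sort_keys=True)
            ds.attrs["objective_history"] = d.objective_history


def load_dictionary(path: str | Path) -> tuple[ClassDictionary, ClassDictionary, CombinedDictionary]:
    dicts = {}
    with h5py.File(path, "r") as f:
        for cls in (1, 2):
            ds = f[f"class{cls}"]
            cfg = None
            if "config" in ds.attrs:
                cfg = DFDLConfig(**json.loads(ds.attrs["config"]))
            dicts[cls] = ClassDictionary(
                ds[()], cls, cfg, list(ds.attrs.get("objective_history", []))
            )
    d1, d2 = dicts[1], dicts[2]
    return d1, d2, CombinedDictionary.from_pair(d1, d2)


def export_atom_mosaic(
    path: str | Path,
    D: CombinedDictionary,
    n: int,
    channel_names: tuple[str, ...],
    atoms: list[int] | None = None,
    max_channels: int = 3,
) -> None:
    """PNG mosaic of atoms rendered as pseudocolor blocks (first channels as RGB)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .patches import unvectorize

    c = len(channel_names)
    if atoms is None:
        atoms = list(range(D.n_atoms))
    ncol = int(np.ceil(np.sqrt(len(atoms))))
    nrow = int(np.ceil(len(atoms) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(1.2 * ncol, 1.2 * nrow))
    axes = np.atleast_1d(axes).ravel()
    for ax in axes:
        ax.axis("off")
    for ax, j in zip(axes, atoms):
        block = unvectorize(D.atoms[:, j], n, c)
        rgb = block[:, :, : min(max_channels, 3)]
        lo, hi = rgb.min(), rgb.max()
        rgb = (rgb - lo) / (hi - lo) if hi > lo else np.zeros_like(rgb)
        if rgb.shape[2] < 3:
            rgb = np.concatenate(
                [rgb, np.zeros((n, n, 3 - rgb.shape[2]))], axis=2
            )
        ax.imshow(rgb, origin="lower")
        ax.set_title(f"{j}", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_proportion_plot(path: str | Path, table: pd.DataFrame) -> None:
    """Grouped bar chart of per-pair correlated-atom proportions by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{a}-{b}" for a, b in zip(table["phenotype_a"], table["phenotype_b"])]
    x = np.arange(len(labels))
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(labels)), 4))
    ax.bar(x - 0.2, table["proportion_class1"], width=0.4, label="class 1")
    ax.bar(x + 0.2, table["proportion_class2"], width=0.4, label="class 2")
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("proportion of significant atoms correlated")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
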