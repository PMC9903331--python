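"""Run configuration, stage orchestration and reproducibility manifests.

A run is a directory of artifacts produced by an ordered set of stages:

    simulate -> surfaces -> patches -> train -> evaluate -> atoms -> report

Each stage reads the previous stage's artifact from the run directory
and writes its own; stages are idempotent and a subset can be re-run as
long as the upstream artifacts exist.  One global seed determines every
stochastic output, and the manifest records a SHA-256 hash of each
artifact so reruns can be checked for bit-identical reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .atoms import (
    WeightedCorrConfig,
    compare_pair_proportions,
    compute_activity,
    pair_proportions,
    select_significant_atoms,
)
from .classify import cross_validate
from .dfdl import DFDLConfig, train_pair
from .patches import PatchMatrix, PatchSpec, extract_patches, filter_low_intensity
from .simulate import (
    CohortSpec,
    Window,
    default_cohort_spec,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from .surfaces import GridSpec, composite_from_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "surfaces", "patches", "train", "evaluate", "atoms", "report")

_ARTIFACTS = {
    "simulate": ["cells.csv", "cells.json"],
    "surfaces": ["composites.h5"],
    "patches": ["patches.h5"],
    "train": ["dictionary.h5"],
    "evaluate": ["metrics.json", "predictions.csv"],
    "atoms": ["atom_significance.csv", "pair_proportions.csv"],
    "report": ["manifest.json", "atom_mosaic.png", "pair_proportions.png"],
}

_UPSTREAM = {
    "surfaces": "simulate",
    "patches": "surfaces",
    "train": "patches",
    "evaluate": "surfaces",
    "atoms": "train",
    "report": "atoms",
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: Path
    seed: int = 0
    cells_csv: Path | None = None  # external cohort; otherwise simulate
    cohort: CohortSpec | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    bandwidth_um: float | None = None
    edge_correction: bool = True
    normalize_channels: bool = False
    patch: PatchSpec = field(default_factory=PatchSpec)
    dfdl: DFDLConfig = field(default_factory=DFDLConfig)
    corr: WeightedCorrConfig = field(default_factory=WeightedCorrConfig)
    cv_mode: str = "subject"
    cv_k: int = 5
    cv_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.cells_csv is None and self.cohort is None:
            self.cohort = default_cohort_spec(seed=self.seed)
        if self.cohort is not None:
            self.cohort.validate()

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        seed = int(raw.get("seed", 0))
        kwargs: dict = {
            "outdir": Path(raw.get("outdir", "phenodict_run")),
            "seed": seed,
        }
        if "cells_csv" in raw and raw["cells_csv"]:
            kwargs["cells_csv"] = Path(raw["cells_csv"])
        if "cohort" in raw:
            co = dict(raw["cohort"])
            for key in ("coupling_class1", "coupling_class2"):
                if key in co:
                    co[key] = {
                        tuple(k.split("->")): float(v) for k, v in co[key].items()
                    }
            if "window" in co:
                co["window"] = Window(**co.pop("window"))
            if "images_per_subject" in co and isinstance(co["images_per_subject"], list):
                co["images_per_subject"] = tuple(co["images_per_subject"])
            kwargs["cohort"] = default_cohort_spec(seed=seed, **co)
        if "grid" in raw:
            kwargs["grid"] = GridSpec(**raw["grid"])
        for key in ("bandwidth_um", "edge_correction", "normalize_channels"):
            if key in raw:
                kwargs[key] = raw[key]
        if "patch" in raw:
            kwargs["patch"] = PatchSpec(**raw["patch"])
        if "dfdl" in raw:
            kwargs["dfdl"] = DFDLConfig(seed=seed, **raw["dfdl"])
        else:
            kwargs["dfdl"] = DFDLConfig(seed=seed)
        if "corr" in raw:
            kwargs["corr"] = WeightedCorrConfig(seed=seed, **raw["corr"])
        else:
            kwargs["corr"] = WeightedCorrConfig(seed=seed)
        cv = raw.get("cv", {})
        kwargs["cv_mode"] = cv.get("mode", "subject")
        kwargs["cv_k"] = int(cv.get("k", 5))
        kwargs["cv_threshold"] = float(cv.get("threshold", 0.5))
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(config: RunConfig, stage: str) -> None:
    upstream = _UPSTREAM.get(stage)
    if upstream is None:
        return
    for name in _ARTIFACTS[upstream]:
        if not (config.outdir / name).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs artifact '{name}'; run stage '{upstream}' first"
            )


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order and return the run manifest."""
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)

    for stage in stages:
        t0 = time.time()
        _require(config, stage)
        if stage == "simulate":
            if config.cells_csv is not None:
                tables = read_cohort(config.cells_csv)
                write_cohort(tables, out / "cells.csv")
            else:
                tables = simulate_cohort(config.cohort)
                write_cohort(tables, out / "cells.csv", config.cohort)
            logger.info("simulate: %d images", len(tables))
        elif stage == "surfaces":
            tables = read_cohort(out / "cells.csv")
            composites = [
                composite_from_table(
                    t,
                    config.grid,
                    config.bandwidth_um,
                    config.edge_correction,
                    config.normalize_channels,
                )
                for t in tables
            ]
            pio.save_composites(out / "composites.h5", composites)
            logger.info("surfaces: %d composites of shape %s", len(composites), composites[0].shape)
        elif stage == "patches":
            composites = pio.load_composites(out / "composites.h5")
            kept, dropped = [], 0
            for img in composites:
                raw = extract_patches(img, config.patch)
                k = filter_low_intensity(raw, config.patch)
                dropped += len(raw) - len(k)
                kept.extend(k)
            pm = PatchMatrix.from_patches(kept)
            pio.save_patch_matrix(
                out / "patches.h5", pm, config.patch.n, len(composites[0].channel_order)
            )
            logger.info("patches: kept %d, dropped %d low-intensity", pm.n_patches, dropped)
        elif stage == "train":
            pm, _, _ = pio.load_patch_matrix(out / "patches.h5")
            split = pm.class_split()
            d1, d2, _ = train_pair(split[1], split[2], config.dfdl)
            pio.save_dictionary(out / "dictionary.h5", d1, d2)
            logger.info("train: %d atoms per class", config.dfdl.k_atoms_per_class)
        elif stage == "evaluate":
            composites = pio.load_composites(out / "composites.h5")
            result = cross_validate(
                composites,
                config.patch,
                config.dfdl,
                mode=config.cv_mode,
                k=config.cv_k,
                threshold=config.cv_threshold,
                seed=config.seed,
            )
            metrics = result.summary()
            metrics["folds"] = result.folds.to_dict(orient="records")
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
            result.predictions.to_csv(out / "predictions.csv", index=False)
            logger.info("evaluate: mean %s-level AUC %.4f", config.cv_mode, metrics["auc"]["mean"])
        elif stage == "atoms":
            pm, patch_n, c = pio.load_patch_matrix(out / "patches.h5")
            _, _, D = pio.load_dictionary(out / "dictionary.h5")
            activity = compute_activity(pm, D, config.dfdl.L)
            sig = select_significant_atoms(activity, config.corr.alpha)
            sig.to_csv(out / "atom_significance.csv", index=False)
            composites = pio.load_composites(out / "composites.h5")
            channels = composites[0].channel_order
            table = pair_proportions(D, sig, patch_n, channels, config.corr)
            table = compare_pair_proportions(table)
            table.to_csv(out / "pair_proportions.csv", index=False)
            logger.info(
                "atoms: selected %d (class 1) / %d (class 2)",
                int(sig[(sig["class"] == 1) & sig["selected"]].shape[0]),
                int(sig[(sig["class"] == 2) & sig["selected"]].shape[0]),
            )
        elif stage == "report":
            pm, patch_n, c = pio.load_patch_matrix(out / "patches.h5")
            _, _, D = pio.load_dictionary(out / "dictionary.h5")
            composites = pio.load_composites(out / "composites.h5")
            sig = pd.read_csv(out / "atom_significance.csv")
            table = pd.read_csv(out / "pair_proportions.csv")
            selected = [int(a) for a in sig[sig["selected"]]["atom"]]
            pio.export_atom_mosaic(
                out / "atom_mosaic.png", D, patch_n, composites[0].channel_order,
                atoms=selected or None,
            )
            pio.export_proportion_plot(out / "pair_proportions.png", table)
            manifest = build_manifest(config)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    return build_manifest(config)


def build_manifest(config: RunConfig) -> dict:
    """Config echo plus SHA-256 hashes of every existing artifact."""
    from . import __version__

    hashes = {}
    for stage, names in _ARTIFACTS.items():
        for name in names:
            p = config.outdir / name
            if p.exists() and name != "manifest.json":
                hashes[name] = _sha256(p)
    echo = {
        "seed": config.seed,
        "grid": asdict(config.grid),
        "patch": asdict(config.patch),
        "dfdl": asdict(config.dfdl),
        "corr": asdict(config.corr),
        "cv": {"mode": config.cv_mode, "k": config.cv_k, "threshold": config.cv_threshold},
        "edge_correction": config.edge_correction,
        "normalize_channels": config.normalize_channels,
        "bandwidth_um": config.bandwidth_um,
    }
    return {
        "version": __version__,
        "config": echo,
        "artifact_hashes": hashes,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
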