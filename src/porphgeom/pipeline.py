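"""Orchestration: curate -> annotate -> descriptors -> train.

A single declarative :class:`PipelineConfig` drives the four stages; every
stage writes its artifact (CSV/JSON) into the output directory and the run
finishes with a manifest recording the configuration, seeds, library
versions and a hash, so a run is self-describing and reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aromaticity import HOMAParams
from .descriptors import FEATURE_NAMES, TARGET_NAMES, build_feature_vector
from .io_curation import (
    FILTER_NAMES,
    MolecularStructure,
    apply_filters,
    parse_structure,
    perceive_bonds,
    write_xyz,
)
from .macrocycle import find_porphyrin_macrocycle
from .ml_analysis import bootstrap_evaluate, coefficient_table
from .nonplanarity import build_nsd_basis
from .synthetic_data import (
    SyntheticSpec,
    _annotate,
    default_calibration,
    generate_population,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    input_dir: str | None = None          # directory of .xyz/.cif files
    input_format: str = "xyz"
    out_dir: str = "porphgeom_out"
    synthetic_n: int | None = None        # generate a population instead
    radii_scale: float = 1.15
    calibration: str = "class_anchor"
    plane_mode: str = "N4"
    variant: str = "cone_angles"
    targets: tuple[str, ...] = ("total_oop", "abs_sad", "abs_ruf")
    seed: int = 0
    n_boot: int = 10
    test_fraction: float = 0.1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_structures(cfg: PipelineConfig) -> list[MolecularStructure]:
    root = Path(cfg.input_dir)
    if not root.is_dir():
        raise PipelineStageError("curate", f"input dir {root} does not exist")
    structures = []
    patterns = {"xyz": "*.xyz", "cif": "*.cif"}
    pat = patterns.get(cfg.input_format)
    if pat is None:
        raise PipelineStageError("curate",
                                 f"unknown input format {cfg.input_format!r}")
    for path in sorted(root.glob(pat)):
        st = parse_structure(path.read_text(), cfg.input_format,
                             source_id=path.stem, bond_scale=cfg.radii_scale)
        if st is None:
            logger.info("structure %s rejected: no dominant disorder "
                        "occupancy", path.stem)
            continue
        if not st.bonds:
            st = perceive_bonds(st, scale=cfg.radii_scale)
        structures.append(st)
    return structures


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute curation, annotation, descriptor building and training.

    Returns the manifest (also written to ``manifest.json``).  Stage
    failures abort with a stage-tagged error; artifacts of completed stages
    are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "versions": {"porphgeom": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": [],
    }

    def _finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    basis = build_nsd_basis()
    params: HOMAParams = default_calibration(cfg.calibration)

    # ---- stage 1: curate (or synthesize) ----------------------------------
    population = None
    try:
        if cfg.synthetic_n is not None:
            population = generate_population(
                SyntheticSpec(n=cfg.synthetic_n, seed=cfg.seed),
                params=params, basis=basis)
            structures = population.structures
            maps = dict(enumerate(population.maps))
            report = apply_filters(structures)
        else:
            structures = _load_structures(cfg)
            report = apply_filters(structures)
            maps = {}
            for i, st in enumerate(structures):
                m = find_porphyrin_macrocycle(st)
                if m is not None:
                    maps[i] = m
        rows = []
        for i, st in enumerate(structures):
            sid = st.source_id or f"structure_{i}"
            row = {"structure": sid, **report.per_structure[sid],
                   "overall": report.overall[sid]}
            rows.append(row)
        pd.DataFrame(rows, columns=["structure", *FILTER_NAMES, "overall"]
                     ).to_csv(out / "curation_report.csv", index=False)
        curated = [i for i, st in enumerate(structures)
                   if report.overall[st.source_id or f"structure_{i}"]
                   and i in maps]
        xyz_dir = out / "curated_xyz"
        xyz_dir.mkdir(exist_ok=True)
        for i in curated:
            sid = structures[i].source_id or f"structure_{i}"
            (xyz_dir / f"{sid}.xyz").write_text(write_xyz(structures[i], sid))
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("curate", str(exc)) from exc
    _finish_stage("curate")
    if not curated:
        raise PipelineStageError("annotate", "no structure passed curation")

    # ---- stage 2: annotate (HOMA + NSD) -----------------------------------
    try:
        ann_rows = []
        for i in curated:
            d = _annotate(structures[i], maps[i], basis, params)
            d["structure"] = structures[i].source_id or f"structure_{i}"
            ann_rows.append(d)
        ann = pd.DataFrame(ann_rows).set_index("structure")
        ann.to_csv(out / "annotations.csv")
    except Exception as exc:
        raise PipelineStageError("annotate", str(exc)) from exc
    _finish_stage("annotate")

    # ---- stage 3: features ------------------------------------------------
    try:
        cone_cache: dict = {}
        feat_rows, sub_sets = [], []
        for i in curated:
            sid = structures[i].source_id or f"structure_{i}"
            targets = {t: float(ann.loc[sid, t]) for t in TARGET_NAMES}
            vec = build_feature_vector(structures[i], maps[i], cfg.variant,
                                       targets=targets, cone_cache=cone_cache)
            row = {"structure": sid, "variant": cfg.variant, **vec.features,
                   **targets,
                   "substituent_ids": ";".join(sorted(vec.substituent_ids))}
            feat_rows.append(row)
            sub_sets.append(vec.substituent_ids)
        feats = pd.DataFrame(feat_rows)
        feats.to_csv(out / "features.csv", index=False)
    except Exception as exc:
        raise PipelineStageError("features", str(exc)) from exc
    _finish_stage("features")

    # ---- stage 4: train ---------------------------------------------------
    try:
        X = feats[list(FEATURE_NAMES[cfg.variant])]
        Y = feats[list(cfg.targets)]
        rep = bootstrap_evaluate(X, Y, sub_sets, cfg.variant,
                                 targets=cfg.targets, n_boot=cfg.n_boot,
                                 seed=cfg.seed,
                                 test_fraction=cfg.test_fraction)
        (out / "model_report.json").write_text(json.dumps({
            "variant": rep.variant, "n_boot": rep.n_boot, "ci": rep.ci,
            "bootstrap_mode": rep.bootstrap_mode,
            "split_sizes": rep.split_sizes, "mae": rep.mae,
            "lasso_coefficients": rep.lasso_coef,
            "rf_importance": rep.rf_importance,
        }, indent=2))
        coefficient_table([rep]).to_csv(out / "coefficients.csv", index=False)
    except Exception as exc:
        raise PipelineStageError("train", str(exc)) from exc
    _finish_stage("train")
    manifest["n_structures"] = len(structures)
    manifest["n_curated"] = len(curated)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
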