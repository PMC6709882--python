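"""End-to-end studies: simulated-data validation and the real-data workflow.

Every run writes a manifest (full configuration + seeds) into its output
directory so outputs are bitwise reproducible, and logs localization/blob
counts at each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import preprocess as pp
from .blobs import Blob, MaskImage
from .features import BlobFeaturizer, features_to_frame
from .models import (
    CrossValidationResult,
    cross_validate,
    make_split_cellwise,
    make_split_mixed,
    report_from_predictions,
    train_rf,
)
from .simulate import SimulationParams, generate_dataset

logger = logging.getLogger(__name__)


def _write_manifest(out_dir: Path, payload: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def validate_simulated(
    params: Optional[SimulationParams] = None,
    n_trees: int = 100,
    k_folds: int = 10,
    cv_seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> CrossValidationResult:
    """The desk-scale validation study: simulate the two-class dataset,
    extract the 28 features, and evaluate the 100-tree random forest under
    stratified 10-fold cross-validation (pooled confusion counts).
    """
    params = params or SimulationParams()
    cv_seed = params.seed if cv_seed is None else cv_seed
    blobs = generate_dataset(params)
    y = np.array([b.label for b in blobs])
    featurizer = BlobFeaturizer().fit([b.points for b in blobs])
    X = featurizer.transform([b.points for b in blobs])
    logger.info(
        "validate_simulated: %d blobs, connectivity threshold %.2f nm",
        len(blobs), featurizer.threshold_nm_,
    )
    result, oof = cross_validate(
        X, y, k=k_folds, n_trees=n_trees, seed=cv_seed, return_predictions=True
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = features_to_frame(
            X, blob_ids=[b.blob_id for b in blobs], labels=y,
        )
        frame["cv_prediction"] = oof
        frame.to_csv(out / "features_and_predictions.csv", index=False)
        (out / "report.json").write_text(json.dumps(result.to_dict(), indent=2))
        _write_manifest(out, {
            "kind": "validate_simulated",
            "params": params.to_dict(),
            "n_trees": n_trees, "k_folds": k_folds, "cv_seed": cv_seed,
            "connectivity_threshold_nm": featurizer.threshold_nm_,
        })
    return result


@dataclass
class RealRunConfig:
    """Configuration of the real-data workflow (every stage's knobs)."""

    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    n_trees: int = 100
    n_test: int = 200
    n_val: int = 100
    test_cell: Optional[str] = None
    val_cell: Optional[str] = None
    split_seed: int = 0
    seed: int = 0


@dataclass
class RealRunResult:
    blobs: list[Blob]
    features: pd.DataFrame
    reports: dict  # split mode -> test-set report dict


def run_real(
    eventlist: pd.DataFrame,
    masks: Mapping[str, Optional[MaskImage]],
    config: Optional[RealRunConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> RealRunResult:
    """The full experimental workflow on user-supplied localizations.

    merge -> noise filter -> segment -> PTRF-mask label (cells mapped to
    ``None`` are declared PTRF-free and labeled all-negative) -> >=60
    molecule stratification -> class balancing -> 28 features -> random
    forest evaluated under the mixed split and, when held-out cells are
    named, the cell-wise split.
    """
    config = config or RealRunConfig()
    cfg = config.preprocess

    merged = pp.merge_eventlist(eventlist, cfg.merge_radius_nm)
    kept_frames = []
    for cell, grp in merged.groupby("cell_id", sort=False):
        keep = pp.filter_noise(grp[["x_nm", "y_nm", "z_nm"]].to_numpy(), cfg.noise_filter)
        kept_frames.append(grp.iloc[np.flatnonzero(keep)])
    filtered = pd.concat(kept_frames, ignore_index=True)
    logger.info("run_real: %d merged -> %d filtered localizations", len(merged), len(filtered))

    blobs = pp.segment_blobs(filtered, cfg.segmentation_radius_nm)
    labeled: list[Blob] = []
    for cell in {b.cell_id for b in blobs}:
        cell_blobs = [b for b in blobs if b.cell_id == cell]
        if cell not in masks:
            raise ValueError(f"no mask entry for cell {cell!r}; map PTRF-free cells to None")
        labeled.extend(pp.label_with_mask(cell_blobs, masks[cell], cfg.mask_overlap_threshold))
    stratified = pp.stratify_classes(labeled, cfg.caveolae_min_molecules)
    balanced = pp.balance_dataset(stratified, seed=cfg.balance_seed)

    y = np.array([b.label for b in balanced])
    ids = np.array([b.blob_id for b in balanced], dtype=object)
    cells = np.array([b.cell_id for b in balanced], dtype=object)
    featurizer = BlobFeaturizer().fit([b.points for b in balanced])
    X = featurizer.transform([b.points for b in balanced])
    features = features_to_frame(X, blob_ids=ids, cell_ids=cells, labels=y)

    reports: dict = {}
    id_to_idx = {bid: i for i, bid in enumerate(ids)}

    def _evaluate(split, mode: str) -> None:
        tr = [id_to_idx[i] for i in split.train_ids]
        te = [id_to_idx[i] for i in split.test_ids]
        model = train_rf(X[tr], y[tr], n_trees=config.n_trees, seed=config.seed)
        pred = model.predict(X[te])
        report = report_from_predictions(y[te], pred)
        reports[mode] = {
            "report": report.to_dict(),
            "n_train": len(tr), "n_val": len(split.val_ids), "n_test": len(te),
            "test_predictions": {str(ids[i]): int(p) for i, p in zip(te, pred)},
        }

    n_test = min(config.n_test, max(2, len(balanced) // 5))
    n_val = min(config.n_val, max(2, len(balanced) // 10))
    _evaluate(make_split_mixed(ids, y, n_test=n_test, n_val=n_val, seed=config.split_seed),
              "mixed")
    if config.test_cell is not None and config.val_cell is not None:
        _evaluate(
            make_split_cellwise(ids, cells, config.test_cell, config.val_cell), "cell_wise"
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        (out / "reports.json").write_text(json.dumps(reports, indent=2))
        _write_manifest(out, {
            "kind": "run_real",
            "config": {
                "preprocess": asdict(cfg), "n_trees": config.n_trees,
                "n_test": n_test, "n_val": n_val, "split_seed": config.split_seed,
                "test_cell": config.test_cell, "val_cell": config.val_cell,
                "seed": config.seed,
            },
            "counts": {
                "input_localizations": int(len(eventlist)),
                "merged": int(len(merged)),
                "filtered": int(len(filtered)),
                "blobs": len(blobs),
                "balanced": len(balanced),
            },
            "connectivity_threshold_nm": featurizer.threshold_nm_,
        })
    return RealRunResult(blobs=balanced, features=features, reports=reports)
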