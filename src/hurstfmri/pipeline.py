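"""End-to-end orchestration: clean -> hurst -> features -> classify.

A run executes the stages in order on either a synthetic cohort (generated
in memory from the config) or on-disk NIfTI inputs, and lands every stage's
outputs plus a manifest (config, versions, seed, output checksums) and a
structured log in one run directory, so a run is self-describing and any
stage's products can be inspected or reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CVResult, grid_search, grid_values, holdout_validation
from .cleaning import clean_volume
from .exceptions import InvalidInputError, InvalidParameterError
from .features import FeatureMatrix, build_feature_matrix
from .hurst import hurst_map
from .io import load_atlas, load_nifti, read_confounds, read_participants, save_nifti
from .synthetic import SyntheticCohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("hurstfmri")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    # inputs: either simulate=dict of SyntheticCohortSpec fields, or paths
    simulate: dict | None = None
    bold_dir: str | None = None
    atlas_path: str | None = None
    participants_path: str | None = None
    confounds_dir: str | None = None
    out_dir: str | None = None
    # stage parameters
    tr_seconds: float = 2.0
    band: tuple[float, float] = (0.01, 0.10)
    correction: bool = False
    alpha: float = 0.05
    grid: tuple[float, float, float] = (-8.0, 8.0, 0.5)
    kernel: str = "rbf"
    stability_fraction: float = 0.95
    holdout: tuple[int, int, int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("bold_dir", "atlas_path", "participants_path"):
                p = getattr(self, name)
                if p is None:
                    raise InvalidParameterError(
                        f"config needs '{name}' unless 'simulate' is given"
                    )
                if not Path(p).exists():
                    raise InvalidInputError(f"{name} does not exist: {p}")
        low, high = self.band
        if not 0 <= low < high:
            raise InvalidParameterError(f"invalid band {self.band}")
        if not 0 < self.stability_fraction <= 1:
            raise InvalidParameterError("stability_fraction must be in (0, 1]")
        if self.kernel not in ("rbf", "linear"):
            raise InvalidParameterError(f"unsupported kernel '{self.kernel}'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "grid", "holdout"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(dataclasses.asdict(self))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        spec = SyntheticCohortSpec(seed=config.seed, **config.simulate)
        cohort = simulate_cohort(spec)
        subjects = list(cohort.participants["subject_id"])
        return (
            dict(zip(subjects, cohort.bold)),
            cohort.atlas,
            cohort.participants,
            {sid: None for sid in subjects},
        )
    participants = read_participants(config.participants_path)
    atlas = load_atlas(config.atlas_path)
    bold_dir = Path(config.bold_dir)
    volumes, confounds = {}, {}
    for sid in participants["subject_id"]:
        path = bold_dir / f"{sid}_bold.nii.gz"
        if not path.exists():
            raise InvalidInputError(f"stage clean: missing BOLD for subject {sid}: {path}")
        volumes[sid], _ = load_nifti(path)
        conf = None
        if config.confounds_dir is not None:
            cpath = Path(config.confounds_dir) / f"{sid}_confounds.tsv"
            if cpath.exists():
                conf = read_confounds(cpath)
        confounds[sid] = conf
    return volumes, atlas, participants, confounds


def _classify_outputs(run_dir: Path, matrix: FeatureMatrix, result: CVResult) -> None:
    metrics = {
        "accuracy": result.accuracy,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "auc": result.auc,
        "best_gamma": result.best_point.gamma,
        "best_C": result.best_point.C,
        "stability_threshold": result.stability_threshold,
        "stable_features": [int(matrix.roi_labels[i]) for i in result.stable_features],
    }
    (run_dir / "cv_result.json").write_text(json.dumps(metrics, indent=1))
    pd.DataFrame(
        result.per_point_accuracy, index=result.gammas, columns=result.Cs
    ).to_csv(run_dir / "grid_accuracy.csv")
    fpr, tpr = result.roc
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(run_dir / "roc.csv", index=False)
    pd.DataFrame(
        {
            "roi_label": [int(matrix.roi_labels[i]) for i in result.stable_features],
            "retention_count": result.retention_counts[result.stable_features],
            "mean_fisher_score": result.stable_mean_fisher,
        }
    ).to_csv(run_dir / "stable_features.csv", index=False)
    with open(run_dir / "fold_audit.jsonl", "w") as fh:
        for k, (outcome, sel) in enumerate(
            zip(result.fold_outcomes, result.fold_selections)
        ):
            fh.write(
                json.dumps(
                    {
                        "fold": k,
                        "held_out_id": outcome.held_out_id,
                        "true_label": outcome.true_label,
                        "predicted_label": outcome.predicted_label,
                        "decision_value": outcome.decision_value,
                        "retained_roi_labels": [
                            int(matrix.roi_labels[i]) for i in sel.retained
                        ],
                    }
                )
                + "\n"
            )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure is re-raised annotated with the stage name (and
    subject id where applicable).
    """
    config.validate()
    if config.out_dir is not None:
        run_dir = Path(config.out_dir)
    else:
        run_dir = Path(f"hurstfmri-run-{time.strftime('%Y%m%dT%H%M%S')}")
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        volumes, atlas, participants, confounds = _load_inputs(config)
        mask = atlas > 0
        low, high = config.band

        maps = {}
        for sid, vol in volumes.items():
            try:
                cleaned = clean_volume(
                    vol, mask, confounds[sid], low, high, config.tr_seconds
                )
                maps[sid] = hurst_map(cleaned, mask, correction=config.correction)
                if maps[sid].n_undefined:
                    log.warning(
                        "subject %s: %d degenerate voxel(s) flagged undefined",
                        sid,
                        maps[sid].n_undefined,
                    )
            except Exception as exc:
                raise type(exc)(f"stage hurst, subject {sid}: {exc}") from exc
        log.info("hurst maps computed for %d subjects", len(maps))

        matrix = build_feature_matrix(maps, atlas, participants)
        matrix.to_csv(run_dir / "features.csv")
        save_nifti(atlas, run_dir / "atlas.nii.gz")

        lo, hi, step = config.grid
        values = grid_values(lo, hi, step)
        gammas = values if config.kernel == "rbf" else np.array([1.0])
        result = grid_search(
            matrix,
            gammas=gammas,
            Cs=values,
            alpha=config.alpha,
            kernel=config.kernel,
            stability_fraction=config.stability_fraction,
        )
        log.info(
            "grid search: best (gamma=%g, C=%g) accuracy=%.3f auc=%.3f",
            result.best_point.gamma,
            result.best_point.C,
            result.accuracy,
            result.auc,
        )
        _classify_outputs(run_dir, matrix, result)

        if config.holdout is not None:
            hres = holdout_validation(
                matrix,
                *config.holdout,
                gammas=gammas,
                Cs=values,
                alpha=config.alpha,
                kernel=config.kernel,
                seed=config.seed,
            )
            (run_dir / "holdout.json").write_text(
                json.dumps(
                    {
                        "accuracy": hres.accuracy,
                        "inner_accuracy": hres.inner_accuracy,
                        "best_gamma": hres.best_point.gamma,
                        "best_C": hres.best_point.C,
                    },
                    indent=1,
                )
            )

        outputs = sorted(
            p for p in run_dir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "package": "hurstfmri",
            "version": __version__,
            "numpy": np.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            # config.yaml / run.log embed run-specific paths and timestamps
            "checksums": {
                p.name: _sha256(p)
                for p in outputs
                if p.name not in ("run.log", "config.yaml")
            },
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return run_dir
    finally:
        log.removeHandler(handler)
        handler.close()
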