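"""Atlas-ROI reduction of Hurst maps and the subjects x ROIs feature matrix."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, MissingROIError, ReconciliationError
from .hurst import HurstMap

__all__ = ["FeatureMatrix", "atlas_labels", "roi_means", "build_feature_matrix"]

GROUPS = ("MCI", "HC")


@dataclass
class FeatureMatrix:
    """Mean Hurst exponent per subject (rows) and atlas region (columns)."""

    values: np.ndarray  # (n_subjects, n_rois)
    subject_ids: list[str]
    groups: list[str]  # entries in {"MCI", "HC"}
    roi_labels: list[int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.subject_ids), len(self.roi_labels)):
            raise InvalidInputError("feature matrix shape mismatch")
        if len(self.groups) != len(self.subject_ids):
            raise InvalidInputError("one group label per subject required")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise InvalidInputError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(v).all():
            raise InvalidInputError("feature matrix contains undefined entries")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def group_indicator(self, group: str = "MCI") -> np.ndarray:
        return np.asarray([g == group for g in self.groups])

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        """Row view for a CV fold; column set and order are preserved."""
        idx = np.asarray(rows)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return FeatureMatrix(
            values=self.values[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            roi_labels=list(self.roi_labels),
        )

    def to_csv(self, path: str | Path) -> None:
        """CSV with ROI-label header and subject index; JSON sidecar for groups."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.roi_labels)
        df.index.name = "subject_id"
        df.to_csv(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"groups": dict(zip(self.subject_ids, self.groups))}, indent=1)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="subject_id")
        meta = json.loads(path.with_suffix(".json").read_text())
        ids = [str(i) for i in df.index]
        return cls(
            values=df.to_numpy(float),
            subject_ids=ids,
            groups=[meta["groups"][i] for i in ids],
            roi_labels=[int(c) for c in df.columns],
        )


def atlas_labels(atlas: np.ndarray) -> np.ndarray:
    """Sorted nonzero labels of an integer atlas volume."""
    a = np.asarray(atlas)
    if not np.issubdtype(a.dtype, np.integer):
        raise InvalidInputError("atlas must be an integer label volume")
    if a.min() < 0:
        raise InvalidInputError("atlas labels must be non-negative")
    labels = np.unique(a)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise InvalidInputError("atlas has no nonzero labels")
    return labels


def roi_means(hmap: HurstMap, atlas: np.ndarray) -> np.ndarray:
    """Arithmetic mean of defined map values over each atlas label.

    Undefined (degenerate) voxels are excluded; a label whose voxels are all
    undefined raises rather than producing a silent gap.
    """
    labels = atlas_labels(atlas)
    if atlas.shape != hmap.values.shape:
        raise InvalidInputError(
            f"atlas grid {atlas.shape} != map grid {hmap.values.shape}"
        )
    defined = hmap.defined
    lab_flat = np.asarray(atlas)[defined]
    val_flat = hmap.values[defined]
    maxlab = int(labels.max())
    counts = np.bincount(lab_flat, minlength=maxlab + 1)
    sums = np.bincount(lab_flat, weights=val_flat, minlength=maxlab + 1)
    empty = labels[counts[labels] == 0]
    if empty.size:
        raise MissingROIError(
            f"ROI label(s) with no defined voxels: {empty.tolist()}"
        )
    return sums[labels] / counts[labels]


def build_feature_matrix(
    maps: dict[str, HurstMap],
    atlas: np.ndarray,
    participants: pd.DataFrame,
) -> FeatureMatrix:
    """Assemble subjects x ROIs mean-HE matrix in participants-table order.

    ``maps`` is keyed by subject id; the participants table must have
    ``subject_id`` and ``group`` columns and match the map keys exactly.
    """
    if len(participants) == 0:
        raise InvalidInputError("participants table is empty")
    for col in ("subject_id", "group"):
        if col not in participants.columns:
            raise InvalidInputError(f"participants table lacks column '{col}'")
    ids = [str(s) for s in participants["subject_id"]]
    missing = [s for s in ids if s not in maps]
    extra = sorted(set(maps) - set(ids))
    if missing or extra:
        raise ReconciliationError(
            f"participants without a map: {missing}; maps without a row: {extra}"
        )
    labels = atlas_labels(atlas)
    values = np.vstack([roi_means(maps[s], atlas) for s in ids])
    return FeatureMatrix(
        values=values,
        subject_ids=ids,
        groups=[str(g) for g in participants["group"]],
        roi_labels=labels.tolist(),
    )
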