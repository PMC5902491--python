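"""NIfTI / TSV / CSV input-output helpers shared by the CLI and pipeline."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .synthetic import CohortData

__all__ = [
    "save_nifti",
    "load_nifti",
    "load_atlas",
    "read_participants",
    "read_confounds",
    "write_cohort",
]

DEFAULT_VOXEL_MM = 3.0


def save_nifti(
    data: np.ndarray,
    path: str | Path,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    tr: float | None = None,
) -> None:
    """Write a 3D/4D array with an isotropic affine; TR goes into the header."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Image]:
    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"no such NIfTI file: {p}")
    img = nib.load(str(p))
    return np.asarray(img.dataobj), img


def load_atlas(path: str | Path) -> np.ndarray:
    """Load a 3D integer label volume, validating dimensionality and dtype."""
    data, _ = load_nifti(path)
    if data.ndim != 3:
        raise InvalidInputError(f"atlas must be 3D, got {data.ndim}D: {path}")
    rounded = np.rint(data)
    if not np.allclose(data, rounded):
        raise InvalidInputError(f"atlas contains non-integer labels: {path}")
    return rounded.astype(np.int32)


def read_participants(path: str | Path) -> pd.DataFrame:
    """Participants TSV with columns subject_id, group and optional mmse."""
    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"no such participants table: {p}")
    df = pd.read_csv(p, sep="\t", dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise InvalidInputError(f"participants table lacks column '{col}'")
    return df


def read_confounds(path: str | Path) -> np.ndarray:
    """Confound regressors as a (timepoints x k) TSV with a header row."""
    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"no such confounds table: {p}")
    df = pd.read_csv(p, sep="\t")
    arr = df.to_numpy(float)
    if not np.isfinite(arr).all():
        raise InvalidInputError(f"confounds contain non-finite values: {p}")
    return arr


def write_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Persist a synthetic cohort: per-subject 4D NIfTI, atlas, participants.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tr = cohort.spec.tr_seconds
    for sid, vol in zip(cohort.participants["subject_id"], cohort.bold):
        save_nifti(vol.astype(np.float32), out / f"{sid}_bold.nii.gz", tr=tr)
    save_nifti(cohort.atlas, out / "atlas.nii.gz")
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    return out
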