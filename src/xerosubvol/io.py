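"""NIfTI volume and CSV cohort I/O.

Volumes (organ masks, dose grids) travel as NIfTI files, one per ROI, with
the voxel grid encoded in the affine (diagonal spacing, translation =
origin).  Tabular data travel as CSV with a leading comment line naming
physical units; readers accept those comment lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError
from .grid import DoseGrid, Mask, VoxelGrid
from .inference import AssessmentTimeline

UNITS_COMMENT = "# units: dose cGy; volume cc; days integer days post-RT\n"


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def _grid_from_affine(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0):
        raise ValidationError(f"{img.get_filename()}: rotated/oblique grids unsupported")
    spacing = tuple(float(aff[i, i]) for i in range(3))
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"{img.get_filename()}: non-positive voxel spacing")
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return VoxelGrid(tuple(int(d) for d in img.shape[:3]), spacing, origin)


def write_volume(path: str | Path, volume: Mask | DoseGrid) -> Path:
    """Write a mask (uint8 0/1) or dose grid (float32 cGy) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, Mask):
        data = volume.voxels.astype(np.uint8)
        grid = volume.grid
    else:
        data = volume.values.astype(np.float32)
        grid = volume.grid
    img = nib.Nifti1Image(data, _affine(grid))
    nib.save(img, str(path))
    return path


def load_volume(
    path: str | Path,
    kind: str,
    roi_name: str | None = None,
    expect_grid: VoxelGrid | None = None,
) -> Mask | DoseGrid:
    """Load a NIfTI volume as a validated Mask or DoseGrid.

    ``kind`` is ``"mask"`` or ``"dose"``.  Masks must be strictly binary;
    doses must be finite and nonnegative (a NaN voxel is reported with its
    index).  If ``expect_grid`` is given, grid metadata must match it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_affine(img)
    if expect_grid is not None and grid != expect_grid:
        raise GridMismatchError(
            f"{path.name}: grid {grid} does not match session grid {expect_grid}"
        )
    data = np.asarray(img.dataobj)
    if kind == "mask":
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError(
                f"{path.name}: mask is non-binary (values include "
                f"{[v for v in uniq if v not in (0, 1)][:5]})"
            )
        return Mask(roi_name or path.stem.replace(".nii", ""), grid,
                    data.astype(bool), require_nonempty=False)
    if kind == "dose":
        return DoseGrid(grid, np.asarray(data, dtype=float))
    raise ValidationError(f"kind must be 'mask' or 'dose', got {kind!r}")


def write_table(path: str | Path, df: pd.DataFrame, index: bool = True) -> Path:
    """Write a CSV with the standard units comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(UNITS_COMMENT)
        df.to_csv(fh, index=index, lineterminator="\n")
    return path


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_assessments(path: str | Path, timelines: list[AssessmentTimeline]) -> Path:
    rows = [
        {"patient_id": tl.patient_id, "days_post_rt": d, "ctcae_grade": g}
        for tl in timelines
        for d, g in tl.assessments
    ]
    return write_table(path, pd.DataFrame(rows), index=False)


def read_assessments(path: str | Path) -> list[AssessmentTimeline]:
    df = pd.read_csv(path, comment="#")
    out = []
    for pid, sub in df.groupby("patient_id", sort=True):
        sub = sub.sort_values("days_post_rt")
        out.append(
            AssessmentTimeline(
                str(pid),
                list(zip(sub["days_post_rt"].astype(int), sub["ctcae_grade"].astype(int))),
            )
        )
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
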