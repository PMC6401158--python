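"""Voxel-grid containers for masks and dose distributions.

Coordinate convention (fixed for the whole package): axis 0 = x, increasing
from the patient's right toward the left; axis 1 = y, increasing from
anterior toward posterior; axis 2 = z, increasing from inferior toward
superior.  Voxels are classified by their center point; voxel ``(i, j, k)``
has center ``origin_mm + (i, j, k) * spacing_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import GridMismatchError, ValidationError

#: canonical paired-organ names, plus the mandible
ORGAN_NAMES = ("PG_left", "PG_right", "SMG_left", "SMG_right", "mandible")

#: parotid sector name components
SI_SECTIONS = ("sup", "mid", "inf")
RADIAL_SECTORS = ("med", "ant", "post")


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice shared by all volumes of one patient."""

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValidationError(f"dims must be three positive ints, got {self.dims}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(
                f"spacing_mm must be three positive reals, got {self.spacing_mm}"
            )
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates (mm) along each axis."""
        return tuple(
            self.origin_mm[a] + np.arange(self.dims[a]) * self.spacing_mm[a]
            for a in range(3)
        )

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical-coordinate arrays (open meshgrid, mm)."""
        ax = self.coordinate_axes()
        return np.ix_(*ax)


def _require_same_grid(a: "VoxelGrid", b: "VoxelGrid") -> None:
    if a != b:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


@dataclass
class Mask:
    """Named binary region of interest on a voxel grid."""

    roi_name: str
    grid: VoxelGrid
    voxels: np.ndarray
    require_nonempty: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.shape != self.grid.dims:
            raise GridMismatchError(
                f"mask {self.roi_name!r}: shape {v.shape} != grid dims {self.grid.dims}"
            )
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError(
                    f"mask {self.roi_name!r} is not binary (values {uniq[:5]}...)"
                )
            v = v.astype(bool)
        self.voxels = v
        if self.require_nonempty and not v.any():
            raise ValidationError(f"mask {self.roi_name!r} is empty")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        """Physical volume: voxel count x voxel volume, exactly."""
        return self.voxel_count * self.grid.voxel_volume_cc

    def centroid_mm(self) -> np.ndarray:
        """Physical centroid of the mask's voxel centers."""
        idx = np.argwhere(self.voxels)
        if idx.size == 0:
            raise ValidationError(f"mask {self.roi_name!r} is empty")
        sp = np.asarray(self.grid.spacing_mm)
        org = np.asarray(self.grid.origin_mm)
        return org + idx.mean(axis=0) * sp

    def with_voxels(self, voxels: np.ndarray, name: str | None = None,
                    require_nonempty: bool = False) -> "Mask":
        return Mask(name or self.roi_name, self.grid, voxels,
                    require_nonempty=require_nonempty)


@dataclass
class DoseGrid:
    """Absorbed-dose distribution in cGy on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.dims:
            raise GridMismatchError(
                f"dose shape {v.shape} != grid dims {self.grid.dims}"
            )
        bad = ~np.isfinite(v)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValidationError(f"dose contains non-finite value at voxel {idx}")
        if (v < 0).any():
            idx = tuple(int(i) for i in np.argwhere(v < 0)[0])
            raise ValidationError(f"dose contains negative value at voxel {idx}")
        self.values = v


@dataclass
class StructureSet:
    """Co-registered organ masks of one patient plus tumor laterality."""

    masks: dict[str, Mask]
    tumor_laterality: str

    def __post_init__(self) -> None:
        missing = [n for n in ORGAN_NAMES if n not in self.masks]
        if missing:
            raise ValidationError(f"structure set missing masks: {missing}")
        if self.tumor_laterality not in ("left", "right"):
            raise ValidationError(
                f"tumor_laterality must be 'left' or 'right', got {self.tumor_laterality!r}"
            )
        grids = {m.grid for m in self.masks.values()}
        if len(grids) != 1:
            raise GridMismatchError("structure-set masks lie on different grids")

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.masks.values())).grid

    def __getitem__(self, name: str) -> Mask:
        return self.masks[name]


def subvolume_names() -> list[str]:
    """The 22 canonical subvolume names (2x9 parotid sectors, SMGs, OC halves)."""
    names = ["iOC", "cOC", "iSMG", "cSMG"]
    for side in ("i", "c"):
        for si in SI_SECTIONS:
            for rad in RADIAL_SECTORS:
                names.append(f"{side}PG_{si}_{rad}")
    return names


@dataclass
class SubvolumeSet:
    """The 22 derived subvolume masks, keyed by canonical name."""

    masks: dict[str, Mask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = set(subvolume_names())
        got = set(self.masks)
        if got != expected:
            raise ValidationError(
                f"subvolume set must contain exactly the 22 canonical names; "
                f"missing {sorted(expected - got)}, unexpected {sorted(got - expected)}"
            )
        grids = {m.grid for m in self.masks.values()}
        if len(grids) != 1:
            raise GridMismatchError("subvolume masks lie on different grids")

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.masks.values())).grid

    def __getitem__(self, name: str) -> Mask:
        return self.masks[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def items(self):
        return self.masks.items()
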