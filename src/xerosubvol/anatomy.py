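"""Radio-morphologic subvolume derivation for salivary-gland dosimetry.

Transforms a patient's organ masks (parotid and submandibular glands,
mandible) into 22 named subvolumes: each parotid is expanded by a 3 mm
shell and partitioned into 3 superior-inferior sections x 3 equal-angle
radial sectors; the submandibular glands are expanded; and a geometric
oral-cavity surrogate (the region outside the glands and mandible, bounded
by the lower two thirds of the parotids, the inferior submandibular extent
and the mandible's anterior/posterior extents) is split into ipsilateral
and contralateral halves.  Laterality ("i"/"c") is assigned from the
primary-tumor side.

All partitions are exact: sector masks are pairwise disjoint and their
union reproduces the parent mask voxel-for-voxel.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import EmptyRegionError, ValidationError
from .grid import (
    Mask,
    StructureSet,
    SubvolumeSet,
    SI_SECTIONS,
    RADIAL_SECTORS,
)

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_MM = 3.0


def map_laterality(structures: StructureSet) -> dict[str, str]:
    """Assign ipsilateral/contralateral roles to the paired organs.

    Organs on the tumor side become ipsilateral (``i``), the opposite side
    contralateral (``c``); the mandible is unpaired and gets no role.

    Returns
    -------
    dict mapping organ mask name (e.g. ``"PG_left"``) to role name
    (e.g. ``"iPG"``).
    """
    lat = structures.tumor_laterality
    if lat not in ("left", "right"):
        raise ValidationError(f"tumor laterality must be set, got {lat!r}")
    other = "right" if lat == "left" else "left"
    return {
        f"PG_{lat}": "iPG",
        f"PG_{other}": "cPG",
        f"SMG_{lat}": "iSMG",
        f"SMG_{other}": "cSMG",
    }


def expand_mask(mask: Mask, margin_mm: float) -> Mask:
    """Expand a mask by an isotropic physical margin (the "+3 mm shell").

    A voxel belongs to the output iff its center lies within ``margin_mm``
    (Euclidean distance, honoring anisotropic spacing) of some voxel center
    of the input mask; the original mask is always included.  Computed with
    a Euclidean distance transform on the mask complement.
    """
    if margin_mm < 0:
        raise ValidationError(f"margin_mm must be >= 0, got {margin_mm}")
    if not mask.voxels.any():
        raise ValidationError(f"cannot expand empty mask {mask.roi_name!r}")
    if margin_mm == 0:
        return mask.with_voxels(mask.voxels.copy(), require_nonempty=True)
    # the expansion can only reach margin_mm beyond the mask, so the
    # distance transform is evaluated on a padded bounding box only
    sp = mask.grid.spacing_mm
    pad = [int(np.ceil(margin_mm / sp[a])) + 1 for a in range(3)]
    sl = []
    for a in range(3):
        nz = np.nonzero(mask.voxels.any(axis=tuple(i for i in range(3) if i != a)))[0]
        sl.append(slice(max(0, nz[0] - pad[a]),
                        min(mask.grid.dims[a], nz[-1] + pad[a] + 1)))
    sl = tuple(sl)
    dist = ndimage.distance_transform_edt(~mask.voxels[sl], sampling=sp)
    out = np.zeros(mask.grid.dims, dtype=bool)
    out[sl] = dist <= margin_mm
    return mask.with_voxels(out, require_nonempty=True)


def split_si_thirds(mask: Mask) -> dict[str, Mask]:
    """Cut a mask into superior/middle/inferior thirds of its z-extent.

    The physical z-extent ``[z_min, z_max]`` of the mask's voxel centers is
    cut at 1/3 and 2/3; voxels are assigned by center coordinate with ties
    on a cut plane going to the more inferior section.  The three outputs
    partition the input exactly.
    """
    if not mask.voxels.any():
        raise ValidationError(f"cannot split empty mask {mask.roi_name!r}")
    zc = mask.grid.coordinate_axes()[2]
    k_idx = np.nonzero(mask.voxels.any(axis=(0, 1)))[0]
    z_min, z_max = zc[k_idx[0]], zc[k_idx[-1]]
    if k_idx[0] == k_idx[-1]:
        logger.warning(
            "mask %r spans a single z-slice; all voxels assigned to 'mid'",
            mask.roi_name,
        )
        empty = np.zeros(mask.grid.dims, dtype=bool)
        return {
            "sup": mask.with_voxels(empty.copy(), f"{mask.roi_name}_sup"),
            "mid": mask.with_voxels(mask.voxels.copy(), f"{mask.roi_name}_mid"),
            "inf": mask.with_voxels(empty.copy(), f"{mask.roi_name}_inf"),
        }
    cut1 = z_min + (z_max - z_min) / 3.0
    cut2 = z_min + 2.0 * (z_max - z_min) / 3.0
    z3 = zc[None, None, :]
    inf_v = mask.voxels & (z3 <= cut1)
    mid_v = mask.voxels & (z3 > cut1) & (z3 <= cut2)
    sup_v = mask.voxels & (z3 > cut2)
    return {
        "sup": mask.with_voxels(sup_v, f"{mask.roi_name}_sup"),
        "mid": mask.with_voxels(mid_v, f"{mask.roi_name}_mid"),
        "inf": mask.with_voxels(inf_v, f"{mask.roi_name}_inf"),
    }


def split_radial_sectors(mask: Mask, side: str) -> dict[str, Mask]:
    """Cut a mask into medial/anterior/posterior 120-degree wedges.

    In-plane angles are measured about the whole-gland 3-D centroid
    projected onto the axial plane — one shared angular frame for the whole
    gland.  The medial wedge is centered on the medial unit vector (-x for
    a left-side gland, +x for a right-side gland); the anterior wedge
    center is the medial vector rotated 120 degrees toward -y (anterior);
    the posterior wedge is the remainder.  Wedge boundaries sit at +/-60
    degrees; a voxel exactly on a boundary joins the next sector in the
    order medial -> anterior -> posterior (cyclic).
    """
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    n_vox = mask.voxel_count
    if n_vox == 0:
        raise ValidationError(f"cannot sector empty mask {mask.roi_name!r}")
    names = {r: f"{mask.roi_name}_{r}" for r in RADIAL_SECTORS}
    if n_vox == 1:
        logger.warning(
            "mask %r is a single voxel; assigned wholly to 'med'", mask.roi_name
        )
        empty = np.zeros(mask.grid.dims, dtype=bool)
        return {
            "med": mask.with_voxels(mask.voxels.copy(), names["med"]),
            "ant": mask.with_voxels(empty.copy(), names["ant"]),
            "post": mask.with_voxels(empty.copy(), names["post"]),
        }
    cx, cy, _ = mask.centroid_mm()
    xg, yg, _ = mask.grid.coordinate_grids()
    dx = xg - cx  # broadcastable (nx,1,1)
    dy = yg - cy  # (1,ny,1)
    # Medial unit vector: -x for a left gland, +x for a right gland.
    mx = -1.0 if side == "left" else 1.0
    # Signed angle from the medial vector, measured in the rotational
    # direction that carries it toward -y (anterior) — +120 deg is the
    # anterior wedge center for either side.  Built from the dot product
    # and the (side-corrected) cross product so that mirror-image inputs
    # yield bit-identical angles.
    s = 1.0 if side == "left" else -1.0
    dot = mx * dx + 0.0 * dy
    cross = s * (mx * dy)
    delta = np.degrees(np.arctan2(np.broadcast_to(cross, mask.grid.dims),
                                  np.broadcast_to(dot, mask.grid.dims)))
    med_v = mask.voxels & (delta >= -60.0) & (delta < 60.0)
    ant_v = mask.voxels & (delta >= 60.0) & (delta < 180.0)
    post_v = mask.voxels & ~med_v & ~ant_v
    return {
        "med": mask.with_voxels(med_v, names["med"]),
        "ant": mask.with_voxels(ant_v, names["ant"]),
        "post": mask.with_voxels(post_v, names["post"]),
    }


def partition_parotid(pg_expanded: Mask, side: str) -> dict[str, Mask]:
    """Partition an (expanded) parotid into 9 named sector masks.

    The radial split is computed once on the whole gland (a single angular
    frame shared by all superior-inferior sections) and intersected with
    the SI thirds.  Keys are ``"(sup|mid|inf)_(med|ant|post)"``; the 9
    masks partition the input exactly.
    """
    si = split_si_thirds(pg_expanded)
    radial = split_radial_sectors(pg_expanded, side)
    out: dict[str, Mask] = {}
    for si_name in SI_SECTIONS:
        for rad_name in RADIAL_SECTORS:
            key = f"{si_name}_{rad_name}"
            out[key] = pg_expanded.with_voxels(
                si[si_name].voxels & radial[rad_name].voxels,
                f"{pg_expanded.roi_name}_{key}",
            )
    return out


def build_oc_surrogate(
    pg_i: Mask,
    pg_c: Mask,
    smg_i: Mask,
    smg_c: Mask,
    mandible: Mask,
    tumor_laterality: str,
) -> tuple[Mask, Mask]:
    """Construct the ipsilateral/contralateral oral-cavity surrogate halves.

    The candidate region consists of all grid voxels

    * at or below the superior boundary of the lower 2/3 of the parotids
      (``z_min,PG + (2/3)(z_max,PG - z_min,PG)`` over the union of both
      expanded parotids),
    * at or above the inferior-most z of the submandibular union,
    * with y between the anterior-most and posterior-most mandible extents,
    * with x between the lateral extents of the two expanded parotids,

    minus every voxel belonging to a parotid, submandibular gland or the
    mandible.  The region is split at the midsagittal plane halfway between
    the two parotid centroids' x-coordinates; the ipsilateral half lies on
    the tumor side (a voxel centered exactly on the plane joins the left
    half).
    """
    grid = pg_i.grid
    xc, yc, zc = grid.coordinate_axes()
    pg_union = pg_i.voxels | pg_c.voxels
    smg_union = smg_i.voxels | smg_c.voxels

    k_pg = np.nonzero(pg_union.any(axis=(0, 1)))[0]
    z_lo_pg, z_hi_pg = zc[k_pg[0]], zc[k_pg[-1]]
    z_sup_bound = z_lo_pg + (2.0 / 3.0) * (z_hi_pg - z_lo_pg)
    k_smg = np.nonzero(smg_union.any(axis=(0, 1)))[0]
    z_inf_bound = zc[k_smg[0]]
    j_mand = np.nonzero(mandible.voxels.any(axis=(0, 2)))[0]
    y_ant_bound, y_post_bound = yc[j_mand[0]], yc[j_mand[-1]]
    i_pg = np.nonzero(pg_union.any(axis=(1, 2)))[0]
    x_lo_bound, x_hi_bound = xc[i_pg[0]], xc[i_pg[-1]]

    xg, yg, zg = grid.coordinate_grids()
    cand = (
        (zg <= z_sup_bound)
        & (zg >= z_inf_bound)
        & (yg >= y_ant_bound)
        & (yg <= y_post_bound)
        & (xg >= x_lo_bound)
        & (xg <= x_hi_bound)
    )
    cand = np.broadcast_to(cand, grid.dims).copy()
    cand &= ~(pg_union | smg_union | mandible.voxels)
    if not cand.any():
        bounds = {
            "superior(z<=lower-2/3-PG)": z_sup_bound,
            "inferior(z>=SMG-min)": z_inf_bound,
            "anterior/posterior(mandible-y)": (y_ant_bound, y_post_bound),
            "lateral(PG-x)": (x_lo_bound, x_hi_bound),
        }
        if z_inf_bound > z_sup_bound:
            which = "superior/inferior z-band (SMG minimum above the PG lower-2/3 bound)"
        elif y_ant_bound > y_post_bound:
            which = "mandible y-extent"
        else:
            which = "candidate region after organ exclusion"
        raise EmptyRegionError(
            f"oral-cavity surrogate is empty: collapsed bound = {which}; bounds={bounds}"
        )

    x_mid = 0.5 * (pg_i.centroid_mm()[0] + pg_c.centroid_mm()[0])
    left_half = cand & np.broadcast_to(xg >= x_mid, grid.dims)
    right_half = cand & ~np.broadcast_to(xg >= x_mid, grid.dims)
    if tumor_laterality == "left":
        i_vox, c_vox = left_half, right_half
    else:
        i_vox, c_vox = right_half, left_half
    for name, v in (("iOC", i_vox), ("cOC", c_vox)):
        if not v.any():
            raise EmptyRegionError(
                f"oral-cavity surrogate half {name} is empty after the midsagittal split"
            )
    return (
        Mask("iOC", grid, i_vox),
        Mask("cOC", grid, c_vox),
    )


def derive_subvolumes(
    structures: StructureSet, margin_mm: float = DEFAULT_MARGIN_MM
) -> SubvolumeSet:
    """Run the full derivation: laterality, expansion, partition, OC surrogate.

    Returns the 22 canonical subvolumes: 2x9 parotid sectors on the expanded
    glands, the two expanded submandibular glands, and the two oral-cavity
    surrogate halves.  Deterministic: identical inputs give bit-identical
    masks.
    """
    roles = map_laterality(structures)
    role_to_organ = {v: k for k, v in roles.items()}
    expanded: dict[str, Mask] = {}
    for role in ("iPG", "cPG", "iSMG", "cSMG"):
        organ = role_to_organ[role]
        m = expand_mask(structures[organ], margin_mm)
        expanded[role] = m.with_voxels(m.voxels, role, require_nonempty=True)

    out: dict[str, Mask] = {}
    for role in ("iSMG", "cSMG"):
        out[role] = expanded[role]
    lat = structures.tumor_laterality
    other = "right" if lat == "left" else "left"
    for role, side in (("iPG", lat), ("cPG", other)):
        sectors = partition_parotid(expanded[role], side)
        for key, m in sectors.items():
            out[f"{role}_{key}"] = m.with_voxels(m.voxels, f"{role}_{key}")
    ioc, coc = build_oc_surrogate(
        expanded["iPG"],
        expanded["cPG"],
        expanded["iSMG"],
        expanded["cSMG"],
        structures["mandible"],
        lat,
    )
    out["iOC"] = ioc
    out["cOC"] = coc
    return SubvolumeSet(out)
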