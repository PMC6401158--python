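"""Cumulative DVHs, Dx features and the 214-column design matrix.

Dose-volume features are the doses covering the hottest x% of each derived
subvolume, D10 through D90 in 10% steps, over the 22 subvolumes: 198 dose
features per patient.  Adding 16 encoded clinical columns (age, gender,
race, chemotherapy, tumor-site dummies and six gland/oral-cavity volumes)
gives the 214-predictor design matrix.

Quantile convention
-------------------
The DVH is the exact empirical voxel sample (no dose binning).  Dx is
computed by linear interpolation of the descending sorted sample at the
0-based rank position ``x/100 * (N - 1)``.  Several Dx conventions exist
and differ on small subvolumes; this one is fixed and recorded in report
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ValidationError
from .grid import DoseGrid, Mask, SubvolumeSet, subvolume_names

logger = logging.getLogger(__name__)

#: Dx levels extracted from every subvolume, percent of volume
DX_LEVELS = tuple(range(10, 100, 10))

#: quantile convention identifier, logged and written to report manifests
QUANTILE_CONVENTION = "linear interpolation of descending sample at rank x/100*(N-1)"

RACES = ("white", "african_american", "other")
TUMOR_SITES = (
    "nasopharynx",
    "oral_cavity",
    "oropharynx",
    "hypopharynx",
    "larynx",
    "others",
)
GENDERS = ("male", "female")
VOLUME_KEYS = ("iPG", "cPG", "iSMG", "cSMG", "iOC", "cOC")

#: the 16 clinical predictor columns, in canonical order
CLINICAL_COLUMNS = (
    "age_gt_65",
    "male",
    "race_african_american",
    "race_other",
    "chemo",
    "site_nasopharynx",
    "site_oral_cavity",
    "site_oropharynx",
    "site_hypopharynx",
    "site_larynx",
    "vol_iPG",
    "vol_cPG",
    "vol_iSMG",
    "vol_cSMG",
    "vol_iOC",
    "vol_cOC",
)


def dose_feature_columns() -> list[str]:
    """The 198 dose-feature column names in canonical order.

    Subvolume names sorted lexically, then Dx ascending within each.
    """
    return [f"{sv}_D{x}" for sv in sorted(subvolume_names()) for x in DX_LEVELS]


def predictor_columns() -> list[str]:
    """All 214 predictor columns: 198 dose then 16 clinical."""
    return dose_feature_columns() + list(CLINICAL_COLUMNS)


@dataclass
class DVHCurve:
    """Exact empirical cumulative DVH: the sorted voxel dose sample."""

    subvolume: str
    doses_cgy: np.ndarray  # sorted descending
    voxel_count: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_cgy, dtype=float)
        if d.size == 0:
            raise ValidationError(f"DVH for {self.subvolume!r} is empty")
        if (np.diff(d) > 0).any():
            raise ValidationError(f"DVH for {self.subvolume!r} is not sorted descending")
        self.doses_cgy = d
        if self.voxel_count == 0:
            self.voxel_count = d.size


def cumulative_dvh(mask: Mask, dose: DoseGrid) -> DVHCurve:
    """Collect the dose at every voxel of ``mask``, sorted descending.

    No binning is applied; the curve is the exact empirical sample and its
    length equals the mask's voxel count.
    """
    if mask.grid != dose.grid:
        raise GridMismatchError(
            f"mask {mask.roi_name!r} and dose lie on different grids"
        )
    if not mask.voxels.any():
        raise ValidationError(f"mask {mask.roi_name!r} is empty")
    sample = np.sort(dose.values[mask.voxels])[::-1]
    return DVHCurve(mask.roi_name, sample)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """Dx: the dose received by the hottest ``x_percent`` of the subvolume.

    Linear interpolation of the descending sample at 0-based rank position
    ``x/100 * (N-1)``.
    """
    if not 0.0 < x_percent < 100.0:
        raise ValidationError(f"x_percent must be in (0, 100), got {x_percent}")
    s = dvh.doses_cgy
    pos = x_percent / 100.0 * (s.size - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    if frac == 0.0 or lo + 1 >= s.size:
        return float(s[lo])
    return float(s[lo] + frac * (s[lo + 1] - s[lo]))


def extract_dose_features(
    subvols: SubvolumeSet, dose: DoseGrid
) -> dict[str, float]:
    """D10..D90 for each of the 22 subvolumes: 198 named features.

    Deterministic column order (subvolume name lexical, Dx ascending).
    An empty subvolume — possible only for degenerate geometry — yields
    zero features with a warning rather than an error.
    """
    features: dict[str, float] = {}
    for sv in sorted(subvolume_names()):
        mask = subvols[sv]
        if not mask.voxels.any():
            logger.warning("subvolume %s is empty; its Dx features set to 0", sv)
            for x in DX_LEVELS:
                features[f"{sv}_D{x}"] = 0.0
            continue
        curve = cumulative_dvh(mask, dose)
        for x in DX_LEVELS:
            features[f"{sv}_D{x}"] = dose_at_volume(curve, x)
    return features


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates entering both outcome models."""

    age_gt_65: bool
    gender: str
    race: str
    chemo: bool
    tumor_site: str
    volumes_cc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.race not in RACES:
            raise ValidationError(f"unknown race {self.race!r}")
        if self.tumor_site not in TUMOR_SITES:
            raise ValidationError(f"unknown tumor site {self.tumor_site!r}")
        missing = [k for k in VOLUME_KEYS if k not in self.volumes_cc]
        if missing:
            raise ValidationError(f"clinical record missing volumes: {missing}")
        for k in VOLUME_KEYS:
            if self.volumes_cc[k] < 0:
                raise ValidationError(f"volume {k} is negative")


def encode_clinical(rec: ClinicalRecord) -> dict[str, float]:
    """Encode a clinical record as the 16 numeric predictor columns.

    Dummy coding with "white" race and "others" tumor site as reference
    cells; six subvolume-group volumes pass through in cc.
    """
    enc = {
        "age_gt_65": float(rec.age_gt_65),
        "male": float(rec.gender == "male"),
        "race_african_american": float(rec.race == "african_american"),
        "race_other": float(rec.race == "other"),
        "chemo": float(rec.chemo),
    }
    for site in TUMOR_SITES[:-1]:  # "others" is the reference
        enc[f"site_{site}"] = float(rec.tumor_site == site)
    for k in VOLUME_KEYS:
        enc[f"vol_{k}"] = float(rec.volumes_cc[k])
    assert len(enc) == 16
    return enc


def build_design_matrix(
    patient_ids: list[str],
    dose_features: list[dict[str, float]],
    clinical: list[ClinicalRecord],
    injury: list[int],
    recovery: list[int | None],
) -> pd.DataFrame:
    """Assemble the n x 214 design matrix with outcome labels attached.

    Returns a DataFrame indexed by patient id with the 198 dose columns,
    the 16 clinical columns, an ``injury`` column (0/1 for every patient)
    and a ``recovery`` column (0/1 for injured patients, NaN otherwise —
    the recovery model population is the injured subset).
    """
    n = len(patient_ids)
    if not (len(dose_features) == len(clinical) == len(injury) == len(recovery) == n):
        raise ValidationError("design-matrix inputs have inconsistent lengths")
    if len(set(patient_ids)) != n:
        dupes = sorted({p for p in patient_ids if patient_ids.count(p) > 1})
        raise ValidationError(f"duplicated patient ids: {dupes}")
    cols = predictor_columns()
    rows = []
    for pid, feats, rec, inj, recov in zip(
        patient_ids, dose_features, clinical, injury, recovery
    ):
        row = dict(feats)
        row.update(encode_clinical(rec))
        missing = [c for c in cols if c not in row]
        if missing:
            raise ValidationError(f"patient {pid}: missing predictors {missing[:5]}")
        if inj not in (0, 1):
            raise ValidationError(f"patient {pid}: injury label must be 0/1")
        if inj == 0 and recov is not None:
            raise ValidationError(
                f"patient {pid}: recovery defined for a non-injured patient"
            )
        if inj == 1 and recov not in (0, 1):
            raise ValidationError(f"patient {pid}: injured but recovery undefined")
        row["injury"] = inj
        row["recovery"] = np.nan if recov is None else recov
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(patient_ids, name="patient_id"))
    return df[cols + ["injury", "recovery"]]


def read_deposited_features(path) -> pd.DataFrame:
    """Read a deposited per-patient feature CSV onto the design-matrix schema.

    Accepts the published study tables (or any CSV with the same column
    names); matching is case-insensitive.  Rows must carry a patient_id
    column, the 198 dose columns, the 16 clinical columns and the outcome
    labels.
    """
    raw = pd.read_csv(path)
    lower_map = {c.lower(): c for c in raw.columns}
    wanted = predictor_columns() + ["injury", "recovery"]
    rename: dict[str, str] = {}
    missing: list[str] = []
    for col in wanted + ["patient_id"]:
        src = lower_map.get(col.lower())
        if src is None:
            if col == "recovery":
                continue  # optional for injury-only tables
            missing.append(col)
        else:
            rename[src] = col
    if missing:
        raise ValidationError(f"deposited table missing columns: {missing[:8]}")
    df = raw.rename(columns=rename).set_index("patient_id")
    keep = [c for c in wanted if c in df.columns]
    return df[keep]
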