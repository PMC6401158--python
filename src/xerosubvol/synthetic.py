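"""Synthetic head-and-neck cohort generator with a known dose -> outcome link.

Emulates the data a salivary-gland dosimetry study consumes, entirely in
silico: bilateral ellipsoidal parotid and submandibular glands around a
mandible arc, an ipsilateral-skewed Gaussian dose field spanning roughly
0-7900 cGy, clinical covariates drawn from study-like category mixes, and
longitudinal CTCAE xerostomia timelines generated from a logistic model on
chosen subvolume dose features.  Because the injury/recovery mechanism is
configured explicitly, every downstream stage (partitioning, DVH features,
permutation testing, nested CV) can be validated against ground truth.

Geometry is deliberately simple — jittered ellipsoids, not meshes — but
satisfies every spatial premise of the real pipeline: parotids lateral-
posterior to the mandible arc, submandibular glands inferior-medial, the
parotids' inferior extent overlapping the SMGs' superior extent so the
oral-cavity surrogate band is nonempty, and left/right symmetry up to
jitter.

Dose features enter the outcome logit in units of 1000 cGy (10 Gy), so a
weight of 1 means one unit of log-odds per 10 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import anatomy
from .dosimetry import (
    ClinicalRecord,
    RACES,
    TUMOR_SITES,
    dose_feature_columns,
    extract_dose_features,
)
from .errors import ConfigurationError, SizingError
from .grid import DoseGrid, Mask, StructureSet, SubvolumeSet, VoxelGrid
from .inference import AssessmentTimeline, derive_outcomes

#: fixed follow-up schedule, days post-RT (NCCN-style: 6 weeks, then q3 months)
VISIT_SCHEDULE = (42, 90, 180, 270, 365, 450, 548)

#: probability that an injured patient's first grade >=2 falls at each of the
#: first three visits (on-treatment, 3-month, 6-month)
ONSET_PROBS = (0.85, 0.10, 0.05)

#: nominal organ geometry, mm (x mirrored for the right side)
PAROTID_CENTER = (52.0, 12.0, 10.0)
PAROTID_AXES = (15.0, 20.0, 25.0)
SMG_CENTER = (26.0, -12.0, -20.0)
SMG_AXES = (12.0, 15.0, 10.0)
MANDIBLE_Y_ANT = -45.0
MANDIBLE_CURVATURE = 0.025  # y = y_ant + c * x^2
MANDIBLE_HALF_WIDTH = 40.0
MANDIBLE_THICKNESS = 4.0
MANDIBLE_Z = (-30.0, 5.0)

#: dose-target offset from midline toward the ipsilateral parotid's
#: medial-inferior aspect, mm
DOSE_TARGET = (32.0, 10.0, -5.0)
DOSE_TARGET_JITTER_MM = 5.0


class ClinicalMix(BaseModel):
    """Category probabilities for the clinical covariates.

    Defaults reproduce the marginal distribution of a 258-patient
    head-and-neck cohort (age > 65 in 27.9%, 78.3% male, etc.).
    """

    age_gt_65: float = 72 / 258
    male: float = 202 / 258
    chemo: float = 175 / 258
    race: dict[str, float] = Field(
        default_factory=lambda: {
            "white": 206 / 258,
            "african_american": 46 / 258,
            "other": 6 / 258,
        }
    )
    tumor_site: dict[str, float] = Field(
        default_factory=lambda: {
            "nasopharynx": 10 / 258,
            "oral_cavity": 66 / 258,
            "oropharynx": 100 / 258,
            "hypopharynx": 6 / 258,
            "larynx": 35 / 258,
            "others": 41 / 258,
        }
    )

    @model_validator(mode="after")
    def _check(self):
        for p in (self.age_gt_65, self.male, self.chemo):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        for name, mix, domain in (
            ("race", self.race, RACES),
            ("tumor_site", self.tumor_site, TUMOR_SITES),
        ):
            if set(mix) != set(domain):
                raise ValueError(f"{name} mix must cover exactly {domain}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        return self


class CohortConfig(BaseModel):
    """Full configuration of a synthetic cohort.

    ``effects`` maps dose-feature names (e.g. ``"cPG_mid_ant_D30"``) to
    logit weights per ``dose_feature_scale_cgy`` of dose, separately for
    the injury and the recovery mechanism.  Intercepts are calibrated so
    the default cohort lands near 68% injury prevalence and 77% recovery
    among the injured.
    """

    n_patients: int = Field(258, gt=0)
    seed: int = 0
    grid_shape: tuple[int, int, int] = (68, 44, 40)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin_mm: tuple[float, float, float] = (-83.75, -58.75, -48.75)
    prescription_cgy: float = Field(7000.0, gt=0)
    dose_sigma_mm: float = Field(35.0, gt=0)
    dose_noise_sd_cgy: float = Field(150.0, ge=0)
    dose_modulation_amp: float = Field(0.5, ge=0)
    dose_modulation_corr_mm: float = Field(12.0, gt=0)
    jitter_axes_frac: float = Field(0.15, ge=0)
    jitter_center_mm: float = Field(4.0, ge=0)
    effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "injury": {"cPG_mid_ant_D30": 10.0, "cPG_mid_post_D30": 10.0},
            "recovery": {"cPG_sup_ant_D50": -10.0, "cPG_sup_post_D50": -10.0},
        }
    )
    injury_intercept: float = -6.08
    recovery_intercept: float = 6.25
    clinical_effects: dict[str, float] = Field(default_factory=dict)
    dose_feature_scale_cgy: float = Field(1000.0, gt=0)
    clinical_mix: ClinicalMix = Field(default_factory=ClinicalMix)

    @model_validator(mode="after")
    def _check(self):
        valid = set(dose_feature_columns())
        for outcome, eff in self.effects.items():
            if outcome not in ("injury", "recovery"):
                raise ValueError(f"effects keys must be injury/recovery, got {outcome!r}")
            unknown = sorted(set(eff) - valid)
            if unknown:
                raise ConfigurationError(
                    f"{outcome} effects name unknown dose features: {unknown}"
                )
            for k, w in eff.items():
                if not np.isfinite(w):
                    raise ValueError(f"effect weight {k} is not finite")
        return self

    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.grid_shape, self.spacing_mm, self.origin_mm)


@dataclass
class SyntheticPatient:
    """One simulated patient with its latent ground-truth labels."""

    patient_id: str
    structure_set: StructureSet | None
    dose: DoseGrid | None
    clinical: ClinicalRecord
    timeline: AssessmentTimeline
    latent_injury: int
    latent_recovery: int | None
    dose_features: dict[str, float]
    subvolumes: SubvolumeSet | None = None


def _patient_rng(config_seed: int, patient_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config_seed & 0x7FFFFFFF, patient_seed, stream])
    )


def _ellipsoid(grid: VoxelGrid, center, axes) -> np.ndarray:
    xg, yg, zg = grid.coordinate_grids()
    q = (
        ((xg - center[0]) / axes[0]) ** 2
        + ((yg - center[1]) / axes[1]) ** 2
        + ((zg - center[2]) / axes[2]) ** 2
    )
    return q <= 1.0


def _check_fits(grid: VoxelGrid, name: str, center, axes, margin: float = 3.0) -> None:
    axes_arr = np.asarray(axes, dtype=float)
    lo = np.asarray(center) - axes_arr - margin
    hi = np.asarray(center) + axes_arr + margin
    ax = grid.coordinate_axes()
    for a in range(3):
        if lo[a] < ax[a][0] or hi[a] > ax[a][-1]:
            raise SizingError(
                f"grid too small to place structure {name!r}: needs "
                f"[{lo[a]:.1f}, {hi[a]:.1f}] mm on axis {a}, grid spans "
                f"[{ax[a][0]:.1f}, {ax[a][-1]:.1f}] mm"
            )


def generate_anatomy(config: CohortConfig, patient_seed: int) -> StructureSet:
    """Generate one patient's five disjoint organ masks plus laterality.

    Parotids are jittered ellipsoids lateral-posterior to a parabolic
    mandible arc, submandibular glands inferior-medial to the parotids.
    Per-patient jitter is uniform within +/-``jitter_axes_frac`` on
    semi-axes and +/-``jitter_center_mm`` on centers.  Where jittered
    ellipsoids graze one another, disjointness is restored by subtraction
    with priority parotid > submandibular > mandible.
    """
    rng = _patient_rng(config.seed, patient_seed, 1)
    grid = config.grid()
    laterality = "left" if rng.random() < 0.5 else "right"

    def jitter_center(c):
        return np.asarray(c) + rng.uniform(-config.jitter_center_mm,
                                           config.jitter_center_mm, 3)

    def jitter_axes(a):
        return np.asarray(a) * (1.0 + rng.uniform(-config.jitter_axes_frac,
                                                  config.jitter_axes_frac, 3))

    masks: dict[str, np.ndarray] = {}
    for organ, nominal_c, nominal_a in (
        ("PG_left", PAROTID_CENTER, PAROTID_AXES),
        ("PG_right", (-PAROTID_CENTER[0],) + PAROTID_CENTER[1:], PAROTID_AXES),
        ("SMG_left", SMG_CENTER, SMG_AXES),
        ("SMG_right", (-SMG_CENTER[0],) + SMG_CENTER[1:], SMG_AXES),
    ):
        c = jitter_center(nominal_c)
        a = jitter_axes(nominal_a)
        _check_fits(grid, organ, c, a)
        masks[organ] = _ellipsoid(grid, c, a)

    xg, yg, zg = grid.coordinate_grids()
    arc_y = MANDIBLE_Y_ANT + MANDIBLE_CURVATURE * xg**2
    mand = (
        (np.abs(yg - arc_y) <= MANDIBLE_THICKNESS)
        & (np.abs(xg) <= MANDIBLE_HALF_WIDTH)
        & (zg >= MANDIBLE_Z[0])
        & (zg <= MANDIBLE_Z[1])
    )
    mand = np.broadcast_to(mand, grid.dims).copy()
    if MANDIBLE_Y_ANT - MANDIBLE_THICKNESS < grid.origin_mm[1]:
        raise SizingError("grid too small to place structure 'mandible' anteriorly")

    pg_union = masks["PG_left"] | masks["PG_right"]
    for smg in ("SMG_left", "SMG_right"):
        masks[smg] &= ~pg_union
    smg_union = masks["SMG_left"] | masks["SMG_right"]
    mand &= ~(pg_union | smg_union)
    masks["mandible"] = mand

    return StructureSet(
        masks={n: Mask(n, grid, v) for n, v in masks.items()},
        tumor_laterality=laterality,
    )


def generate_dose(
    structures: StructureSet, config: CohortConfig, patient_seed: int
) -> DoseGrid:
    """Generate an ipsilateral-skewed Gaussian dose field on the grid.

    ``dose(v) = prescription * exp(-||v - c||^2 / (2 sigma^2)) + noise``
    with the target ``c`` placed on the tumor side near the ipsilateral
    parotid's medial-inferior aspect, additive Gaussian noise truncated at
    +/-3 sd, and the result clipped at 0.  Ipsilateral structures receive
    systematically higher dose than contralateral ones.

    A smooth multiplicative modulation field (correlation length
    ``dose_modulation_corr_mm``, relative amplitude
    ``dose_modulation_amp``) emulates per-plan fluence variability, so
    regional doses vary partly independently between patients the way
    modulated plans do; the modulated field is capped at the prescription
    before noise, mimicking plan normalization.
    """
    rng = _patient_rng(config.seed, patient_seed, 2)
    grid = structures.grid
    sign = 1.0 if structures.tumor_laterality == "left" else -1.0
    target = np.array([sign * DOSE_TARGET[0], DOSE_TARGET[1], DOSE_TARGET[2]])
    target += rng.uniform(-DOSE_TARGET_JITTER_MM, DOSE_TARGET_JITTER_MM, 3)

    xg, yg, zg = grid.coordinate_grids()
    r2 = (xg - target[0]) ** 2 + (yg - target[1]) ** 2 + (zg - target[2]) ** 2
    dose = config.prescription_cgy * np.exp(-r2 / (2.0 * config.dose_sigma_mm**2))
    dose = np.broadcast_to(dose, grid.dims).copy()
    if config.dose_modulation_amp > 0:
        from scipy.ndimage import gaussian_filter

        white = rng.normal(0.0, 1.0, grid.dims)
        sig_vox = [config.dose_modulation_corr_mm / s for s in grid.spacing_mm]
        smooth = gaussian_filter(white, sig_vox, mode="nearest")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        dose *= np.clip(1.0 + config.dose_modulation_amp * smooth, 0.4, 1.6)
        dose = np.minimum(dose, config.prescription_cgy)
    if config.dose_noise_sd_cgy > 0:
        sd = config.dose_noise_sd_cgy
        noise = np.clip(rng.normal(0.0, sd, grid.dims), -3.0 * sd, 3.0 * sd)
        dose += noise
    return DoseGrid(grid, np.clip(dose, 0.0, None))


def _draw_clinical(rng: np.random.Generator, mix: ClinicalMix,
                   volumes_cc: dict[str, float]) -> ClinicalRecord:
    race = rng.choice(list(RACES), p=[mix.race[r] for r in RACES])
    site = rng.choice(list(TUMOR_SITES), p=[mix.tumor_site[s] for s in TUMOR_SITES])
    return ClinicalRecord(
        age_gt_65=bool(rng.random() < mix.age_gt_65),
        gender="male" if rng.random() < mix.male else "female",
        race=str(race),
        chemo=bool(rng.random() < mix.chemo),
        tumor_site=str(site),
        volumes_cc=volumes_cc,
    )


def _group_volumes(subvols: SubvolumeSet) -> dict[str, float]:
    """cc volumes of the six subvolume groups (parotid sectors summed)."""
    vols = {}
    for key in ("iSMG", "cSMG", "iOC", "cOC"):
        vols[key] = subvols[key].volume_cc
    for pg in ("iPG", "cPG"):
        vols[pg] = sum(m.volume_cc for n, m in subvols.items() if n.startswith(pg))
    return vols


def _make_timeline(
    patient_id: str,
    injured: bool,
    recovered: bool | None,
    rng: np.random.Generator,
) -> AssessmentTimeline:
    """Realize latent labels as a CTCAE timeline on the fixed visit schedule.

    Injured patients show their first grade >=2 at an on-treatment, 3-month
    or 6-month visit; recovered patients follow a monotone-recovery
    template dropping below grade 2 before the 18-month visit, which is
    always present.
    """
    n = len(VISIT_SCHEDULE)
    grades = [0] * n
    if not injured:
        grades[0] = 1 if rng.random() < 0.6 else 0
        grades[1] = min(grades[0], 1 if rng.random() < 0.5 else 0)
    else:
        onset = int(rng.choice(3, p=ONSET_PROBS))
        peak = 2 if rng.random() < 0.7 else 3
        for i in range(onset):
            grades[i] = 1 if rng.random() < 0.6 else 0
        if recovered:
            # drop below grade 2 at a follow-up visit strictly after onset
            # and no later than 18 months
            candidates = [i for i in range(max(onset + 1, 3), n)]
            probs = np.array([0.4, 0.3, 0.2, 0.1][-len(candidates):], dtype=float)
            rec_visit = int(rng.choice(candidates, p=probs / probs.sum()))
            for i in range(onset, rec_visit):
                grades[i] = peak if i == onset else 2
            for i in range(rec_visit, n):
                grades[i] = 1 if i < rec_visit + 2 else 0
        else:
            for i in range(onset, n):
                grades[i] = peak if i == onset else 2
    return AssessmentTimeline(
        patient_id, list(zip(VISIT_SCHEDULE, grades))
    )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_patient(
    config: CohortConfig, index: int, keep_volumes: bool = True
) -> SyntheticPatient:
    """Generate one fully reproducible patient (anatomy, dose, outcome)."""
    pid = f"SYN{index:04d}"
    structures = generate_anatomy(config, index)
    dose = generate_dose(structures, config, index)
    subvols = anatomy.derive_subvolumes(structures)
    feats = extract_dose_features(subvols, dose)
    volumes = _group_volumes(subvols)

    rng_clin = _patient_rng(config.seed, index, 4)
    clinical = _draw_clinical(rng_clin, config.clinical_mix, volumes)
    from .dosimetry import encode_clinical

    enc = encode_clinical(clinical)
    rng_out = _patient_rng(config.seed, index, 3)
    scale = config.dose_feature_scale_cgy

    def logit_for(outcome: str, intercept: float) -> float:
        eta = intercept
        for feat, w in config.effects.get(outcome, {}).items():
            eta += w * feats[feat] / scale
        for col, w in config.clinical_effects.items():
            eta += w * enc[col]
        return eta

    injured = int(rng_out.random() < _logistic(logit_for("injury", config.injury_intercept)))
    recovered: int | None = None
    if injured:
        recovered = int(
            rng_out.random() < _logistic(logit_for("recovery", config.recovery_intercept))
        )
    timeline = _make_timeline(pid, bool(injured),
                              None if recovered is None else bool(recovered), rng_out)
    labels = derive_outcomes(timeline)
    assert labels is not None and labels.injury == injured and labels.recovery == recovered

    return SyntheticPatient(
        patient_id=pid,
        structure_set=structures if keep_volumes else None,
        dose=dose if keep_volumes else None,
        clinical=clinical,
        timeline=timeline,
        latent_injury=injured,
        latent_recovery=recovered,
        dose_features=feats,
        subvolumes=subvols if keep_volumes else None,
    )


def generate_cohort(
    config: CohortConfig, keep_volumes: bool = True
) -> list[SyntheticPatient]:
    """Generate the full cohort; bit-identical for identical config+seed."""
    return [
        generate_patient(config, i, keep_volumes=keep_volumes)
        for i in range(config.n_patients)
    ]


def cohort_design_matrix(patients: list[SyntheticPatient]):
    """Assemble the 214-predictor design matrix for a synthetic cohort."""
    from .dosimetry import build_design_matrix

    return build_design_matrix(
        [p.patient_id for p in patients],
        [p.dose_features for p in patients],
        [p.clinical for p in patients],
        [p.latent_injury for p in patients],
        [p.latent_recovery for p in patients],
    )
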