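"""Synthetic DCE-MRI cohorts with known kinetic and survival ground truth.

Each simulated patient carries an ellipsoidal tumor embedded in a
parenchyma ellipsoid on a fat-suppressed background.  Voxelwise kinetics are
drawn per tissue class:

- fat: baseline near the noise floor, negligible enhancement;
- parenchyma: moderate uptake (PE ~ 35%), persistent enhancement (SER < 1);
- tumor: a two-component mixture per patient — a *background* enhancing
  component (high PE, SER below 1) and a *washout* component (PE and SER
  centered above the true thresholds) occupying a patient-specific fraction
  of the tumor.

Post-contrast volumes invert the map definitions: ``s_early = s0(1+PE/100)``
and ``s_late = s0(1+(PE/SER)/100)``, so the enhancement module recovers the
drawn kinetics exactly when noise is switched off.

Tumors shrink across visits via per-patient residual volume fractions, and
the early-treatment visit is missing at random for a subset of patients, as
in real neoadjuvant cohorts.

Survival ground truth: event times are exponential with hazard
``h0 * exp(true_beta * z / scale)`` where ``z`` is the chosen FTV predictor
evaluated *at the true threshold pair only*, computed from the simulated
images through the actual pipeline.  Thresholds away from the true pair see
progressively noisier versions of ``z`` (patient-level kinetic means vary,
so threshold survivor fractions vary between patients), which is what makes
"the sweep should find the true cell" a falsifiable property.  Censoring is
the minimum of an administrative horizon and exponential dropout.

All randomness flows through one :class:`numpy.random.Generator`; identical
seeds give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .enhancement import DCEStudy, compute_enhancement_maps
from .ftv import (
    DEFAULT_MIN_CLUSTER_VOXELS,
    FTVSurface,
    PredictorRecord,
    ThresholdGrid,
    build_predictors,
    default_grid,
    ftv_surface,
)
from .survival import DEFAULT_SCALES, SurvivalRecord
from .voi import ProjectionROI, VOISpec

__all__ = [
    "SimConfig",
    "PatientTruth",
    "Cohort",
    "draw_patients",
    "simulate_study",
    "simulate_survival",
    "simulate_cohort",
    "write_cohort",
]

_SUBTYPE_SER_SHIFT = {"HRpos_HER2neg": -0.08, "HER2pos": 0.08, "TN": 0.04, "unknown": 0.0}
_SUBTYPE_PE_SHIFT = {"HRpos_HER2neg": -8.0, "HER2pos": 10.0, "TN": 5.0, "unknown": 0.0}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the modeled study: 64 patients with a 21/15/11/17 split
    of HR+/HER2-, HER2+, TN and unknown subtypes, three visits with ~20%
    of early-treatment exams missing, 0.7 x 0.94 x 2.0 mm voxels, and a
    hazard that depends log-linearly on the final functional tumor volume
    evaluated at the true threshold pair (PE* = 100%, SER* = 1.0).
    Simulated volumes are 32 x 32 x 16 voxels — large enough for hundreds of
    tumor voxels at study voxel size while keeping cohort-scale simulation
    cheap.
    """

    n_patients: int = 64
    subtype_mix: tuple[tuple[str, float], ...] = (
        ("HRpos_HER2neg", 21 / 64),
        ("HER2pos", 15 / 64),
        ("TN", 11 / 64),
        ("unknown", 17 / 64),
    )
    volume_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (0.7, 0.94, 2.0)

    # tumor geometry (mm)
    tumor_radius_mm: tuple[float, float] = (7.0, 11.0)  # uniform range, base radius
    tumor_radius_anisotropy: tuple[float, float] = (0.8, 1.2)
    tumor_center_jitter_mm: float = 3.0
    parenchyma_radius_fraction: float = 0.42  # of the half field of view
    voi_margin_voxels: int = 3

    # baseline signal (arbitrary scanner units)
    s0_fat: float = 60.0
    s0_parenchyma: float = 260.0
    s0_tumor: float = 350.0
    s0_noise_sd: float = 8.0

    # voxelwise kinetics: (mean, sd)
    fat_pe: tuple[float, float] = (3.0, 4.0)
    parenchyma_pe: tuple[float, float] = (35.0, 15.0)
    parenchyma_ser: tuple[float, float] = (0.70, 0.15)
    # tumor kinetics: (population mean, between-patient sd, within-patient sd)
    tumor_bg_pe: tuple[float, float, float] = (140.0, 20.0, 15.0)
    tumor_bg_ser: tuple[float, float, float] = (0.65, 0.12, 0.10)
    tumor_washout_pe: tuple[float, float, float] = (118.0, 25.0, 10.0)
    tumor_washout_ser: tuple[float, float, float] = (1.35, 0.20, 0.10)
    washout_fraction_range: tuple[float, float] = (0.05, 0.95)

    # response model: residual tumor volume fractions (1 = no response)
    mri2_residual_range: tuple[float, float] = (0.3, 1.0)
    mrif_residual_range: tuple[float, float] = (0.0, 0.9)
    missing_mri2_rate: float = 0.2

    # survival ground truth
    true_pe_t: float = 100.0
    true_ser_t: float = 1.0
    true_beta: float = 0.5
    active_predictor: str = "ftv_f"
    predictor_scale: float | None = 0.25  # cc per hazard unit for ftv_f
    baseline_hazard: float = 0.004  # events per month at z = 0
    admin_censor_months: float = 96.0
    dropout_rate: float = 0.003  # per month

    # pipeline settings used when deriving z from the images
    s0_floor: float | None = None
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [p for _, p in self.subtype_mix]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("subtype_mix probabilities must be non-negative and sum to 1")
        if self.tumor_radius_mm[0] <= 0:
            raise ValueError("tumor radii must be positive")
        for lo, hi in (self.mri2_residual_range, self.mrif_residual_range):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("residual-volume fractions must lie in [0, 1]")
        if self.active_predictor not in DEFAULT_SCALES:
            raise ValueError(f"unknown active_predictor {self.active_predictor!r}")

    @property
    def scale(self) -> float:
        return (
            self.predictor_scale
            if self.predictor_scale is not None
            else DEFAULT_SCALES[self.active_predictor]
        )

    def noise_free(self, pe: float = 150.0, ser: float = 1.5) -> "SimConfig":
        """Copy with all noise off and tumor kinetics pinned to (pe, ser)."""
        return replace(
            self,
            subtype_mix=(("unknown", 1.0),),  # no subtype kinetic shifts
            s0_noise_sd=0.0,
            fat_pe=(0.0, 0.0),
            parenchyma_pe=(30.0, 0.0),
            parenchyma_ser=(0.7, 0.0),
            tumor_bg_pe=(pe, 0.0, 0.0),
            tumor_bg_ser=(ser, 0.0, 0.0),
            tumor_washout_pe=(pe, 0.0, 0.0),
            tumor_washout_ser=(ser, 0.0, 0.0),
            washout_fraction_range=(0.5, 0.5),
        )


@dataclass(frozen=True)
class PatientTruth:
    """Per-patient latent parameters, fixed across visits."""

    patient_id: str
    subtype: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    washout_fraction: float
    bg_pe_mean: float
    bg_ser_mean: float
    washout_pe_mean: float
    washout_ser_mean: float
    mri2_residual: float
    mrif_residual: float
    missing_mri2: bool


@dataclass
class Cohort:
    """A fully simulated cohort: predictors, survival, and ground truth."""

    config: SimConfig
    patients: list[PatientTruth]
    predictors: list[PredictorRecord]
    survival: list[SurvivalRecord]
    z: np.ndarray  # active predictor at the true cell, per patient
    grid: ThresholdGrid
    surfaces: dict[str, dict[str, FTVSurface]] = field(default_factory=dict)


def draw_patients(cfg: SimConfig, rng: np.random.Generator) -> list[PatientTruth]:
    labels = [s for s, _ in cfg.subtype_mix]
    probs = [p for _, p in cfg.subtype_mix]
    extent = np.array(cfg.volume_shape) * np.array(cfg.voxel_size_mm)
    patients = []
    for k in range(cfg.n_patients):
        subtype = labels[rng.choice(len(labels), p=probs)]
        base_r = rng.uniform(*cfg.tumor_radius_mm)
        radii = base_r * rng.uniform(*cfg.tumor_radius_anisotropy, size=3)
        center = extent / 2 + rng.uniform(
            -cfg.tumor_center_jitter_mm, cfg.tumor_center_jitter_mm, size=3
        )
        patients.append(
            PatientTruth(
                patient_id=f"P{k:03d}",
                subtype=subtype,
                center_mm=tuple(center),
                radii_mm=tuple(radii),
                washout_fraction=rng.uniform(*cfg.washout_fraction_range),
                bg_pe_mean=rng.normal(cfg.tumor_bg_pe[0] + _SUBTYPE_PE_SHIFT[subtype],
                                      cfg.tumor_bg_pe[1]),
                bg_ser_mean=rng.normal(cfg.tumor_bg_ser[0] + _SUBTYPE_SER_SHIFT[subtype],
                                       cfg.tumor_bg_ser[1]),
                washout_pe_mean=rng.normal(cfg.tumor_washout_pe[0] + _SUBTYPE_PE_SHIFT[subtype],
                                           cfg.tumor_washout_pe[1]),
                washout_ser_mean=rng.normal(cfg.tumor_washout_ser[0] + _SUBTYPE_SER_SHIFT[subtype],
                                            cfg.tumor_washout_ser[1]),
                mri2_residual=rng.uniform(*cfg.mri2_residual_range),
                mrif_residual=rng.uniform(*cfg.mrif_residual_range),
                missing_mri2=bool(rng.random() < cfg.missing_mri2_rate),
            )
        )
    return patients


def _ellipsoid_mask(
    shape: Sequence[int],
    voxel_size: Sequence[float],
    center_mm: Sequence[float],
    radii_mm: Sequence[float],
) -> np.ndarray:
    if min(radii_mm) <= 0:
        return np.zeros(tuple(shape), dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(tuple(shape), dtype=np.float64)
    for g, d, c, r in zip(grids, voxel_size, center_mm, radii_mm):
        acc = acc + (((g + 0.5) * d - c) / r) ** 2
    return acc <= 1.0


def _visit_residual(patient: PatientTruth, visit: str) -> float:
    return {"MRI_1": 1.0, "MRI_2": patient.mri2_residual, "MRI_f": patient.mrif_residual}[visit]


def simulate_study(
    cfg: SimConfig, patient: PatientTruth, visit: str, rng: np.random.Generator
) -> DCEStudy:
    """Simulate one visit's three-timepoint series for one patient.

    The tumor ellipsoid's radii are scaled by the cube root of the visit's
    residual volume fraction, so residual fraction 0 gives an empty tumor.
    """
    shape = cfg.volume_shape
    extent = np.array(shape) * np.array(cfg.voxel_size_mm)
    residual = _visit_residual(patient, visit)
    radii = np.array(patient.radii_mm) * residual ** (1 / 3)
    tumor = _ellipsoid_mask(shape, cfg.voxel_size_mm, patient.center_mm, radii)
    paren = _ellipsoid_mask(
        shape, cfg.voxel_size_mm, extent / 2, cfg.parenchyma_radius_fraction * extent
    )
    paren &= ~tumor

    s0 = np.full(shape, cfg.s0_fat)
    s0[paren] = cfg.s0_parenchyma
    s0[tumor] = cfg.s0_tumor
    if cfg.s0_noise_sd > 0:
        s0 = s0 + rng.normal(0.0, cfg.s0_noise_sd, size=shape)
    s0 = np.maximum(s0, 1.0)

    if cfg.fat_pe[1] > 0:
        pe = rng.normal(cfg.fat_pe[0], cfg.fat_pe[1], size=shape)
    else:
        pe = np.full(shape, float(cfg.fat_pe[0]))
    ser = np.ones(shape)

    n_paren = int(paren.sum())
    if n_paren:
        pe[paren] = _draw(rng, cfg.parenchyma_pe[0], cfg.parenchyma_pe[1], n_paren)
        ser[paren] = np.clip(
            _draw(rng, cfg.parenchyma_ser[0], cfg.parenchyma_ser[1], n_paren), 0.2, 3.5
        )

    n_tumor = int(tumor.sum())
    if n_tumor:
        in_washout = rng.random(n_tumor) < patient.washout_fraction
        pe_t = np.where(
            in_washout,
            _draw(rng, patient.washout_pe_mean, cfg.tumor_washout_pe[2], n_tumor),
            _draw(rng, patient.bg_pe_mean, cfg.tumor_bg_pe[2], n_tumor),
        )
        ser_t = np.where(
            in_washout,
            _draw(rng, patient.washout_ser_mean, cfg.tumor_washout_ser[2], n_tumor),
            _draw(rng, patient.bg_ser_mean, cfg.tumor_bg_ser[2], n_tumor),
        )
        pe[tumor] = pe_t
        ser[tumor] = np.clip(ser_t, 0.2, 3.5)

    s_early = s0 * (1.0 + pe / 100.0)
    s_late = s0 * (1.0 + pe / ser / 100.0)
    return DCEStudy(
        patient_id=patient.patient_id,
        visit=visit,
        s0=s0,
        s_early=s_early,
        s_late=s_late,
        voxel_size_mm=cfg.voxel_size_mm,
    )


def _draw(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd <= 0:
        return np.full(n, mean)
    return rng.normal(mean, sd, size=n)


def default_voi_spec(cfg: SimConfig, patient: PatientTruth) -> VOISpec:
    """Tight box VOI around the baseline tumor extent plus a margin.

    Mirrors a reader placing two orthogonal rectangles around the lesion on
    MIP images; the same VOI is reused for every visit.
    """
    shape = cfg.volume_shape
    vox = np.array(cfg.voxel_size_mm)
    lo = (np.array(patient.center_mm) - np.array(patient.radii_mm)) / vox
    hi = (np.array(patient.center_mm) + np.array(patient.radii_mm)) / vox
    m = cfg.voi_margin_voxels
    lo = np.maximum(np.floor(lo).astype(int) - m, 0)
    hi = np.minimum(np.ceil(hi).astype(int) + m, np.array(shape))
    # axis-0 projection constrains axes (1, 2); axis-1 projection constrains (0, 2)
    roi_a = ProjectionROI(axis=0, rect=((int(lo[1]), int(hi[1])), (int(lo[2]), int(hi[2]))))
    roi_b = ProjectionROI(axis=1, rect=((int(lo[0]), int(hi[0])), (int(lo[2]), int(hi[2]))))
    return VOISpec(roi_a=roi_a, roi_b=roi_b)


def simulate_survival(
    z: Sequence[float] | np.ndarray,
    patients: Sequence[PatientTruth],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Draw RFS times with hazard ``h0 * exp(true_beta * z / scale)``.

    Censoring is the earlier of the administrative horizon and an
    exponential dropout time; the event flag records which came first.
    """
    if cfg.baseline_hazard <= 0:
        raise ValueError(f"baseline hazard must be positive, got {cfg.baseline_hazard}")
    z = np.asarray(z, dtype=np.float64)
    if len(z) != len(patients):
        raise ValueError("one predictor value per patient required")
    if not np.all(np.isfinite(z)):
        raise ValueError("predictor values must be non-missing for all simulated patients")
    rates = cfg.baseline_hazard * np.exp(cfg.true_beta * z / cfg.scale)
    t_event = rng.exponential(1.0 / rates)
    if cfg.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / cfg.dropout_rate, size=len(z))
    else:
        t_drop = np.full(len(z), np.inf)
    t_cens = np.minimum(t_drop, cfg.admin_censor_months)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return [
        SurvivalRecord(
            patient_id=p.patient_id,
            rfs_months=float(max(t, 1e-6)),
            event=bool(e),
            subtype=p.subtype,
        )
        for p, t, e in zip(patients, time, event)
    ]


def _patient_visits(cfg: SimConfig, patient: PatientTruth) -> list[str]:
    visits = ["MRI_1", "MRI_f"]
    if not patient.missing_mri2:
        visits.insert(1, "MRI_2")
    return visits


def simulate_cohort(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    grid: ThresholdGrid | None = None,
    keep_surfaces: bool = False,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a cohort end to end: images -> surfaces -> predictors -> RFS.

    The survival ground truth is tied to the *pipeline-computed* predictor at
    the true threshold cell, so re-running the pipeline on the cohort
    reproduces exactly the covariate the hazard was built from.  With
    ``out_dir`` set, images, VOI specs, the clinical table and a ground-truth
    JSON are also written to disk in the formats the pipeline reads.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if grid is None:
        grid = default_grid()
    i_true, j_true = grid.index_of(cfg.true_pe_t, cfg.true_ser_t)

    patients = draw_patients(cfg, rng)
    predictors: list[PredictorRecord] = []
    all_surfaces: dict[str, dict[str, FTVSurface]] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)
        (out_path / "voi").mkdir(parents=True, exist_ok=True)

    from .voi import voi_mask  # local import to avoid cycle at module load

    for patient in patients:
        spec = default_voi_spec(cfg, patient)
        voi = voi_mask(spec, cfg.volume_shape)
        surfaces: dict[str, FTVSurface] = {}
        for visit in _patient_visits(cfg, patient):
            study = simulate_study(cfg, patient, visit, rng)
            maps = compute_enhancement_maps(study, s0_floor=cfg.s0_floor)
            surfaces[visit] = ftv_surface(
                study, maps, voi, grid, cfg.min_cluster_voxels, cfg.connectivity
            )
            if out_path is not None:
                from .io import save_study

                save_study(study, out_path / "images" / f"{patient.patient_id}_{visit}.nii.gz")
        if out_path is not None:
            from .io import save_voi_spec

            save_voi_spec(spec, out_path / "voi" / f"{patient.patient_id}.json")
        predictors.append(build_predictors(surfaces, subtype=patient.subtype))
        if keep_surfaces:
            all_surfaces[patient.patient_id] = surfaces

    z = np.array([p.values(cfg.active_predictor)[i_true, j_true] for p in predictors])
    if not np.all(np.isfinite(z)):
        # percent-change predictors can be undefined (zero baseline FTV at the
        # true cell); treat absent disease burden signal as z = 0
        z = np.nan_to_num(z, nan=0.0)
    survival = simulate_survival(z, patients, cfg, rng)

    cohort = Cohort(
        config=cfg, patients=patients, predictors=predictors, survival=survival,
        z=z, grid=grid, surfaces=all_surfaces,
    )
    if out_path is not None:
        write_cohort_tables(cohort, out_path)
    return cohort


def write_cohort_tables(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the clinical table and ground-truth JSON beside the images."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient, surv in zip(cohort.patients, cohort.survival):
        row = {
            "patient_id": patient.patient_id,
            "subtype": patient.subtype,
            "rfs_months": surv.rfs_months,
            "event": int(surv.event),
        }
        for visit in ("MRI_1", "MRI_2", "MRI_f"):
            present = visit in _patient_visits(cohort.config, patient)
            row[f"{visit.lower()}_file"] = (
                f"images/{patient.patient_id}_{visit}.nii.gz" if present else ""
            )
        row["voi_file"] = f"voi/{patient.patient_id}.json"
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "clinical.csv", index=False)

    truth = {
        "true_pe_t": cohort.config.true_pe_t,
        "true_ser_t": cohort.config.true_ser_t,
        "true_beta": cohort.config.true_beta,
        "active_predictor": cohort.config.active_predictor,
        "predictor_scale": cohort.config.scale,
        "z": {p.patient_id: float(v) for p, v in zip(cohort.patients, cohort.z)},
        "config": {
            k: v for k, v in asdict(cohort.config).items() if not isinstance(v, np.ndarray)
        },
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str))


def write_cohort(cfg: SimConfig, out_dir: str | Path) -> Cohort:
    """Simulate a cohort and write images + tables under ``out_dir``."""
    return simulate_cohort(cfg, out_dir=out_dir)
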