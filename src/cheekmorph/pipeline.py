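"""End-to-end orchestration: registration → ROI volumetrics → cheek metric →
cohort statistics.

``measure_patient`` runs one pre/post model pair through the full chain and
returns every intermediate scalar; ``run_cohort`` aggregates patient
measurements (excluding registration-QC failures) into the four report
tables of the analysis — descriptive movements, soft/bone ratios, prediction
models with multiple correlations, and the stratified normative comparison —
plus a QC block and scatter data of observed vs fitted soft movement.
``run_synthetic_cohort`` drives the same chain over generated phantoms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import cohortstats
from .anatomy import (LandmarkSet, build_reference_frame, construct_planes,
                      maxillary_rotation_angle)
from .cheekmetric import (NORM_MEAN_MM, NORM_N, NORM_SD_MM, CheekMassResult,
                          cheek_mass_position)
from .errors import CheekmorphError
from .phantom import (CohortSpec, Phantom, SurgeryParams, apply_surgery,
                      make_phantom, sample_cohort)
from .registration import (RegistrationResult, landmark_initialize,
                           qc_registration, registration_mask, rigid_icp)
from .volumetrics import (DEFAULT_GRID_MM, RegionMeasurement, measure_region,
                          rotation_change, stratify_advancement)


@dataclass(frozen=True)
class RunConfig:
    """Numerical settings of the measurement pipeline."""

    icp_max_iter: int = 100
    icp_tol_mm: float = 1e-4
    icp_max_points: int = 2000
    qc_rms_threshold_mm: float = 0.5
    grid_mm: float = DEFAULT_GRID_MM
    fh_margin_mm: float = 3.0
    landmark_radius_mm: float = 15.0
    norm_mean: float = NORM_MEAN_MM
    norm_sd: float = NORM_SD_MM
    norm_n: int = NORM_N
    include_intercept: bool = False

    def __post_init__(self):
        if self.grid_mm <= 0:
            raise ValueError("grid_mm must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class PatientMeasurement:
    """Every scalar the pipeline produces for one patient."""

    patient: str
    rms_deviation: float
    qc_pass: bool
    registration: RegistrationResult
    rotation_pre: float
    rotation_post: float
    rotation_change: float
    bone: Dict[str, RegionMeasurement]          # keyed by side
    soft: Dict[str, RegionMeasurement]
    cheek_pre: Dict[str, CheekMassResult]
    cheek_post: Dict[str, CheekMassResult]
    stratum: Dict[str, str]
    failed_stage: Optional[str] = None

    def records(self) -> List[Dict]:
        """Tidy per-(patient, side) rows for the cohort table."""
        rows = []
        for side in ("L", "R"):
            rows.append({
                "patient": self.patient, "side": side,
                "soft_movement": self.soft[side].movement,
                "bone_advancement": self.bone[side].movement,
                "rotation": self.rotation_change,
                "cheek_mass_position": self.cheek_post[side].position,
                "stratum": self.stratum[side],
                "rms_deviation": self.rms_deviation,
                "qc_pass": self.qc_pass,
            })
        return rows


def measure_patient(patient: str,
                    pre_bone: trimesh.Trimesh, pre_soft: trimesh.Trimesh,
                    post_bone: trimesh.Trimesh, post_soft: trimesh.Trimesh,
                    pre_lm: LandmarkSet, post_lm: LandmarkSet,
                    config: Optional[RunConfig] = None) -> PatientMeasurement:
    """Register, clip, subtract and measure one patient.

    The post-operative bone model is aligned to the pre-operative one over
    the non-operated mask; the recovered transform is applied to both
    post-operative models and landmarks.  All measurements are then taken in
    the pre-operative anatomical frame.
    """
    config = config or RunConfig()
    frame = build_reference_frame(pre_lm)
    planes = construct_planes(frame, pre_lm)

    post_frame = build_reference_frame(post_lm)
    post_planes = construct_planes(post_frame, post_lm)
    mask = registration_mask(post_bone, post_planes["FH"], post_lm,
                             fh_margin_mm=config.fh_margin_mm,
                             landmark_radius_mm=config.landmark_radius_mm)
    init = landmark_initialize(post_lm, pre_lm)
    reg = rigid_icp(post_bone, pre_bone, mask=mask, initial=init,
                    max_iter=config.icp_max_iter, tol_mm=config.icp_tol_mm,
                    max_points=config.icp_max_points)
    qc = qc_registration(reg, config.qc_rms_threshold_mm)

    post_bone_r = reg.apply_mesh(post_bone)
    post_soft_r = reg.apply_mesh(post_soft)
    post_lm_r = reg.apply_landmarks(post_lm)

    rot_pre = maxillary_rotation_angle(frame, pre_lm)
    rot_post = maxillary_rotation_angle(frame, post_lm_r)
    d_rot = rotation_change(rot_pre, rot_post)

    bone: Dict[str, RegionMeasurement] = {}
    soft: Dict[str, RegionMeasurement] = {}
    cheek_pre: Dict[str, CheekMassResult] = {}
    cheek_post: Dict[str, CheekMassResult] = {}
    stratum: Dict[str, str] = {}
    for side in ("L", "R"):
        bone[side] = measure_region(pre_bone, post_bone_r, planes, frame, side,
                                    "bone", grid_mm=config.grid_mm,
                                    rotation_delta=d_rot)
        soft[side] = measure_region(pre_soft, post_soft_r, planes, frame, side,
                                    "soft", grid_mm=config.grid_mm,
                                    rotation_delta=d_rot)
        cheek_pre[side] = cheek_mass_position(pre_soft, frame, pre_lm, side,
                                              planes=planes)
        cheek_post[side] = cheek_mass_position(post_soft_r, frame, pre_lm, side,
                                               planes=planes)
        stratum[side] = stratify_advancement(max(bone[side].movement, 0.0))

    return PatientMeasurement(
        patient=patient, rms_deviation=reg.rms_deviation, qc_pass=qc,
        registration=reg, rotation_pre=rot_pre, rotation_post=rot_post,
        rotation_change=d_rot, bone=bone, soft=soft,
        cheek_pre=cheek_pre, cheek_post=cheek_post, stratum=stratum)


def cohort_table(measurements: Sequence[PatientMeasurement],
                 include_qc_failures: bool = False) -> pd.DataFrame:
    rows: List[Dict] = []
    for m in measurements:
        if m.failed_stage is not None:
            continue
        if not m.qc_pass and not include_qc_failures:
            continue
        rows.extend(m.records())
    return pd.DataFrame(rows)


@dataclass
class CohortReport:
    """Aggregated cohort results in the shape of the four report tables."""

    table: pd.DataFrame
    descriptives: pd.DataFrame
    ratios: pd.DataFrame
    models: Dict[str, cohortstats.PredictionModel]
    norm_comparison: pd.DataFrame
    qc: Dict[str, float]
    scatter: pd.DataFrame
    side_p_values: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        models = {k: {**dataclasses.asdict(v),
                      "multiple_r": cohortstats.multiple_correlation(v)}
                  for k, v in self.models.items()}
        return {
            "descriptives": self.descriptives.to_dict(orient="records"),
            "ratios": self.ratios.reset_index(names="region")
                          .to_dict(orient="records"),
            "models": models,
            "norm_comparison": self.norm_comparison.to_dict(orient="records"),
            "qc": self.qc,
            "side_p_values": self.side_p_values,
            "scatter": self.scatter.to_dict(orient="records"),
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True,
                                   default=float))
        return path


def run_cohort(measurements: Sequence[PatientMeasurement],
               config: Optional[RunConfig] = None) -> CohortReport:
    """Aggregate per-patient measurements into the cohort report."""
    config = config or RunConfig()
    usable = [m for m in measurements
              if m.failed_stage is None and m.qc_pass]
    if len(usable) < 2:
        raise CheekmorphError("fewer than 2 patients passed QC")
    table = cohort_table(measurements)

    models = {}
    for region in ("Right", "Left", "Total"):
        models[region] = cohortstats.fit_prediction_model(
            table, region=region, include_intercept=config.include_intercept)
    fitted = (models["Total"].b1 * table["bone_advancement"]
              + models["Total"].b2 * table["rotation"]
              + models["Total"].intercept)
    scatter = pd.DataFrame({
        "patient": table["patient"], "side": table["side"],
        "bone_advancement": table["bone_advancement"],
        "rotation": table["rotation"],
        "soft_movement": table["soft_movement"],
        "fitted_soft_movement": fitted,
    })
    rms = np.array([m.rms_deviation for m in measurements
                    if m.failed_stage is None])
    qc = {
        "n_patients": len(measurements),
        "n_passed": len(usable),
        "n_excluded": len(measurements) - len(usable),
        "rms_mean": float(rms.mean()),
        "rms_min": float(rms.min()),
        "rms_max": float(rms.max()),
        "rms_threshold": config.qc_rms_threshold_mm,
    }
    side_p = {}
    for var in ("soft_movement", "bone_advancement", "rotation"):
        try:
            _, side_p[var] = cohortstats.side_comparison(table, var)
        except ValueError:
            pass
    return CohortReport(
        table=table,
        descriptives=cohortstats.descriptive_by_side(table),
        ratios=cohortstats.soft_bone_ratio(table),
        models=models,
        norm_comparison=cohortstats.norm_comparison_table(
            table, norm_mean=config.norm_mean, norm_sd=config.norm_sd,
            norm_n=config.norm_n),
        qc=qc, scatter=scatter, side_p_values=side_p)


@dataclass
class SyntheticCohortResult:
    table: pd.DataFrame
    measurements: List[PatientMeasurement]
    truth: pd.DataFrame


def run_synthetic_cohort(spec: Optional[CohortSpec] = None,
                         config: Optional[RunConfig] = None,
                         pre: Optional[Phantom] = None
                         ) -> SyntheticCohortResult:
    """Mesh-mode cohort: full geometric pipeline over generated phantoms.

    One canonical pre-operative phantom is shared by all patients; each
    patient receives an individually drawn surgery (advancement, rotation,
    response noise, scan-pose offset) and is measured end to end.
    """
    spec = spec or CohortSpec()
    config = config or RunConfig()
    pre = pre or make_phantom(spec.phantom)
    draws = sample_cohort(spec)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(draws))
    a1, a2 = spec.coefficients
    measurements: List[PatientMeasurement] = []
    truth_rows: List[Dict] = []
    for draw, seed in zip(draws, seeds):
        rng = np.random.default_rng(seed)
        params = SurgeryParams(
            advancement=draw.advancement, rotation_deg=draw.rotation,
            a1=a1, a2=a2, noise_lr=draw.noise)
        post, record = apply_surgery(pre, params, rng=rng)
        m = measure_patient(draw.patient, pre.bone, pre.soft, post.bone,
                            post.soft, pre.landmarks, post.landmarks, config)
        measurements.append(m)
        for side, d, eps in (("L", draw.advancement[0], draw.noise[0]),
                             ("R", draw.advancement[1], draw.noise[1])):
            truth_rows.append({
                "patient": draw.patient, "side": side, "advancement": d,
                "rotation": draw.rotation,
                "soft_displacement": a1 * d + a2 * draw.rotation + eps,
            })
    table = cohort_table(measurements)
    return SyntheticCohortResult(table=table, measurements=measurements,
                                 truth=pd.DataFrame(truth_rows))
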