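"""End-to-end orchestration: per-patient simulation, cohort analysis,
threshold calibration, and the stem-position sweep.

The per-patient chain is geometry -> stem placement -> meshing -> loading ->
plane-stress solve -> SED -> stimulus -> Gruen-zone medians -> mechanostat
classes.  Every stage failure is re-raised with the stage name prefixed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .cohort import ObservedLabels, PatientRecord, generate_observed_labels
from .errors import FemremError, InsufficientDataError
from .fem import assemble, interface_band, solve, strain_energy_density
from .geometry import (
    Alignment,
    FemurGeometry,
    PlacedStem,
    StemType,
    ZoneMap,
    build_femur_contour,
    build_stem_contour,
    partition_gruen_zones,
    place_stem,
)
from .geometry import _STEM_DEFAULTS  # archetype defaults, templated per patient
from .loading import build_load_case, distal_fixed_nodes, nodal_forces
from .meshing import MaterialTable, Region, default_materials, triangulate
from .remodeling import (
    CalibrationResult,
    RemodelingClass,
    ThresholdPair,
    ZoneSummary,
    calibrate_upper_threshold,
    classification_accuracy,
    cortical_overload,
    lower_threshold_from_iqr,
    mechanical_stimulus,
    predict_zone_remodeling,
    zone_median_stimulus,
)
from .stats import TestResult, chi_square_independence, pairwise_mann_whitney

logger = logging.getLogger("femrem")

__all__ = [
    "SimulationSettings",
    "PatientResult",
    "CohortResult",
    "PositionSweepResult",
    "run_patient",
    "run_cohort",
    "position_sweep",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical knobs shared by every run in an analysis."""

    max_element_area: float = 2.0  # mm^2
    thickness: float = 10.0  # mm, plane-stress slab; main absolute-scale knob
    band_width: float = 3.0  # mm, bone-implant interface band
    joint_force_factor: float = 2.38
    abductor_mode: str = "equilibrium"
    thresholds: ThresholdPair = field(default_factory=ThresholdPair)
    literal_cancellous_density: bool = True  # use cancellous rho for all bone
    area_weighted_median: bool = True
    materials: MaterialTable = field(default_factory=default_materials)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "max_element_area": self.max_element_area,
                "thickness": self.thickness,
                "band_width": self.band_width,
                "joint_force_factor": self.joint_force_factor,
                "abductor_mode": self.abductor_mode,
                "thresholds": [self.thresholds.low, self.thresholds.high],
                "literal_cancellous_density": self.literal_cancellous_density,
                "area_weighted_median": self.area_weighted_median,
                "materials": {
                    name: vars(getattr(self.materials, name))
                    for name in ("cortical", "cancellous", "implant")
                },
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PatientResult:
    record: PatientRecord
    zone_medians: dict[int, float]  # J/kg
    zone_summaries: list[ZoneSummary]
    overload_fraction: float
    max_cortical_stimulus: float
    elements: pd.DataFrame  # per-element table
    femur: FemurGeometry
    placed_stem: PlacedStem
    zone_map: ZoneMap
    mesh: "object"
    displacement: np.ndarray  # (n_nodes, 2)
    solve_residual: float
    config_hash: str
    version: str

    @property
    def predicted(self) -> dict[int, RemodelingClass]:
        return {z.zone_id: z.predicted for z in self.zone_summaries}


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FemremError as exc:
                raise type(exc)(f"[{name}] {exc}") from exc

        return wrapper

    return deco


def run_patient(
    record: PatientRecord, settings: SimulationSettings | None = None
) -> PatientResult:
    """Run the full per-patient chain; deterministic in (record, settings)."""
    s = settings or SimulationSettings()
    t0 = time.perf_counter()

    femur = _stage("geometry")(build_femur_contour)(record.geometry_params)
    stem_params = replace(
        _STEM_DEFAULTS[record.stem_type], neck_angle=record.geometry_params.ccd_angle
    )
    stem = _stage("stem")(build_stem_contour)(record.stem_type, stem_params)
    placed = _stage("placement")(place_stem)(femur, stem, record.alignment_angle)
    zone_map = _stage("zones")(partition_gruen_zones)(femur, placed)
    mesh = _stage("meshing")(triangulate)(femur, placed, s.max_element_area)

    load_case = _stage("loading")(build_load_case)(
        record.body_weight,
        femur,
        record.pauwels_angle,
        joint_force_factor=s.joint_force_factor,
        abductor_mode=s.abductor_mode,
    )
    # the joint contact force is carried by the prosthetic neck: attach it to
    # the implant elements nearest the head centre
    forces = nodal_forces(mesh, load_case.loads, region_preference={"joint": Region.IMPLANT})
    fixed = distal_fixed_nodes(mesh)
    system = _stage("assembly")(assemble)(mesh, s.materials, s.thickness)
    disp = _stage("solve")(solve)(system, forces, fixed)
    sed_field = _stage("sed")(strain_energy_density)(mesh, s.materials, disp)

    band = interface_band(mesh, placed, s.band_width)
    stimuli = _stimulus_field(sed_field.sed, mesh.region, s)
    zone_ids = _assign_zones(mesh, zone_map)

    band_zoned = band & (zone_ids > 0)
    medians = _stage("zone medians")(zone_median_stimulus)(
        stimuli[band_zoned],
        mesh.areas[band_zoned],
        zone_ids[band_zoned],
        weighted=s.area_weighted_median,
    )
    summaries = predict_zone_remodeling(medians, s.thresholds)
    frac, smax = cortical_overload(stimuli, mesh.areas, mesh.region, band, s.thresholds.high)

    elements = pd.DataFrame(
        {
            "cx": mesh.centroids[:, 0],
            "cy": mesh.centroids[:, 1],
            "area": mesh.areas,
            "region": [r.name for r in mesh.region],
            "sed_mpa": sed_field.sed,
            "stimulus_j_per_kg": stimuli,
            "in_band": band,
            "zone": zone_ids,
        }
    )
    logger.info(
        "patient %s: %d elements, residual %.2e, %.2f s",
        record.patient_id,
        mesh.n_elements,
        disp.residual,
        time.perf_counter() - t0,
    )
    return PatientResult(
        record=record,
        zone_medians=medians,
        zone_summaries=summaries,
        overload_fraction=frac,
        max_cortical_stimulus=smax,
        elements=elements,
        femur=femur,
        placed_stem=placed,
        zone_map=zone_map,
        mesh=mesh,
        displacement=disp.values,
        solve_residual=disp.residual,
        config_hash=s.config_hash(),
        version=__version__,
    )


def _stimulus_field(sed, region, s: SimulationSettings) -> np.ndarray:
    """SED -> stimulus per element; implant elements get 0."""
    rho_cancellous = s.materials.cancellous.density
    out = np.zeros(len(sed))
    for reg in (Region.CORTICAL, Region.CANCELLOUS):
        mask = region == reg
        if not mask.any():
            continue
        rho = (
            rho_cancellous
            if s.literal_cancellous_density
            else s.materials.for_region(reg).density
        )
        out[mask] = mechanical_stimulus(sed[mask], rho)
    return out


def _assign_zones(mesh, zone_map: ZoneMap) -> np.ndarray:
    """Zone id per element centroid (0 = unzoned or implant)."""
    cents = mesh.centroids
    out = np.zeros(mesh.n_elements, dtype=int)
    pts = shapely.points(cents)
    for zid in range(1, 8):
        geom = zone_map.zones[zid]
        if geom.is_empty:
            continue
        shapely.prepare(geom)
        hit = shapely.contains(geom, pts) | shapely.touches(geom, pts)
        out[(out == 0) & hit] = zid
    return out


@dataclass(frozen=True)
class CohortResult:
    patients: list[PatientResult]
    observed: dict[str, ObservedLabels]  # patient_id -> labels
    pooled: pd.DataFrame  # one row per (patient, zone)
    t_low: float
    t_low_fallback: bool
    calibration: CalibrationResult
    accuracy: float
    mann_whitney: dict[tuple[str, str], TestResult]
    chi_square: TestResult | None
    chi_table: pd.DataFrame | None


def run_cohort(
    records: list[PatientRecord],
    settings: SimulationSettings | None = None,
    *,
    observed: dict[str, ObservedLabels] | None = None,
    true_thresholds: ThresholdPair | None = None,
    noise_rate: float = 0.0,
    label_seed: int = 0,
    calibration_grid: tuple[float, float, float] = (3.0, 25.0, 0.25),
    default_t_low: float = 2.0,
    t_low: float | None = None,
) -> CohortResult:
    """Simulate every patient, then calibrate thresholds against labels.

    Observed labels are either supplied per patient or synthesised from each
    patient's zone medians with ``true_thresholds`` (default: the settings'
    thresholds) and ``noise_rate`` class-uniform flips.
    """
    s = settings or SimulationSettings()
    results = [run_patient(rec, s) for rec in records]

    if observed is None:
        gen = true_thresholds or s.thresholds
        observed = {
            r.record.patient_id: generate_observed_labels(
                r.zone_medians, gen, noise_rate, seed=label_seed + i
            )
            for i, r in enumerate(results)
        }

    rows = []
    for r in results:
        obs = observed[r.record.patient_id]
        for z in r.zone_summaries:
            rows.append(
                {
                    "patient_id": r.record.patient_id,
                    "stem_type": r.record.stem_type.value,
                    "zone": z.zone_id,
                    "median_stimulus_j_per_kg": z.median_stimulus,
                    "predicted": z.predicted.value,
                    "observed": obs.labels[z.zone_id].value,
                }
            )
    pooled = pd.DataFrame(rows)

    fallback = False
    if t_low is None:
        resorption_stimuli = pooled.loc[
            pooled.observed == RemodelingClass.RESORPTION.value,
            "median_stimulus_j_per_kg",
        ].to_numpy()
        try:
            t_low = lower_threshold_from_iqr(resorption_stimuli)
        except InsufficientDataError:
            t_low = default_t_low
            fallback = True
    t_low = min(t_low, calibration_grid[0] - 1e-9)  # grid must start above T_low

    calibration = calibrate_upper_threshold(
        pooled.median_stimulus_j_per_kg.to_numpy(),
        [RemodelingClass(v) for v in pooled.observed],
        t_low=t_low,
        grid=calibration_grid,
    )
    thr = ThresholdPair(low=t_low, high=calibration.t_high_star)
    pred_cal = [
        _classify(m, thr) for m in pooled.median_stimulus_j_per_kg.to_numpy()
    ]
    accuracy = classification_accuracy(
        pred_cal, [RemodelingClass(v) for v in pooled.observed]
    )

    groups = {
        lab: pooled.loc[pooled.observed == lab, "median_stimulus_j_per_kg"].to_numpy()
        for lab in pooled.observed.unique()
    }
    mwu = pairwise_mann_whitney(groups)

    chi_table = pd.crosstab(pooled.stem_type, pooled.observed)
    chi = None
    if chi_table.shape[0] >= 2 and chi_table.shape[1] >= 2:
        chi = chi_square_independence(chi_table.to_numpy())

    return CohortResult(
        patients=results,
        observed=observed,
        pooled=pooled,
        t_low=t_low,
        t_low_fallback=fallback,
        calibration=calibration,
        accuracy=accuracy,
        mann_whitney=mwu,
        chi_square=chi,
        chi_table=chi_table,
    )


def _classify(m: float, thr: ThresholdPair) -> RemodelingClass:
    from .remodeling import classify_stimulus

    return classify_stimulus(m, thr)


@dataclass(frozen=True)
class PositionSweepResult:
    """3 stems x 3 alignments grid of overload diagnostics."""

    cells: pd.DataFrame  # stem_type, alignment, angle, max_cortical_stimulus, ...
    results: dict[tuple[str, str], PatientResult]


def position_sweep(
    record: PatientRecord,
    settings: SimulationSettings | None = None,
    *,
    malposition_angle: float = 5.0,
) -> PositionSweepResult:
    """Simulate every stem in varus/neutral/valgus for one patient geometry."""
    s = settings or SimulationSettings()
    rows = []
    results: dict[tuple[str, str], PatientResult] = {}
    for stem_type in sorted(StemType, key=lambda t: t.value):
        for alignment, angle in (
            (Alignment.VARUS, +malposition_angle),
            (Alignment.NEUTRAL, 0.0),
            (Alignment.VALGUS, -malposition_angle),
        ):
            rec = replace(record, stem_type=stem_type, alignment_angle=angle)
            res = run_patient(rec, s)
            results[(stem_type.value, alignment.value)] = res
            row = {
                "stem_type": stem_type.value,
                "alignment": alignment.value,
                "alignment_angle": angle,
                "max_cortical_stimulus": res.max_cortical_stimulus,
                "overload_fraction": res.overload_fraction,
            }
            for zid, med in res.zone_medians.items():
                row[f"zone{zid}_median"] = med
            rows.append(row)
    cells = pd.DataFrame(rows).sort_values(["stem_type", "alignment"]).reset_index(drop=True)
    return PositionSweepResult(cells=cells, results=results)
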