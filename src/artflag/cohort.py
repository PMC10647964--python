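"""Synthetic head-and-neck treatment courses for end-to-end testing.

No clinical dataset ships with this package, so this module generates
cohorts with the statistical structure the flagging protocols assume:
courses of 30-35 daily fractions, target prescriptions between 52.5 and
70 Gy, roughly ten ROIs per patient (up to three target categories plus
eight organs at risk), planned metrics that respect the clinical thresholds,
and per-fraction delivered metrics equal to plan/N plus gradual adverse
drift (coverage loss for targets, dose creep for OARs) and per-fraction
noise.

Two modes are provided:

* **metric mode** (default test path): per-fraction DVH-metric time series
  are synthesised directly, skipping geometry;
* **grid mode**: small voxel lattices with a spherical target, nested
  CTV/CTV+2mm/CTV+4mm masks and a conformal dose with peripheral fall-off,
  drifting laterally over the course — the substrate for margin-variant
  coverage experiments.

All randomness flows from a single cohort seed through per-patient derived
streams, so a cohort is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .accumulation import FractionDose, extrapolate_course_metrics
from .grids import DoseGrid, StructureMask
from .dvh import expand_margin
from .protocol import (
    DEFAULT_ORGAN_CLASSES,
    GREEN,
    ORANGE,
    RED,
    ProtocolConfig,
    flag_course,
)

TARGET_ROIS = ("PTV_T", "PTV_NL", "PTV_NR")
OAR_ROIS = tuple(DEFAULT_ORGAN_CLASSES)
#: metric kind evaluated for each OAR (matches the protocol criteria table)
OAR_METRIC = {
    "SpinalCord": "D2",
    "Brainstem": "D2",
    "Mandible": "D2",
    "Larynx": "D5",
    "Parotid_ipsi": "Dmean",
    "Parotid_contra": "Dmean",
    "OralCavity": "Dmean",
    "Constrictors_sup": "Dmean",
}
#: clinical threshold per OAR, used to place plausible planned values below it
OAR_THRESHOLD = {
    "SpinalCord": 48.0,
    "Brainstem": 60.0,
    "Parotid_ipsi": 30.0,
    "Parotid_contra": 26.0,
    "Larynx": 45.0,
    "OralCavity": 30.0,
    "Mandible": 70.0,
    "Constrictors_sup": 45.0,
}


@dataclass(frozen=True)
class DriftModel:
    """Adverse dosimetric drift for one ROI.

    ``trend`` is the linear worsening of the *per-fraction* metric in
    Gy/fraction (applied in the adverse direction for the organ class:
    coverage down for targets, dose up for OARs), starting at ``onset``
    (drawn uniformly in the first half of the course when None).
    ``noise_sd`` is the Gaussian per-fraction metric noise in Gy, emulating
    day-to-day registration/contouring variability; ``affected_probability``
    is the chance that a given patient exhibits the drift at all.
    """

    trend: float = 0.0
    noise_sd: float = 0.03
    onset: int | None = None
    affected_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.affected_probability <= 1:
            raise ValueError("affected_probability must be in [0, 1]")
        if self.onset is not None and self.onset < 1:
            raise ValueError(f"onset must be >= 1, got {self.onset}")


def default_drift_models() -> dict[str, DriftModel]:
    """Plausible defaults: adverse drift in a minority of ROIs (so roughly a
    third of patients drift in some target), per-fraction noise everywhere."""
    models: dict[str, DriftModel] = {}
    for roi in TARGET_ROIS:
        models[roi] = DriftModel(trend=0.02, noise_sd=0.03, affected_probability=0.15)
    for roi in OAR_ROIS:
        cls = DEFAULT_ORGAN_CLASSES[roi]
        trend = 0.015 if cls == "parallel" else 0.02
        models[roi] = DriftModel(trend=trend, noise_sd=0.03, affected_probability=0.15)
    return models


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters (defaults emulate the study size)."""

    n_patients: int = 38
    fractions_range: tuple[int, int] = (30, 35)
    prescription_range: tuple[float, float] = (52.5, 70.0)
    node_probability: float = 0.8
    planned_violation_rate: float = 0.0
    drift_models: Mapping[str, DriftModel] = field(default_factory=default_drift_models)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fractions_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid fractions_range {self.fractions_range}")
        plo, phi = self.prescription_range
        if not (0 < plo <= phi):
            raise ValueError(f"invalid prescription_range {self.prescription_range}")
        if not 0 <= self.planned_violation_rate < 1:
            raise ValueError("planned_violation_rate must be in [0, 1)")


@dataclass(frozen=True)
class CohortTables:
    """The generated cohort as tidy tables (the package's CSV contracts)."""

    planned: pd.DataFrame      # patient_id, roi, metric, value_Gy
    fractions: pd.DataFrame    # patient_id, fraction, roi, metric, value_Gy (delivered)
    prescriptions: pd.DataFrame  # patient_id, roi, dpre_Gy
    courses: pd.DataFrame      # patient_id, n_fractions

    @property
    def course_lengths(self) -> dict[str, int]:
        return dict(zip(self.courses["patient_id"], self.courses["n_fractions"]))


def simulate_roi_series(
    planned_total: float,
    n_fractions: int,
    organ_class: str,
    drift: DriftModel,
    affected: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-fraction delivered metric values for one ROI over a course.

    The baseline is plan/N each fraction; when ``affected``, an adverse
    linear ramp of ``drift.trend`` Gy/fraction accrues from the onset
    fraction; Gaussian noise of ``drift.noise_sd`` is added per fraction.
    Values are floored at zero (doses are non-negative).
    """
    per_fraction = planned_total / n_fractions
    values = per_fraction + rng.normal(0.0, drift.noise_sd, size=n_fractions)
    if affected and drift.trend:
        onset = drift.onset or int(rng.integers(1, max(2, n_fractions // 2 + 1)))
        ramp = np.maximum(0, np.arange(1, n_fractions + 1) - onset + 1)
        sign = -1.0 if organ_class == "target" else 1.0
        values = values + sign * drift.trend * ramp
    return np.maximum(values, 0.0)


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def generate_course(spec: CohortSpec, patient_index: int) -> CohortTables:
    """One synthetic patient course, deterministic given (spec.seed, index)."""
    rng = _patient_rng(spec.seed, patient_index)
    patient_id = f"P{patient_index:03d}"
    n_fractions = int(rng.integers(spec.fractions_range[0], spec.fractions_range[1] + 1))

    plo, phi = spec.prescription_range
    rois: list[tuple[str, float | None]] = [("PTV_T", float(rng.uniform(max(plo, phi - 4.0), phi)))]
    node_dpre_hi = min(phi, plo + 7.5)
    for node in ("PTV_NL", "PTV_NR"):
        if rng.random() < spec.node_probability:
            rois.append((node, float(rng.uniform(plo, node_dpre_hi))))
    for oar in OAR_ROIS:
        rois.append((oar, None))

    violating_oar: str | None = None
    if rng.random() < spec.planned_violation_rate:
        violating_oar = str(rng.choice(OAR_ROIS))

    planned_rows, fraction_rows, prescription_rows = [], [], []
    for roi, d_pre in rois:
        drift = spec.drift_models.get(roi, DriftModel())
        affected = bool(rng.random() < drift.affected_probability)
        if d_pre is not None:  # target: D95 and D99 planned above thresholds
            prescription_rows.append(
                {"patient_id": patient_id, "roi": roi, "dpre_Gy": d_pre}
            )
            d95_star = d_pre * float(rng.uniform(0.96, 0.99))
            d99_star = max(d95_star - d_pre * float(rng.uniform(0.01, 0.04)),
                           0.905 * d_pre)
            # one anatomy-driven drift realisation shared by both coverage metrics
            drift = replace(drift, onset=drift.onset
                            or int(rng.integers(1, max(2, n_fractions // 2 + 1))))
            for metric, star in (("D99", d99_star), ("D95", d95_star)):
                planned_rows.append(
                    {"patient_id": patient_id, "roi": roi, "metric": metric,
                     "value_Gy": star}
                )
                series = simulate_roi_series(star, n_fractions, "target", drift,
                                             affected, rng)
                fraction_rows += [
                    {"patient_id": patient_id, "fraction": i + 1, "roi": roi,
                     "metric": metric, "value_Gy": float(v)}
                    for i, v in enumerate(series)
                ]
        else:
            metric = OAR_METRIC[roi]
            threshold = OAR_THRESHOLD[roi]
            if roi == violating_oar:
                star = threshold * float(rng.uniform(1.02, 1.10))
            else:
                star = threshold * float(rng.uniform(0.55, 0.95))
            planned_rows.append(
                {"patient_id": patient_id, "roi": roi, "metric": metric, "value_Gy": star}
            )
            organ_class = DEFAULT_ORGAN_CLASSES[roi]
            series = simulate_roi_series(star, n_fractions, organ_class, drift,
                                         affected, rng)
            fraction_rows += [
                {"patient_id": patient_id, "fraction": i + 1, "roi": roi,
                 "metric": metric, "value_Gy": float(v)}
                for i, v in enumerate(series)
            ]

    return CohortTables(
        planned=pd.DataFrame(planned_rows),
        fractions=pd.DataFrame(fraction_rows),
        prescriptions=pd.DataFrame(prescription_rows,
                                   columns=["patient_id", "roi", "dpre_Gy"]),
        courses=pd.DataFrame(
            [{"patient_id": patient_id, "n_fractions": n_fractions}]
        ),
    )


def generate_cohort(spec: CohortSpec) -> CohortTables:
    """A full synthetic cohort (default 38 patients)."""
    courses = [generate_course(spec, i) for i in range(spec.n_patients)]
    return CohortTables(
        planned=pd.concat([c.planned for c in courses], ignore_index=True),
        fractions=pd.concat([c.fractions for c in courses], ignore_index=True),
        prescriptions=pd.concat([c.prescriptions for c in courses], ignore_index=True),
        courses=pd.concat([c.courses for c in courses], ignore_index=True),
    )


def reference_decisions(cohort: CohortTables, protocol: ProtocolConfig) -> pd.DataFrame:
    """Run the protocol on the cohort (extrapolate, then flag every fraction)."""
    estimated = extrapolate_course_metrics(cohort.fractions, cohort.course_lengths)
    return flag_course(estimated, cohort.planned, cohort.prescriptions, protocol)


def label_with_reference(
    cohort: CohortTables,
    protocol: ProtocolConfig,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Surrogate ground-truth labels: the reference protocol's decisions with
    a fraction ``noise_rate`` of units perturbed by exactly one colour step
    (green<->orange, orange<->red), emulating imperfect physician agreement.
    """
    if not 0 <= noise_rate < 1:
        raise ValueError(f"noise_rate must be in [0, 1), got {noise_rate}")
    decisions = reference_decisions(cohort, protocol)
    labels = decisions[["patient_id", "fraction", "roi", "colour"]].copy()
    if noise_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1ABE1]))
        perturb = rng.random(len(labels)) < noise_rate
        colours = labels["colour"].to_numpy(copy=True)
        flips = rng.random(len(labels))  # direction draw for orange units
        for i in np.flatnonzero(perturb):
            if colours[i] == GREEN:
                colours[i] = ORANGE
            elif colours[i] == RED:
                colours[i] = ORANGE
            else:
                colours[i] = GREEN if flips[i] < 0.5 else RED
        labels["colour"] = colours
    return labels


# --------------------------------------------------------------------------
# grid mode
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridCourse:
    """A voxel-level synthetic course: planned dose, CTV mask, fraction doses."""

    planned: DoseGrid
    ctv: StructureMask
    fractions: tuple[FractionDose, ...]
    d_pre: float
    n_fractions: int


def _conformal_dose(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centre_mm: np.ndarray,
    plateau_radius_mm: float,
    falloff_mm: float,
    d_pre: float,
) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(
        (x - centre_mm[0]) ** 2 + (y - centre_mm[1]) ** 2 + (z - centre_mm[2]) ** 2
    )
    return d_pre * np.clip((plateau_radius_mm + falloff_mm - r) / falloff_mm, 0.0, 1.0)


def generate_grid_course(
    n_fractions: int = 30,
    shape: tuple[int, int, int] = (32, 32, 32),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    d_pre: float = 70.0,
    ctv_radius_mm: float = 15.0,
    planning_margin_mm: float = 4.0,
    falloff_mm: float = 12.0,
    shift_per_fraction_mm: float = 0.3,
) -> GridCourse:
    """A geometric course with peripheral dose fall-off and progressive drift.

    The planned dose is a conformal plateau of ``d_pre`` covering the CTV plus
    the planning margin, falling off linearly over ``falloff_mm`` outside.
    Each delivered fraction is the planned profile translated by
    ``shift_per_fraction_mm * i`` along one axis (an anatomical drift
    surrogate), divided by N — so target coverage erodes gradually from the
    trailing edge, and erodes earliest on the largest margin-expanded volume.
    Deterministic: the drift is systematic, with no random component.
    """
    centre = np.array([(n - 1) * s / 2.0 for n, s in zip(shape, spacing)])
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt((x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2)
    ctv = StructureMask(r <= ctv_radius_mm, label="CTV", organ_class="target")

    plateau = ctv_radius_mm + planning_margin_mm
    planned = DoseGrid(
        _conformal_dose(shape, spacing, centre, plateau, falloff_mm, d_pre),
        spacing=spacing,
    )
    fractions = []
    for i in range(1, n_fractions + 1):
        shifted_centre = centre + np.array([shift_per_fraction_mm * i, 0.0, 0.0])
        values = _conformal_dose(shape, spacing, shifted_centre, plateau, falloff_mm,
                                 d_pre) / n_fractions
        fractions.append(FractionDose(i, DoseGrid(values, spacing=spacing)))
    return GridCourse(planned, ctv, tuple(fractions), d_pre, n_fractions)


def margin_flag_counts(
    course: GridCourse,
    margins_mm: tuple[float, ...] = (0.0, 2.0, 4.0),
    config: ProtocolConfig | None = None,
) -> pd.DataFrame:
    """Per-fraction target flag colours for each margin-expanded CTV.

    For every delivered fraction the end-of-course dose is re-estimated, the
    target coverage metrics (D99, D95) are extracted on each CTV+margin
    volume, and the protocol's target rule is applied against the planned
    metrics on the same volume.  Returns a tidy frame (fraction, margin_mm,
    colour) — the substrate for flag-count-vs-margin comparisons.
    """
    from .accumulation import estimate_final_dose
    from .dvh import compute_cumulative_dvh, dose_at_volume
    from .protocol import evaluate_initial, evaluate_upgraded_target, worst_colour

    config = config or ProtocolConfig.upgraded()
    spec1, spec2 = config.target_specs()
    t1 = spec1.resolve_threshold(course.d_pre)
    t2 = spec2.resolve_threshold(course.d_pre)
    spacing = course.planned.spacing

    masks = {m: expand_margin(course.ctv, m, spacing) for m in margins_mm}
    planned_metrics = {}
    for m, mask in masks.items():
        dvh = compute_cumulative_dvh(course.planned, mask)
        planned_metrics[m] = (dose_at_volume(dvh, 99), dose_at_volume(dvh, 95))

    rows = []
    running = np.zeros_like(course.planned.values)
    for f in course.fractions:
        running = running + f.dose.values
        estimate = DoseGrid(running * (course.n_fractions / f.index), spacing=spacing)
        for m, mask in masks.items():
            dvh = compute_cumulative_dvh(estimate, mask)
            m1, m2 = dose_at_volume(dvh, 99), dose_at_volume(dvh, 95)
            m1_star, m2_star = planned_metrics[m]
            if config.variant == "upgraded":
                colour, _ = evaluate_upgraded_target(
                    m1, m1_star, t1, m2, m2_star, t2, config.dead_band
                )
            else:
                colour = worst_colour(
                    evaluate_initial(mm, ms, tt, "lower", config.tol, config.dead_band)[0]
                    for mm, ms, tt in ((m1, m1_star, t1), (m2, m2_star, t2))
                )
            rows.append({"fraction": f.index, "margin_mm": m, "colour": colour})
    return pd.DataFrame(rows)
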