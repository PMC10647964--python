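"""Rule-based flagging protocols for dosimetrically triggered adaptation.

Two protocol variants are implemented.  Both compare a DVH metric ``m``
estimated at the end of the course (see :mod:`artflag.accumulation`) against
its planned value ``m*`` and a clinical threshold ``t``, and emit one of
three action levels per ROI per fraction:

* ``green``  — no action required;
* ``orange`` — surveillance suggested (offline notification);
* ``red``    — immediate verification required (online decision).

**Initial protocol** (one rule shape for every ROI, tolerance levels
10% / 5% / 2.5%):

* when the planned value satisfies the threshold —
  orange iff the adverse difference ``m - m*`` exceeds ``tol * t``;
  red iff it exceeds ``tol * m*`` AND the estimate itself violates ``t``;
* when the planned value already violates the threshold (a knowingly
  accepted planned violation) — no orange; red iff the adverse difference
  exceeds ``tol * m*``;
* red takes precedence when both hold.

**Upgraded protocol** (organ-architecture aware, OAR tolerance fixed at 20%):

* targets combine the two coverage metrics m1 = D99 (t1 = 90% of the
  prescription) and m2 = D95 (t2 = 95% of the prescription):
  red iff both are below plan AND both below threshold; orange iff exactly
  one metric fails (below plan and threshold) while the other still meets
  its threshold;
* serial OARs (near-maximum metrics): orange iff ``m - m* > tol*t`` while
  ``m < t``; red iff ``m > m*`` and ``m > t``;
* parallel OARs (mean-dose metrics): orange iff ``m - m* > tol*t`` and
  ``m > t``; red is never emitted.

All inequalities are strict, and adverse differences with magnitude below the
0.1 Gy dead band are ignored in every difference-based condition (never in
the absolute ``m`` vs ``t`` comparisons).  Each fraction is evaluated
independently of treatment history.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GREEN, ORANGE, RED = "green", "orange", "red"
COLOURS = (GREEN, ORANGE, RED)
SEVERITY = {GREEN: 0, ORANGE: 1, RED: 2}

DEFAULT_DEAD_BAND = 0.1  # Gy
INITIAL_TOLERANCE_LEVELS = {1: 0.10, 2: 0.05, 3: 0.025}
UPGRADED_OAR_TOLERANCE = 0.20

#: default organ architecture per ROI label; targets are additionally
#: recognised by their PTV/CTV prefix.  Larynx D5 is treated as serial
#: (near-maximum metric); reclassify via ProtocolConfig if needed.
DEFAULT_ORGAN_CLASSES: dict[str, str] = {
    "SpinalCord": "serial",
    "Brainstem": "serial",
    "Mandible": "serial",
    "Larynx": "serial",
    "Parotid_ipsi": "parallel",
    "Parotid_contra": "parallel",
    "OralCavity": "parallel",
    "Constrictors_sup": "parallel",
}


@dataclass(frozen=True)
class MetricSpec:
    """One (ROI, DVH metric, threshold) row of the protocol's criteria table.

    ``threshold`` is absolute Gy when ``relative`` is False, otherwise a
    fraction of the target prescription ``D_pre`` (e.g. D95 with relative
    threshold 0.95 of a 70 Gy prescription resolves to 66.5 Gy).
    ``direction`` is ``lower`` for coverage metrics (flag on decrease) and
    ``upper`` for OAR dose metrics (flag on increase).
    """

    index: int
    roi: str
    kind: str  # "D99", "D95", "D2", "D5", "Dmean"
    threshold: float
    relative: bool = False
    direction: str = "upper"

    def __post_init__(self) -> None:
        if self.direction not in ("lower", "upper"):
            raise ValueError(f"direction must be 'lower' or 'upper', got {self.direction!r}")
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")

    def resolve_threshold(self, d_pre: float | None = None) -> float:
        """Absolute threshold in Gy, given the prescription for relative specs."""
        if not self.relative:
            return self.threshold
        if d_pre is None or d_pre <= 0:
            raise ValueError(
                f"metric {self.index} ({self.roi} {self.kind}): relative threshold "
                "requires a positive prescription dose"
            )
        return self.threshold * d_pre


#: the ten ROI-metric criteria of the protocol.  Target rows apply to every
#: PTV/CTV category (primary tumour, left node, right node) separately.
DEFAULT_METRICS: tuple[MetricSpec, ...] = (
    MetricSpec(1, "PTV", "D99", 0.90, relative=True, direction="lower"),
    MetricSpec(2, "PTV", "D95", 0.95, relative=True, direction="lower"),
    MetricSpec(3, "SpinalCord", "D2", 48.0),
    MetricSpec(4, "Brainstem", "D2", 60.0),
    MetricSpec(5, "Parotid_ipsi", "Dmean", 30.0),
    MetricSpec(6, "Parotid_contra", "Dmean", 26.0),
    MetricSpec(7, "Larynx", "D5", 45.0),
    MetricSpec(8, "OralCavity", "Dmean", 30.0),
    MetricSpec(9, "Mandible", "D2", 70.0),
    MetricSpec(10, "Constrictors_sup", "Dmean", 45.0),
)

TARGET_D99 = DEFAULT_METRICS[0]
TARGET_D95 = DEFAULT_METRICS[1]


@dataclass(frozen=True)
class FlagDecision:
    """The protocol's colour for one (patient, fraction, ROI), with a trace."""

    patient_id: str
    fraction: int
    roi: str
    colour: str
    fired: tuple[str, ...] = ()


@dataclass(frozen=True)
class ProtocolConfig:
    """Variant, tolerance, dead band, organ classes and criteria table."""

    variant: str = "upgraded"  # "initial" | "upgraded"
    tol: float = UPGRADED_OAR_TOLERANCE
    dead_band: float = DEFAULT_DEAD_BAND
    organ_classes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_CLASSES)
    )
    metrics: tuple[MetricSpec, ...] = DEFAULT_METRICS

    def __post_init__(self) -> None:
        if self.variant not in ("initial", "upgraded"):
            raise ValueError(f"variant must be 'initial' or 'upgraded', got {self.variant!r}")
        if not 0 < self.tol < 1:
            raise ValueError(f"tol must be in (0, 1), got {self.tol}")
        if self.dead_band < 0:
            raise ValueError(f"dead_band must be >= 0, got {self.dead_band}")

    @classmethod
    def initial(cls, level: int = 1, **kwargs) -> "ProtocolConfig":
        """Initial protocol at tolerance level 1 (10%), 2 (5%) or 3 (2.5%)."""
        if level not in INITIAL_TOLERANCE_LEVELS:
            raise ValueError(f"tolerance level must be 1, 2 or 3, got {level}")
        return cls(variant="initial", tol=INITIAL_TOLERANCE_LEVELS[level], **kwargs)

    @classmethod
    def upgraded(cls, **kwargs) -> "ProtocolConfig":
        return cls(variant="upgraded", tol=UPGRADED_OAR_TOLERANCE, **kwargs)

    def organ_class(self, roi: str) -> str | None:
        if roi in self.organ_classes:
            return self.organ_classes[roi]
        if roi.startswith(("PTV", "CTV")):
            return "target"
        return None

    def oar_spec(self, roi: str) -> MetricSpec | None:
        for spec in self.metrics:
            if spec.roi == roi and spec.direction == "upper":
                return spec
        return None

    def target_specs(self) -> tuple[MetricSpec, MetricSpec]:
        """The (D99, D95) coverage specs applied to every target category."""
        lower = sorted(
            (s for s in self.metrics if s.direction == "lower"), key=lambda s: s.index
        )
        if len(lower) != 2:
            raise ValueError("protocol requires exactly two target coverage metrics")
        return lower[0], lower[1]

    # --- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "tol": self.tol,
            "dead_band": self.dead_band,
            "organ_classes": dict(self.organ_classes),
            "metrics": [
                {
                    "index": s.index,
                    "roi": s.roi,
                    "kind": s.kind,
                    "threshold": s.threshold,
                    "relative": s.relative,
                    "direction": s.direction,
                }
                for s in self.metrics
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ProtocolConfig":
        metrics = tuple(MetricSpec(**row) for row in data.get("metrics", []))
        return cls(
            variant=data.get("variant", "upgraded"),
            tol=float(data.get("tol", UPGRADED_OAR_TOLERANCE)),
            dead_band=float(data.get("dead_band", DEFAULT_DEAD_BAND)),
            organ_classes=dict(data.get("organ_classes", DEFAULT_ORGAN_CLASSES)),
            metrics=metrics or DEFAULT_METRICS,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")


def _fires(adverse_diff: float, margin: float, dead_band: float) -> bool:
    """A strict difference condition, suppressed inside the dead band."""
    return adverse_diff > margin and adverse_diff >= dead_band


def worst_colour(colours: Iterable[str]) -> str:
    return max(colours, key=SEVERITY.__getitem__, default=GREEN)


def evaluate_initial(
    m: float,
    m_star: float,
    threshold: float,
    direction: str,
    tol: float,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> tuple[str, tuple[str, ...]]:
    """Initial-protocol colour for one metric value against its plan.

    ``direction='upper'`` treats increases as adverse (OAR dose),
    ``'lower'`` treats decreases as adverse (target coverage).  Returns the
    colour and a trace of the conditions that fired.
    """
    _check_finite(m=m, m_star=m_star, threshold=threshold)
    if direction not in ("lower", "upper"):
        raise ValueError(f"direction must be 'lower' or 'upper', got {direction!r}")
    upper = direction == "upper"
    adverse = (m - m_star) if upper else (m_star - m)
    planned_ok = (m_star < threshold) if upper else (m_star > threshold)
    estimate_violates = (m > threshold) if upper else (m < threshold)

    fired: list[str] = []
    if planned_ok:
        orange = _fires(adverse, tol * threshold, dead_band)
        red = _fires(adverse, tol * m_star, dead_band) and estimate_violates
        if orange:
            fired.append("adverse_diff>tol*t")
        if red:
            fired.append("adverse_diff>tol*m_star")
            fired.append("estimate_violates_t")
    else:
        # the planned metric knowingly violates t: only the relative-to-plan
        # red condition applies, to avoid futile flags
        fired.append("planned_violation")
        orange = False
        red = _fires(adverse, tol * m_star, dead_band)
        if red:
            fired.append("adverse_diff>tol*m_star")
    colour = RED if red else ORANGE if orange else GREEN
    return colour, tuple(fired) if colour != GREEN else tuple(
        f for f in fired if f == "planned_violation"
    )


def evaluate_upgraded_target(
    m1: float,
    m1_star: float,
    t1: float,
    m2: float,
    m2_star: float,
    t2: float,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> tuple[str, tuple[str, ...]]:
    """Upgraded-protocol colour for a target, combining D99 (m1) and D95 (m2).

    Red iff both metrics are below their planned values and below their
    thresholds; orange iff exactly one metric fails while the other still
    meets its threshold.  Orange and red are mutually exclusive by
    construction.
    """
    _check_finite(m1=m1, m1_star=m1_star, t1=t1, m2=m2, m2_star=m2_star, t2=t2)
    below_plan_1 = _fires(m1_star - m1, 0.0, dead_band)
    below_plan_2 = _fires(m2_star - m2, 0.0, dead_band)
    below_t1 = m1 < t1
    below_t2 = m2 < t2

    red = below_plan_1 and below_plan_2 and below_t1 and below_t2
    orange_1 = below_plan_1 and below_t1 and m2 >= t2
    orange_2 = below_plan_2 and below_t2 and m1 >= t1
    fired: list[str] = []
    if m1_star < t1 or m2_star < t2:
        fired.append("planned_violation")
    if red:
        fired += ["m1<m1_star", "m2<m2_star", "m1<t1", "m2<t2"]
        return RED, tuple(fired)
    if orange_1:
        fired += ["m1<m1_star", "m1<t1", "m2>=t2"]
    if orange_2:
        fired += ["m2<m2_star", "m2<t2", "m1>=t1"]
    if orange_1 or orange_2:
        return ORANGE, tuple(fired)
    return GREEN, tuple(f for f in fired if f == "planned_violation")


def evaluate_upgraded_serial(
    m: float,
    m_star: float,
    threshold: float,
    tol: float = UPGRADED_OAR_TOLERANCE,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> tuple[str, tuple[str, ...]]:
    """Upgraded-protocol colour for a serial OAR (near-maximum metric).

    Orange iff the increase over plan exceeds ``tol * t`` while the estimate
    is still below the threshold; red iff the estimate exceeds both its plan
    (beyond the dead band) and the threshold.
    """
    _check_finite(m=m, m_star=m_star, threshold=threshold)
    diff = m - m_star
    if _fires(diff, 0.0, dead_band) and m > threshold:
        return RED, ("m>m_star", "m>t")
    if _fires(diff, tol * threshold, dead_band) and m < threshold:
        return ORANGE, ("diff>tol*t", "m<t")
    return GREEN, ()


def evaluate_upgraded_parallel(
    m: float,
    m_star: float,
    threshold: float,
    tol: float = UPGRADED_OAR_TOLERANCE,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> tuple[str, tuple[str, ...]]:
    """Upgraded-protocol colour for a parallel OAR (mean-dose metric).

    Orange iff the increase over plan exceeds ``tol * t`` and the estimate
    exceeds the threshold; parallel organs never trigger red.
    """
    _check_finite(m=m, m_star=m_star, threshold=threshold)
    diff = m - m_star
    if _fires(diff, tol * threshold, dead_band) and m > threshold:
        return ORANGE, ("diff>tol*t", "m>t")
    return GREEN, ()


def _evaluate_roi(
    roi: str,
    organ_class: str,
    planned: Mapping[str, float],
    estimated: Mapping[str, float],
    d_pre: float | None,
    config: ProtocolConfig,
) -> tuple[str, tuple[str, ...]] | None:
    """Colour one ROI at one fraction; None when required metrics are absent."""
    if organ_class == "target":
        spec1, spec2 = config.target_specs()
        needed = (spec1.kind, spec2.kind)
        if any(k not in planned or k not in estimated for k in needed):
            return None
        t1 = spec1.resolve_threshold(d_pre)
        t2 = spec2.resolve_threshold(d_pre)
        if config.variant == "upgraded":
            return evaluate_upgraded_target(
                estimated[spec1.kind], planned[spec1.kind], t1,
                estimated[spec2.kind], planned[spec2.kind], t2,
                dead_band=config.dead_band,
            )
        results = [
            evaluate_initial(
                estimated[s.kind], planned[s.kind], t, "lower",
                config.tol, config.dead_band,
            )
            for s, t in ((spec1, t1), (spec2, t2))
        ]
        colour = worst_colour(c for c, _ in results)
        fired = tuple(
            f"{s.kind}:{cond}"
            for s, (_, conds) in zip((spec1, spec2), results)
            for cond in conds
        )
        return colour, fired

    spec = config.oar_spec(roi)
    if spec is None or spec.kind not in planned or spec.kind not in estimated:
        return None
    t = spec.resolve_threshold()
    m, m_star = estimated[spec.kind], planned[spec.kind]
    if config.variant == "initial":
        return evaluate_initial(m, m_star, t, "upper", config.tol, config.dead_band)
    if organ_class == "serial":
        return evaluate_upgraded_serial(m, m_star, t, config.tol, config.dead_band)
    return evaluate_upgraded_parallel(m, m_star, t, config.tol, config.dead_band)


def flag_course(
    estimated_metrics: pd.DataFrame,
    planned_metrics: pd.DataFrame,
    prescriptions: pd.DataFrame,
    config: ProtocolConfig,
) -> pd.DataFrame:
    """Apply the protocol to every (patient, fraction, ROI) of a cohort.

    Parameters
    ----------
    estimated_metrics:
        End-of-course metric estimates per fraction: columns (patient_id,
        fraction, roi, metric, value_Gy).  Each fraction is judged
        independently on its own estimates.
    planned_metrics:
        Planned metric values: columns (patient_id, roi, metric, value_Gy).
    prescriptions:
        Target prescriptions: columns (patient_id, roi, dpre_Gy).
    config:
        Protocol variant, tolerance, dead band and organ classes.

    Returns
    -------
    DataFrame with one row per (patient_id, fraction, roi): columns colour
    and fired (a ``|``-joined trace of the conditions that held).  ROIs with
    no applicable criteria or missing metrics are skipped with a warning.
    """
    est = estimated_metrics.pivot_table(
        index=["patient_id", "fraction", "roi"],
        columns="metric", values="value_Gy", aggfunc="first",
    )
    plan = planned_metrics.pivot_table(
        index=["patient_id", "roi"], columns="metric", values="value_Gy", aggfunc="first"
    )
    d_pre_map = {
        (row.patient_id, row.roi): float(row.dpre_Gy)
        for row in prescriptions.itertuples()
    }

    skipped: set[tuple[str, str]] = set()
    rows: list[dict] = []
    plan_index = set(plan.index)
    for (patient, fraction, roi), est_row in est.iterrows():
        organ_class = config.organ_class(roi)
        if organ_class is None:
            if (patient, roi) not in skipped:
                logger.warning("ROI %r (patient %s): no organ class, skipped", roi, patient)
                skipped.add((patient, roi))
            continue
        if (patient, roi) not in plan_index:
            if (patient, roi) not in skipped:
                logger.warning("ROI %r (patient %s): no planned metrics, skipped", roi, patient)
                skipped.add((patient, roi))
            continue
        planned_row = plan.loc[(patient, roi)].dropna().to_dict()
        estimated_row = est_row.dropna().to_dict()
        result = _evaluate_roi(
            roi, organ_class, planned_row, estimated_row,
            d_pre_map.get((patient, roi)), config,
        )
        if result is None:
            if (patient, roi) not in skipped:
                logger.warning("ROI %r (patient %s): required metrics missing, skipped",
                               roi, patient)
                skipped.add((patient, roi))
            continue
        colour, fired = result
        rows.append(
            {
                "patient_id": patient,
                "fraction": int(fraction),
                "roi": roi,
                "colour": colour,
                "fired": "|".join(fired),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "fraction", "roi", "colour", "fired"])
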