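"""Dose accumulation and end-of-treatment dose extrapolation.

At fraction ``n`` of an ``N``-fraction course the final delivered dose is
estimated by accumulating the fractions delivered so far and assuming the
remaining ``N - n`` fractions will deliver their average:

    D_estimated(n) = sum_{i<=n} d_i + (N - n) * mean(d_1..d_n)
                   = (N / n) * sum_{i<=n} d_i

The estimate is voxelwise on the common planning grid; DVH metrics are then
extracted from the estimated grid.  A metrics-only mode applies the same
formula to per-fraction DVH-metric values read from CSV — an approximation,
since quantile metrics such as D95 are nonlinear in dose, but convenient when
only per-fraction metric tables are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import DoseGrid

FRACTION_METRIC_COLUMNS = ["patient_id", "fraction", "roi", "metric", "value_Gy"]


@dataclass(frozen=True)
class FractionDose:
    """The dose delivered at one fraction, expressed on the planning grid."""

    index: int  # 1-based fraction number
    dose: DoseGrid

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"fraction index must be >= 1, got {self.index}")


@dataclass(frozen=True)
class CourseSchedule:
    """Planned course: total fractions, prescriptions per target, planned dose."""

    n_fractions: int
    prescriptions: Mapping[str, float] = field(default_factory=dict)
    planned_dose: DoseGrid | None = None

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")
        for roi, d_pre in self.prescriptions.items():
            if d_pre <= 0:
                raise ValueError(f"prescription for {roi!r} must be positive, got {d_pre}")


def _validated_prefix(fractions: Sequence[FractionDose]) -> list[FractionDose]:
    if not fractions:
        raise ValueError("at least one delivered fraction is required")
    indices = sorted(f.index for f in fractions)
    if indices != list(range(1, len(fractions) + 1)):
        raise ValueError(
            f"fractions must form the contiguous prefix 1..n, got indices {indices}"
        )
    first = fractions[0].dose
    for f in fractions[1:]:
        if not first.congruent_with(f.dose):
            raise ValueError(
                f"fraction {f.index} dose grid is not congruent with fraction 1"
            )
    return sorted(fractions, key=lambda f: f.index)


def accumulate(fractions: Sequence[FractionDose]) -> DoseGrid:
    """Voxelwise sum of the delivered fraction doses."""
    ordered = _validated_prefix(fractions)
    total = np.zeros_like(ordered[0].dose.values)
    for f in ordered:
        total += f.dose.values
    ref = ordered[0].dose
    return DoseGrid(total, spacing=ref.spacing, origin=ref.origin)


def estimate_final_dose(fractions: Sequence[FractionDose], n_total: int) -> DoseGrid:
    """Voxelwise end-of-course estimate ``(N/n) * sum_{i<=n} d_i``.

    Exactly equals :func:`accumulate` when all ``N`` fractions are in; under
    perfect delivery (every fraction = plan / N) it recovers the planned dose
    at every ``n``.
    """
    ordered = _validated_prefix(fractions)
    n = len(ordered)
    if n > n_total:
        raise ValueError(f"delivered {n} fractions exceeds course length N={n_total}")
    total = accumulate(ordered)
    scaled = total.values * (n_total / n)
    return DoseGrid(scaled, spacing=total.spacing, origin=total.origin)


def extrapolate_metric_series(values: Sequence[float], n_total: int) -> np.ndarray:
    """Metrics-only extrapolation: estimate after each fraction of a series.

    ``values[i-1]`` is a per-fraction metric value for fraction ``i``; the
    returned array gives ``(N/n) * sum_{i<=n} values[i]`` for each n.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("metric series must be a non-empty 1-D sequence")
    if v.size > n_total:
        raise ValueError(f"series length {v.size} exceeds course length N={n_total}")
    n = np.arange(1, v.size + 1)
    return np.cumsum(v) * (n_total / n)


def extrapolate_course_metrics(
    fraction_metrics: pd.DataFrame, course_lengths: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Per-fraction end-of-course metric estimates for a whole cohort table.

    ``fraction_metrics`` has columns (patient_id, fraction, roi, metric,
    value_Gy) holding per-fraction delivered metric values.  When
    ``course_lengths`` is omitted, each patient's course length N is taken as
    their largest fraction number (complete retrospective courses).  Returns a
    table of the same shape where ``value_Gy`` is the estimate at each
    fraction.
    """
    missing = set(FRACTION_METRIC_COLUMNS) - set(fraction_metrics.columns)
    if missing:
        raise ValueError(f"fraction metrics table is missing columns {sorted(missing)}")
    df = fraction_metrics.sort_values(["patient_id", "roi", "metric", "fraction"]).copy()
    if course_lengths is None:
        course_lengths = df.groupby("patient_id")["fraction"].max().to_dict()
    n_total = df["patient_id"].map(course_lengths)
    if n_total.isna().any():
        unknown = sorted(df.loc[n_total.isna(), "patient_id"].unique())
        raise ValueError(f"no course length for patients {unknown}")

    group = df.groupby(["patient_id", "roi", "metric"], sort=False)
    n_delivered = group.cumcount() + 1
    first_fraction = group["fraction"].transform("min")
    contiguous = df["fraction"] == n_delivered
    if not (contiguous.all() and (first_fraction == 1).all()):
        raise ValueError("each (patient, roi, metric) series must cover fractions 1..n")
    df["value_Gy"] = group["value_Gy"].cumsum() / n_delivered * n_total.to_numpy()
    return df.reset_index(drop=True)


def read_fraction_metrics(path) -> pd.DataFrame:
    """Read a per-fraction metric CSV (patient_id, fraction, roi, metric, value_Gy)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FRACTION_METRIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["fraction"] = df["fraction"].astype(int)
    return df
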