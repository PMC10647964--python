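"""Benchmarking protocol decisions against ground-truth flag labels.

The comparison unit is one (patient, fraction, ROI) triple.  For a chosen
positive class — one colour, or "any flag regardless of colour" — decisions
and labels are reduced to binary outcomes and tallied into a confusion
matrix; sensitivity TP/(TP+FN) and specificity TN/(TN+FP) summarise the
agreement.  With per-colour positives, a unit where the protocol says red but
the reference says orange counts as a false positive for red and a false
negative for orange — the cross-counting that makes per-colour and global
(colour-agnostic) results differ.

Cohort summaries mirror the clinical reporting style: the percentage of
patients with at least one flag of a colour per treatment week (five
fractions), the percentage still flagged at their last fraction, and the
share of flags on targets versus organs at risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .protocol import GREEN, ORANGE, RED

logger = logging.getLogger(__name__)

UNIT_KEYS = ["patient_id", "fraction", "roi"]
ANY_FLAG = "any"


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts over comparison units for one positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def sensitivity(cm: ConfusionMatrix) -> float | None:
    """TP/(TP+FN); None (undefined) when no positive reference units exist."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else None


def specificity(cm: ConfusionMatrix) -> float | None:
    """TN/(TN+FP); None (undefined) when no negative reference units exist."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else None


def _aligned(decisions: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    dec_units = set(map(tuple, decisions[UNIT_KEYS].itertuples(index=False)))
    lab_units = set(map(tuple, labels[UNIT_KEYS].itertuples(index=False)))
    if dec_units != lab_units:
        missing = sorted(dec_units ^ lab_units)[:10]
        raise ValueError(
            f"decisions and labels cover different comparison units; "
            f"{len(dec_units ^ lab_units)} mismatched, e.g. {missing}"
        )
    if len(dec_units) != len(decisions) or len(lab_units) != len(labels):
        raise ValueError("duplicate comparison units present")
    return decisions.merge(labels, on=UNIT_KEYS, suffixes=("_dec", "_lab"))


def confusion(
    decisions: pd.DataFrame, labels: pd.DataFrame, positive_class: str
) -> ConfusionMatrix:
    """Confusion matrix of protocol decisions against reference labels.

    ``positive_class`` is one colour (``"orange"``/``"red"``), or ``"any"``
    for the global, colour-agnostic comparison in which any non-green flag
    counts as positive.  Both tables need columns (patient_id, fraction, roi,
    colour) over identical unit sets.
    """
    if positive_class not in (ORANGE, RED, ANY_FLAG):
        raise ValueError(f"positive_class must be 'orange', 'red' or 'any', got {positive_class!r}")
    merged = _aligned(decisions, labels)
    if positive_class == ANY_FLAG:
        pos_dec = merged["colour_dec"] != GREEN
        pos_lab = merged["colour_lab"] != GREEN
    else:
        pos_dec = merged["colour_dec"] == positive_class
        pos_lab = merged["colour_lab"] == positive_class
    return ConfusionMatrix(
        tp=int((pos_dec & pos_lab).sum()),
        fp=int((pos_dec & ~pos_lab).sum()),
        fn=int((~pos_dec & pos_lab).sum()),
        tn=int((~pos_dec & ~pos_lab).sum()),
    )


def week_of_fraction(fraction: int, n_fractions: int) -> int:
    """Treatment week of a fraction (five fractions per week).

    A trailing partial week of at most two fractions is folded into the
    previous week; three or more remaining fractions form their own week
    (e.g. a 32-fraction course ends in week 6, a 33-fraction course in
    week 7).
    """
    week = (fraction - 1) // 5 + 1
    full_weeks, remainder = divmod(n_fractions, 5)
    if full_weeks and 0 < remainder <= 2 and week == full_weeks + 1:
        return full_weeks
    return week


def weekly_flag_rate(
    decisions: pd.DataFrame, colour: str, n_patients: int
) -> dict:
    """Percent of patients with >= 1 flag of ``colour`` per week, plus the
    percent still flagged at their last fraction.

    ``colour`` may be ``"orange"``, ``"red"`` or ``"any"`` (non-green).
    Each patient's course length is taken as their largest fraction number.
    """
    if n_patients <= 0:
        raise ValueError(f"n_patients must be positive, got {n_patients}")
    if decisions.empty:
        logger.warning("weekly_flag_rate: empty decision set")
        return {"weeks": {}, "last_fraction": 0.0}
    df = decisions.copy()
    course_length = df.groupby("patient_id")["fraction"].transform("max")
    df["week"] = [
        week_of_fraction(int(f), int(n)) for f, n in zip(df["fraction"], course_length)
    ]
    flagged = df["colour"] != GREEN if colour == ANY_FLAG else df["colour"] == colour

    weeks: dict[int, float] = {}
    max_week = int(df["week"].max())
    for week in range(1, max_week + 1):
        in_week = df["week"] == week
        patients = df.loc[in_week & flagged, "patient_id"].nunique()
        weeks[week] = 100.0 * patients / n_patients
    last = df["fraction"] == course_length
    last_patients = df.loc[last & flagged, "patient_id"].nunique()
    return {"weeks": weeks, "last_fraction": 100.0 * last_patients / n_patients}


def flag_composition(
    decisions: pd.DataFrame, target_prefixes: tuple[str, ...] = ("PTV", "CTV")
) -> dict:
    """Share (percent) of flags on targets vs OARs, per colour.

    Counting unit = individual (patient, fraction, ROI) flags; shares sum to
    100 for every colour that has at least one flag, and are None (undefined)
    otherwise.
    """
    out: dict[str, dict] = {}
    is_target = decisions["roi"].str.startswith(target_prefixes)
    for colour in (ORANGE, RED):
        of_colour = decisions["colour"] == colour
        total = int(of_colour.sum())
        if total == 0:
            logger.warning("flag_composition: no %s flags", colour)
            out[colour] = {"PTV": None, "OAR": None, "n_flags": 0}
            continue
        ptv = int((of_colour & is_target).sum())
        out[colour] = {
            "PTV": 100.0 * ptv / total,
            "OAR": 100.0 * (total - ptv) / total,
            "n_flags": total,
        }
    return out


def _rounded(value: float | None) -> float | None:
    return None if value is None else round(value, 2)


def evaluation_report(
    decisions: pd.DataFrame, labels: pd.DataFrame, n_patients: int | None = None
) -> dict:
    """Full benchmarking report: per-colour and global confusion matrices,
    sensitivity/specificity (rounded to two decimals, the reporting
    convention), weekly flag rates and flag composition."""
    report: dict = {"classes": {}}
    for positive in (RED, ORANGE, ANY_FLAG):
        cm = confusion(decisions, labels, positive)
        report["classes"][positive] = {
            "TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn,
            "sensitivity": _rounded(sensitivity(cm)),
            "specificity": _rounded(specificity(cm)),
        }
    if n_patients is None:
        n_patients = decisions["patient_id"].nunique()
    report["weekly_rates"] = {
        colour: weekly_flag_rate(decisions, colour, n_patients)
        for colour in (ORANGE, RED)
    }
    report["composition"] = flag_composition(decisions)
    report["n_units"] = int(len(decisions))
    report["n_patients"] = int(n_patients)
    return report
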