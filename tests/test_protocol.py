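"""Flagging rules: worked examples, properties, and a brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artflag.protocol import (
    GREEN,
    ORANGE,
    RED,
    SEVERITY,
    MetricSpec,
    ProtocolConfig,
    evaluate_initial,
    evaluate_upgraded_parallel,
    evaluate_upgraded_serial,
    evaluate_upgraded_target,
    flag_course,
)
from conftest import make_metric_tables

DB = 0.1  # dead band in Gy


# ---------------------------------------------------------------------------
# independent straight-line transcriptions of the published rule tables
# (deliberately sharing no helpers with the engine)
# ---------------------------------------------------------------------------

def initial_rule_oracle(m, m_star, t, direction, tol):
    if direction == "upper":
        diff = m - m_star
        if m_star < t:  # planned value satisfies the threshold
            orange = diff > tol * t and diff >= DB
            red = diff > tol * m_star and diff >= DB and m > t
        else:  # knowingly accepted planned violation
            orange = False
            red = diff > tol * m_star and diff >= DB
    else:
        diff = m_star - m
        if m_star > t:
            orange = diff > tol * t and diff >= DB
            red = diff > tol * m_star and diff >= DB and m < t
        else:
            orange = False
            red = diff > tol * m_star and diff >= DB
    if red:
        return RED
    if orange:
        return ORANGE
    return GREEN


def upgraded_target_oracle(m1, m1s, t1, m2, m2s, t2):
    f1 = m1s - m1 > 0 and m1s - m1 >= DB
    f2 = m2s - m2 > 0 and m2s - m2 >= DB
    if f1 and f2 and m1 < t1 and m2 < t2:
        return RED
    if (f1 and m1 < t1 and m2 >= t2) or (f2 and m2 < t2 and m1 >= t1):
        return ORANGE
    return GREEN


def upgraded_serial_oracle(m, m_star, t, tol=0.20):
    if m - m_star > 0 and m - m_star >= DB and m > t:
        return RED
    if m - m_star > tol * t and m - m_star >= DB and m < t:
        return ORANGE
    return GREEN


def upgraded_parallel_oracle(m, m_star, t, tol=0.20):
    if m - m_star > tol * t and m - m_star >= DB and m > t:
        return ORANGE
    return GREEN


# ---------------------------------------------------------------------------
# worked examples from the published rule tables
# ---------------------------------------------------------------------------

class TestInitialProtocolExamples:
    def test_target_d95_red(self):
        """70 Gy prescription, t = 66.5 Gy, plan 68, estimate 60, tol 10%:
        the 8 Gy coverage loss exceeds both the 6.65 Gy orange margin and the
        6.8 Gy red margin while D95 < t, and red takes precedence."""
        colour, fired = evaluate_initial(60.0, 68.0, 66.5, "lower", 0.10)
        assert colour == RED
        assert "adverse_diff>tol*m_star" in fired

    def test_parotid_orange_but_not_red(self):
        """Ipsilateral parotid, t = 30 Gy: +3.5 Gy exceeds the 3 Gy orange
        margin but the estimate (28.5) still satisfies t, so no red."""
        colour, _ = evaluate_initial(28.5, 25.0, 30.0, "upper", 0.10)
        assert colour == ORANGE

    def test_no_change_is_green(self):
        for direction, t in (("lower", 66.5), ("upper", 30.0)):
            assert evaluate_initial(40.0, 40.0, t, direction, 0.025)[0] == GREEN

    def test_planned_violation_uses_relative_condition_only(self):
        """Planned parotid mean already above 30 Gy: orange is impossible and
        red fires only on a further >tol*m* increase."""
        colour, fired = evaluate_initial(32.0, 31.0, 30.0, "upper", 0.10)
        assert colour == GREEN and "planned_violation" in fired
        colour, _ = evaluate_initial(35.0, 31.0, 30.0, "upper", 0.10)
        assert colour == RED

    def test_non_finite_input_error(self):
        with pytest.raises(ValueError):
            evaluate_initial(float("nan"), 68.0, 66.5, "lower", 0.1)


class TestUpgradedProtocolExamples:
    # plan: D_pre = 70 -> t1 = 63 (D99), t2 = 66.5 (D95)
    T1, T2 = 63.0, 66.5

    def test_target_single_metric_failure_is_orange(self):
        colour, _ = evaluate_upgraded_target(62.0, 66.0, self.T1, 67.0, 68.0, self.T2)
        assert colour == ORANGE

    def test_target_double_failure_is_red(self):
        colour, _ = evaluate_upgraded_target(62.0, 66.0, self.T1, 65.0, 68.0, self.T2)
        assert colour == RED

    def test_target_on_plan_is_green(self):
        assert evaluate_upgraded_target(66.0, 66.0, self.T1, 68.0, 68.0, self.T2)[0] == GREEN

    def test_serial_oar(self):
        # spinal cord, t = 48, tol 20% -> 9.6 Gy orange margin
        assert evaluate_upgraded_serial(46.0, 36.0, 48.0)[0] == ORANGE
        assert evaluate_upgraded_serial(49.0, 36.0, 48.0)[0] == RED
        assert evaluate_upgraded_serial(36.0, 36.0, 48.0)[0] == GREEN

    def test_parallel_oar_never_red(self):
        # ipsilateral parotid, t = 30, tol 20% -> 6 Gy margin
        assert evaluate_upgraded_parallel(33.0, 26.0, 30.0)[0] == ORANGE
        assert evaluate_upgraded_parallel(31.0, 26.0, 30.0)[0] == GREEN
        # even an extreme overdose stays orange at most
        assert evaluate_upgraded_parallel(60.0, 26.0, 30.0)[0] == ORANGE


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

def test_threshold_resolution_from_prescription():
    d95 = MetricSpec(2, "PTV", "D95", 0.95, relative=True, direction="lower")
    assert d95.resolve_threshold(70.0) == pytest.approx(66.5)
    assert d95.resolve_threshold(52.5) == pytest.approx(49.875)
    with pytest.raises(ValueError):
        d95.resolve_threshold(None)


@given(
    m_star=st.floats(10, 80),
    t=st.floats(10, 80),
    eps=st.floats(-0.0999, 0.0999),
    tol=st.sampled_from([0.025, 0.05, 0.10, 0.20]),
    direction=st.sampled_from(["lower", "upper"]),
)
@settings(max_examples=300, deadline=None)
def test_dead_band_suppresses_subthreshold_changes(m_star, t, eps, tol, direction):
    """Any perturbation below 0.1 Gy from plan never leaves green, in both
    protocol variants, regardless of thresholds or planned violations."""
    m = m_star + eps
    assert evaluate_initial(m, m_star, t, direction, tol)[0] == GREEN
    assert evaluate_upgraded_serial(m, m_star, t, tol)[0] == GREEN
    assert evaluate_upgraded_parallel(m, m_star, t, tol)[0] == GREEN
    assert evaluate_upgraded_target(m, m_star, t, m, m_star, t)[0] == GREEN


def test_initial_red_precedence():
    """When orange and red conditions hold simultaneously, red is emitted."""
    # target: big coverage loss fires both conditions
    colour, fired = evaluate_initial(50.0, 68.0, 66.5, "lower", 0.10)
    assert colour == RED
    assert "adverse_diff>tol*t" in fired  # orange condition did hold


def test_upgraded_orange_red_exclusive_on_lattice():
    """Exhaustive scan of metric values around plan and thresholds: the
    upgraded rules never satisfy orange and red clauses simultaneously."""
    t1, t2 = 63.0, 66.5
    values = np.arange(58.0, 72.1, 0.5)
    for m1s, m2s in ((66.0, 68.0), (63.0, 66.5), (62.0, 66.0)):
        for m1, m2 in itertools.product(values, values):
            red = (
                m1s - m1 >= DB and m2s - m2 >= DB and m1 < t1 and m2 < t2
            )
            orange = (m1s - m1 >= DB and m1 < t1 and m2 >= t2) or (
                m2s - m2 >= DB and m2 < t2 and m1 >= t1
            )
            assert not (red and orange)
            colour, _ = evaluate_upgraded_target(m1, m1s, t1, m2, m2s, t2)
            assert colour == (RED if red else ORANGE if orange else GREEN)
    # serial: the orange clause needs m < t, the red clause m > t
    for m in np.arange(30.0, 60.1, 0.25):
        for m_star in (30.0, 40.0, 47.0):
            assert not (
                upgraded_serial_oracle(m, m_star, 48.0) == ORANGE
                and m > 48.0
            )


def test_tolerance_monotonicity_initial_protocol(rng):
    """Tighter tolerances flag supersets: every non-green unit at tol=10%
    stays non-green at 5% and 2.5%, and severities never decrease."""
    for _ in range(2000):
        direction = rng.choice(["lower", "upper"])
        t = rng.uniform(20, 70)
        m_star = rng.uniform(15, 75)
        m = m_star + rng.normal(0, 8)
        colours = [
            evaluate_initial(m, m_star, t, direction, tol)[0]
            for tol in (0.10, 0.05, 0.025)
        ]
        sev = [SEVERITY[c] for c in colours]
        assert sev[0] <= sev[1] <= sev[2]


def test_engine_matches_brute_force_oracle(rng):
    """10^5 randomised metric tuples: the engine agrees with the independent
    straight-line transcription of both rule tables."""
    n = 100_000
    directions = rng.choice(["lower", "upper"], n)
    ts = rng.uniform(20, 70, n)
    m_stars = rng.uniform(15, 75, n)
    ms = m_stars + rng.normal(0, 6, n)
    tols = rng.choice([0.025, 0.05, 0.10], n)
    for i in range(n):
        expected = initial_rule_oracle(ms[i], m_stars[i], ts[i], directions[i], tols[i])
        got, _ = evaluate_initial(ms[i], m_stars[i], ts[i], directions[i], tols[i])
        assert got == expected, (ms[i], m_stars[i], ts[i], directions[i], tols[i])

    # upgraded rules on fresh draws
    t1s = rng.uniform(55, 65, n)
    t2s = t1s + rng.uniform(1, 6, n)
    m1ss = rng.uniform(55, 70, n)
    m2ss = m1ss + rng.uniform(0, 4, n)
    m1s_ = m1ss + rng.normal(0, 4, n)
    m2s_ = m2ss + rng.normal(0, 4, n)
    oar_ts = rng.uniform(25, 70, n)
    oar_stars = rng.uniform(15, 75, n)
    oar_ms = oar_stars + rng.normal(0, 6, n)
    for i in range(n):
        assert (
            evaluate_upgraded_target(m1s_[i], m1ss[i], t1s[i], m2s_[i], m2ss[i], t2s[i])[0]
            == upgraded_target_oracle(m1s_[i], m1ss[i], t1s[i], m2s_[i], m2ss[i], t2s[i])
        )
        assert (
            evaluate_upgraded_serial(oar_ms[i], oar_stars[i], oar_ts[i])[0]
            == upgraded_serial_oracle(oar_ms[i], oar_stars[i], oar_ts[i])
        )
        assert (
            evaluate_upgraded_parallel(oar_ms[i], oar_stars[i], oar_ts[i])[0]
            == upgraded_parallel_oracle(oar_ms[i], oar_stars[i], oar_ts[i])
        )


def test_determinism():
    args = (61.3, 66.2, 63.0, 64.9, 67.8, 66.5)
    assert evaluate_upgraded_target(*args) == evaluate_upgraded_target(*args)


# ---------------------------------------------------------------------------
# course-level flagging
# ---------------------------------------------------------------------------

def course_tables(collapse_fraction=None, n_fractions=15):
    """A one-patient course on plan everywhere, optionally with a target
    coverage collapse injected at a single fraction."""
    planned = {
        ("PTV_T", "D99"): 65.0,
        ("PTV_T", "D95"): 67.5,
        ("SpinalCord", "D2"): 36.0,
        ("Parotid_ipsi", "Dmean"): 24.0,
    }
    per_fraction = {}
    for fx in range(1, n_fractions + 1):
        metrics = dict(planned)
        if fx == collapse_fraction:
            metrics[("PTV_T", "D99")] = 60.0  # below t1 = 63 and plan
            metrics[("PTV_T", "D95")] = 64.0  # below t2 = 66.5 and plan
        per_fraction[fx] = metrics
    planned_df, est_df = make_metric_tables(planned, per_fraction)
    prescriptions = pd.DataFrame(
        [{"patient_id": "P0", "roi": "PTV_T", "dpre_Gy": 70.0}]
    )
    return est_df, planned_df, prescriptions


class TestFlagCourse:
    def test_on_plan_course_is_all_green(self, upgraded_config, initial_config):
        for config in (upgraded_config, initial_config):
            decisions = flag_course(*course_tables(), config=config)
            assert set(decisions["colour"]) == {GREEN}
            assert len(decisions) == 15 * 3  # 3 ROIs x 15 fractions

    def test_fraction_independence_of_injected_collapse(self, upgraded_config):
        """A D99/D95 collapse at fraction 10 only yields red at fraction 10
        and nowhere else: decisions carry no history."""
        decisions = flag_course(*course_tables(collapse_fraction=10),
                                config=upgraded_config)
        target = decisions[decisions["roi"] == "PTV_T"].set_index("fraction")
        assert target.loc[10, "colour"] == RED
        assert set(target.drop(index=10)["colour"]) == {GREEN}

    def test_unknown_roi_skipped_with_warning(self, upgraded_config, caplog):
        est_df, planned_df, prescriptions = course_tables()
        extra = pd.DataFrame(
            [{"patient_id": "P0", "fraction": 1, "roi": "Mystery",
              "metric": "Dmean", "value_Gy": 1.0}]
        )
        with caplog.at_level("WARNING", logger="artflag.protocol"):
            decisions = flag_course(
                pd.concat([est_df, extra], ignore_index=True),
                planned_df, prescriptions, upgraded_config,
            )
        assert "Mystery" not in set(decisions["roi"])
        assert any("Mystery" in r.message for r in caplog.records)

    def test_initial_variant_tolerance_superset_on_course(self):
        """On a fixed drifting course, flag sets grow as tolerance tightens."""
        rng = np.random.default_rng(7)
        planned = {("PTV_T", "D99"): 65.0, ("PTV_T", "D95"): 67.5}
        per_fraction = {
            fx: {k: v - rng.uniform(0, 6) for k, v in planned.items()}
            for fx in range(1, 16)
        }
        planned_df, est_df = make_metric_tables(planned, per_fraction)
        rx = pd.DataFrame([{"patient_id": "P0", "roi": "PTV_T", "dpre_Gy": 70.0}])
        flagged = {}
        for level in (1, 2, 3):
            decisions = flag_course(est_df, planned_df, rx,
                                    ProtocolConfig.initial(level))
            flagged[level] = set(
                decisions.loc[decisions["colour"] != GREEN, "fraction"]
            )
        assert flagged[1] <= flagged[2] <= flagged[3]


def test_config_yaml_round_trip(tmp_path):
    config = ProtocolConfig.initial(level=3)
    path = tmp_path / "protocol.yaml"
    config.to_yaml(path)
    back = ProtocolConfig.from_yaml(path)
    assert back == config
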