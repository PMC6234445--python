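"""Respiratory-parameter arithmetic and its invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwaycfd import geometry, respiration as resp


@pytest.mark.parametrize(
    "age, mv, q_insp, q_exp",
    [
        ("infant", 1404.0, 3.51, 2.34),
        ("child", 3620.0, 9.77, 5.75),
        ("adult", 7000.0, 18.90, 11.12),
    ],
)
def test_tabulated_breathing_parameters(age, mv, q_insp, q_exp):
    """Minute ventilation and phase flow rates match the published table."""
    pattern = resp.breathing_pattern(age)
    assert resp.minute_ventilation(pattern) == pytest.approx(mv)
    qi, qe = resp.phase_flow_rates(pattern)
    assert round(qi, 2) == pytest.approx(q_insp)
    assert round(qe, 2) == pytest.approx(q_exp)


@pytest.mark.parametrize(
    "age, alpha", [("infant", 0.25), ("child", 0.34), ("adult", 0.44)]
)
def test_womersley_numbers(age, alpha):
    """Radius-based Womersley numbers reproduce the published 0.25/0.34/0.44."""
    pattern = resp.breathing_pattern(age)
    profile = geometry.build_profile(age)
    d6 = profile.generation(6).diameter_mm * 1e-3
    assert resp.womersley_number(d6, pattern.respiratory_rate) == pytest.approx(
        alpha, abs=0.01
    )


def test_zero_tidal_volume_gives_zero_ventilation():
    pattern = resp.BreathingPattern(0.0, 30.0, (1.0, 1.5))
    assert resp.minute_ventilation(pattern) == 0.0


def test_symmetric_phases_double_minute_ventilation():
    pattern = resp.BreathingPattern(100.0, 10.0, (1.0, 1.0))
    qi, qe = resp.phase_flow_rates(pattern)
    assert qi == qe == pytest.approx(2 * resp.minute_ventilation(pattern) / 1000.0)


@given(
    tv=st.floats(1.0, 2000.0),
    rr=st.floats(5.0, 80.0),
    te=st.floats(0.2, 5.0),
)
@settings(max_examples=50, deadline=None)
def test_phase_flows_conserve_minute_ventilation(tv, rr, te):
    """Time-weighted phase flows each move exactly the minute ventilation."""
    pattern = resp.BreathingPattern(tv, rr, (1.0, te))
    mv = resp.minute_ventilation(pattern)
    qi, qe = resp.phase_flow_rates(pattern)
    t_i, t_e = pattern.ie_ratio
    assert qi * 1000 * t_i / (t_i + t_e) == pytest.approx(mv, rel=1e-12)
    assert qe * 1000 * t_e / (t_i + t_e) == pytest.approx(mv, rel=1e-12)
    if t_e > t_i:
        assert qi > qe


@given(q=st.floats(0.1, 50.0), g=st.integers(0, 12))
@settings(max_examples=50, deadline=None)
def test_branch_flow_halves_and_recovers(q, g):
    """Per-branch flow halves each generation; branches sum back to the total."""
    single = resp.branch_flow_rate(q, g)
    assert single * 2**g == pytest.approx(resp.branch_flow_rate(q, 0), rel=1e-12)
    assert resp.branch_flow_rate(q, 0) == pytest.approx(q * 1e-3 / 60.0)


def test_branch_flow_rejects_negative_generation():
    with pytest.raises(ValueError):
        resp.branch_flow_rate(1.0, -1)


def test_mean_inlet_velocity_identity():
    q = math.pi / 4 * 1e-6
    assert resp.mean_inlet_velocity(q, 1e-3) == pytest.approx(1.0)


def test_infant_adult_inlet_velocities_and_reynolds():
    """G6 inlet speeds ~1.16 / ~0.80 m/s give Re ~80 / ~153."""
    for age, u_ref, re_ref in [("infant", 1.16, 80.0), ("adult", 0.80, 153.0)]:
        pattern = resp.breathing_pattern(age)
        profile = geometry.build_profile(age)
        d6 = profile.generation(6).diameter_mm * 1e-3
        qi, _ = resp.phase_flow_rates(pattern)
        u = resp.mean_inlet_velocity(resp.branch_flow_rate(qi, 6), d6)
        assert u == pytest.approx(u_ref, rel=0.01)
        assert resp.reynolds_number(u, d6) == pytest.approx(re_ref, rel=0.01)


def test_reynolds_definition():
    fluid = resp.FluidProperties()
    d = 1e-3
    u = fluid.dynamic_viscosity / (fluid.density * d)
    assert resp.reynolds_number(u, d, fluid) == pytest.approx(1.0)


def test_interpolated_pattern_hits_anchors_and_rejects_range():
    assert resp.interpolate_pattern(5.0).tidal_volume_ml == 181.0
    mid = resp.interpolate_pattern(15.0)
    assert 181.0 < mid.tidal_volume_ml < 500.0
    with pytest.raises(ValueError):
        resp.interpolate_pattern(30.0)


def test_unknown_age_group_rejected():
    with pytest.raises(ValueError):
        resp.breathing_pattern("dog")


def test_phase_flow_object():
    pf = resp.phase_flow(resp.breathing_pattern("adult"), "inspiration", 6)
    assert pf.total_flow_rate_lpm == pytest.approx(18.90)
    assert pf.branch_flow_rate_m3s == pytest.approx(18.90 / 64 * 1e-3 / 60, rel=1e-6)
    with pytest.raises(ValueError):
        resp.phase_flow(resp.breathing_pattern("adult"), "holding")
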