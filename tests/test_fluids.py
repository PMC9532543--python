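"""Tait equation-of-state operations of the working liquid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellhammer import (
    FluidSpec,
    WATER,
    dp_dc_isentropic,
    isentrope_density,
    linearized_density,
    local_sound_speed,
    tait_density,
    tait_pressure,
)


def test_water_bulk_modulus_derived_from_rho0_c0():
    assert WATER.K == pytest.approx(WATER.rho0 * WATER.c0**2, rel=1e-12)


def test_invalid_fluid_constants_rejected():
    with pytest.raises(ValueError):
        FluidSpec(rho0=-1, c0=1439, mu=1e-3, B=3.35e8, gamma=7.15, p0=101325)
    with pytest.raises(ValueError):
        FluidSpec(rho0=999.8, c0=1439, mu=1e-3, B=3.35e8, gamma=0.9, p0=101325)


@pytest.mark.parametrize(
    "rho, expected, rel",
    [
        (999.8, 0.0, 0),            # reference density sits on the datum
        (1000.8, 2.4031e6, 1e-3),   # hand evaluation of the Tait curve
    ],
)
def test_tait_pressure_reference_values(rho, expected, rel):
    assert tait_pressure(WATER, rho) == pytest.approx(expected, rel=rel, abs=1e-9)


def test_tait_pressure_rejects_nonpositive_density():
    with pytest.raises(ValueError):
        tait_pressure(WATER, 0.0)


def test_tait_density_at_zero_pressure_is_rho0():
    assert tait_density(WATER, 0.0) == WATER.rho0


def test_tait_density_of_representative_pulse_is_nearly_incompressible():
    rho = tait_density(WATER, 3.0e6)
    assert WATER.rho0 < rho < 1.01 * WATER.rho0


def test_tait_density_domain_error():
    with pytest.raises(ValueError):
        tait_density(WATER, -WATER.B)


@given(st.floats(min_value=-1e7, max_value=5e7))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_tait_round_trip(p):
    """tait_pressure and tait_density are mutual inverses to 1e-10."""
    assert tait_pressure(WATER, tait_density(WATER, p)) == pytest.approx(
        p, rel=1e-10, abs=1e-4
    )


def test_tait_density_slope_matches_differential_form():
    """drho/dp at p=0 equals the inverse of gamma*(p+B)/rho (FD oracle)."""
    dp = 10.0
    fd = (tait_density(WATER, dp) - tait_density(WATER, -dp)) / (2 * dp)
    analytic = WATER.rho0 / (WATER.gamma * WATER.B)
    assert fd == pytest.approx(analytic, rel=1e-6)


@pytest.mark.parametrize(
    "p, expected",
    [(0.0, 999.8), (1.4387e6, 999.8 + 1.4387e6 / 1439.0**2)],
)
def test_linearized_density_values(p, expected):
    assert linearized_density(WATER, p) == pytest.approx(expected, rel=1e-9)


def test_linearized_density_tracks_isentrope_to_first_order():
    """|linearized - isentrope| / isentrope < 1e-3 for p up to 30 MPa."""
    p = np.linspace(0, 30e6, 121)
    lin = linearized_density(WATER, p)
    ise = isentrope_density(WATER, p)
    assert np.max(np.abs(lin - ise) / ise) < 1e-3


def test_linearized_density_error_is_second_order():
    p = np.array([1e6, 2e6, 4e6])
    err = np.abs(linearized_density(WATER, p) - isentrope_density(WATER, p))
    # quadrupling with doubled pressure => O((p/K)^2)
    assert err[1] / err[0] == pytest.approx(4.0, rel=0.05)
    assert err[2] / err[1] == pytest.approx(4.0, rel=0.05)


def test_sound_speed_reference_state():
    assert local_sound_speed(WATER, p=0.0) == WATER.c0
    assert local_sound_speed(WATER, rho=WATER.rho0) == WATER.c0


def test_sound_speed_monotone_in_compression():
    p = np.linspace(0, 30e6, 61)
    c = local_sound_speed(WATER, p=p)
    assert np.all(np.diff(c) > 0)
    assert local_sound_speed(WATER, rho=1001.0) > WATER.c0


def test_sound_speed_matches_isentrope_slope():
    """c^2 equals dp/drho of the c0-anchored isentrope (FD oracle)."""
    for p0 in (0.0, 5e6, 20e6):
        dp = 100.0
        drho = isentrope_density(WATER, p0 + dp) - isentrope_density(WATER, p0 - dp)
        c_fd = np.sqrt(2 * dp / drho)
        assert local_sound_speed(WATER, p=p0) == pytest.approx(c_fd, rel=1e-6)


def test_sound_speed_requires_exactly_one_state_argument():
    with pytest.raises(ValueError):
        local_sound_speed(WATER)
    with pytest.raises(ValueError):
        local_sound_speed(WATER, p=0.0, rho=999.8)


def test_dp_dc_slope_value_and_sign():
    """(2 gamma/(gamma-1)) (p0+B)/c0 ~ 5.415e5 Pa s/m, always positive."""
    slope = dp_dc_isentropic(WATER)
    assert slope == pytest.approx(5.415e5, rel=1e-3)
    assert slope > 0


def test_dp_dc_consistent_with_integrated_isentrope():
    """FD of p(c) from integrating dp/dc = (2g/(g-1))(p+p0+B)/c matches
    the linearized slope at the reference point within 0.1%."""
    f = WATER
    g = f.gamma
    ref = f.p0 + f.B

    def p_of_c(c):
        # closed-form integral of the slope relation through (0, c0)
        return ref * (c / f.c0) ** (2 * g / (g - 1)) - ref

    dc = 1e-3
    fd = (p_of_c(f.c0 + dc) - p_of_c(f.c0 - dc)) / (2 * dc)
    assert fd == pytest.approx(dp_dc_isentropic(f), rel=1e-3)
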