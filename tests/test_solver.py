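"""Transient method-of-characteristics solver."""

import numpy as np
import pytest

from cellhammer import (
    BOROSILICATE,
    WATER,
    ChannelSpec,
    SourcePulse,
    design_grid,
    monitor,
    peak_attenuation,
    solve,
)
from cellhammer.solver import poiseuille_number


@pytest.fixture(scope="module")
def chan():
    return ChannelSpec(a=3e-3, b=3e-3, e=3e-3, l=60e-3, wall=BOROSILICATE)


@pytest.fixture(scope="module")
def src():
    # ~3 MPa pulse with a 7 us decay time
    return SourcePulse(p_peak=3.0e6, lam=1.41e5, ambient=WATER.p0)


def _grid(cf, total=4.2e-5, dz=2e-4, courant=1.0):
    return design_grid(cf, 0.06, total, dz=dz, courant_target=courant)


def analytic_field(src, cf, z, t):
    """d'Alembert traveling-wave solution for the prescribed inlet pulse."""
    tt, zz = np.meshgrid(t, z, indexing="ij")
    arg = tt - zz / cf
    return np.where(arg >= -1e-15,
                    src.p_peak * np.exp(-src.lam * np.maximum(arg, 0.0)),
                    0.0) + src.ambient


def test_initial_condition_quiescent(chan, src):
    f = solve(WATER, chan, src, _grid(WATER.c0), friction="none")
    assert np.allclose(f.p[0, 1:], src.ambient)
    assert np.allclose(f.u[0, 1:], 0.0)
    assert f.p[0, 0] == src.p_peak + src.ambient


def test_friction_free_solver_matches_dalembert(chan, src):
    """On a Courant-1 grid the friction-free solve equals the analytic
    traveling wave to well below 0.1% of the peak."""
    cf = 1400.0
    f = solve(WATER, chan, src, _grid(cf), friction="none", cf=cf)
    ana = analytic_field(src, cf, f.z, f.t)
    assert np.max(np.abs(f.p - ana)) / src.p_peak < 1e-3


def test_step_inlet_velocity_is_characteristic_invariant(chan):
    """Behind a step front, u = dp/(rho cf) (characteristic relation)."""
    dp = 1e6
    step = SourcePulse(p_peak=dp, lam=1e-9, ambient=WATER.p0)  # ~constant
    cf = WATER.c0
    f = solve(WATER, chan, step, _grid(cf), friction="none", cf=cf)
    n = f.u.shape[0] - 1
    mid = f.u[n, f.u.shape[1] // 2]
    assert mid == pytest.approx(dp / (WATER.rho0 * cf), rel=1e-6)


def test_courant_above_one_refused(chan, src):
    g = design_grid(WATER.c0, 0.06, 4.2e-5, dz=1e-4, dt=0.7e-7)  # C ~ 1.007
    with pytest.raises(ValueError, match="Courant"):
        solve(WATER, chan, src, g)


def test_no_spurious_overshoot(chan, src):
    """Constant-pressure outlet: no sample exceeds inlet peak + ambient
    by more than 0.5%."""
    f = solve(WATER, chan, src, _grid(1400.0, total=1.5e-4), cf=1400.0)
    assert f.p.max() <= (src.p_peak + src.ambient) * 1.005


def test_reflection_coefficients(chan, src):
    """Closed end doubles the incident pressure (R = +1); a constant-
    pressure end reflects with R = -1 (velocity doubling)."""
    cf = 1400.0
    g = _grid(cf, total=1.2e-4)
    closed = solve(WATER, chan, src, g, outlet="closed", friction="none", cf=cf)
    gauge_end = closed.p[:, -1] - src.ambient
    assert gauge_end.max() == pytest.approx(2 * src.p_peak, rel=1e-6)

    open_ = solve(WATER, chan, src, g, outlet="constant_pressure",
                  friction="none", cf=cf)
    u_char = src.p_peak / (WATER.rho0 * cf)
    assert open_.u[:, -1].max() == pytest.approx(2 * u_char, rel=1e-6)
    # outlet pressure pinned at ambient
    assert np.allclose(open_.p[:, -1], src.ambient)


def test_discrete_invariants_conserved_without_friction(chan, src):
    """Riemann invariants propagate unchanged along characteristics."""
    cf = 1400.0
    f = solve(WATER, chan, src, _grid(cf), friction="none", cf=cf)
    rc = WATER.rho0 * cf
    pg = f.p - src.ambient
    jplus = pg + rc * f.u
    # J+ at (i, n) equals J+ at (i-1, n-1) for interior nodes
    assert np.allclose(jplus[1:, 1:-1], jplus[:-1, 0:-2], rtol=0, atol=1e-6)


def test_peak_attenuation_zero_without_friction(chan, src):
    cf = 1400.0
    f = solve(WATER, chan, src, _grid(cf), friction="none", cf=cf)
    assert peak_attenuation(f, 0.015) == pytest.approx(0.0, abs=1e-12)


def test_peak_attenuation_monotone_in_viscosity(chan, src):
    from cellhammer import FluidSpec

    cf = 1400.0
    attens = []
    for mu in (5e-4, 1e-3, 4e-3):
        fl = FluidSpec(rho0=999.8, c0=1439.0, mu=mu, B=3.35e8,
                       gamma=7.15, p0=101325.0)
        f = solve(fl, chan, src, _grid(cf), friction="quasi_steady", cf=cf)
        attens.append(peak_attenuation(f, 0.015, z_min=0.015, z_max=0.045))
    assert attens[0] < attens[1] < attens[2]
    assert attens[-1] > 0


def test_unsteady_friction_attenuates_at_least_as_much(chan, src):
    cf = 1400.0
    g = _grid(cf, dz=4e-4)
    qs = solve(WATER, chan, src, g, friction="quasi_steady", cf=cf)
    un = solve(WATER, chan, src, g, friction="unsteady", cf=cf)
    a_qs = peak_attenuation(qs, 0.015, z_min=0.015, z_max=0.045)
    a_un = peak_attenuation(un, 0.015, z_min=0.015, z_max=0.045)
    assert a_un >= a_qs > 0


def test_monitor_traces(chan, src):
    cf = 1400.0
    f = solve(WATER, chan, src, _grid(cf), friction="none", cf=cf)
    traces = monitor(f, [0.0, 0.045])
    # inlet trace equals pulse + ambient
    assert np.allclose(traces[0].p, src(f.t) + src.ambient)
    # arrival at 0.75 l within one time step of z/cf
    tr = traces[1]
    arrived = np.nonzero(tr.p - src.ambient > 0.5 * src.p_peak)[0]
    t_arr = f.t[arrived[0]]
    assert abs(t_arr - 0.045 / cf) <= f.grid.dt + 1e-15
    assert np.all(tr.tau_x == 0.0)
    with pytest.raises(ValueError):
        monitor(f, [1.0])


def test_monitor_phase_offsets_match_celerity(chan, src):
    """The three canonical monitors show the same waveform shifted by
    the characteristic travel time."""
    cf = 1400.0
    f = solve(WATER, chan, src, _grid(cf, dz=1e-4), friction="none", cf=cf)
    trs = monitor(f, [0.015, 0.030, 0.045])
    lag_steps = round(0.015 / cf / f.grid.dt)
    a, b = trs[0].p, trs[1].p
    assert np.allclose(a[:-lag_steps], b[lag_steps:], rtol=1e-9)


def test_poiseuille_number_limits():
    assert poiseuille_number(1.0) == pytest.approx(56.91, rel=5e-3)
    assert poiseuille_number(1e-6) == pytest.approx(96.0, rel=1e-3)
    with pytest.raises(ValueError):
        poiseuille_number(1.5)
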