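"""Weak-shock Rankine-Hugoniot jump conditions in the working liquid.

A projectile impact launches a *weak* compression front: the pressure
jump (a few MPa) is small against the liquid's bulk modulus (~2 GPa),
heating across the front is negligible, and the jump may be treated as
isentropic.  This module computes the front speed, the particle velocity
behind the front and the density ratio, and provides an exact
conservation residual that the tests use as an independent oracle.

Frame convention: laboratory frame with the fluid ahead of the front at
rest (``u_up = 0`` by default); front-fixed quantities are formed
internally.  Rarefactions (``p_down < p_up``) are rejected, not
mishandled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluids import FluidSpec, isentrope_density

__all__ = [
    "ShockState",
    "WeakShockSpeed",
    "ParticleVelocity",
    "shock_speed_isentropic",
    "particle_velocity",
    "shock_speed_weak",
    "density_ratio",
    "jump_residuals",
    "make_jump_state",
]


@dataclass(frozen=True)
class ShockState:
    """Complete state across a compression front (SI units).

    ``_up`` fields are ahead of the front (pre-shock), ``_down`` behind
    it; pressures are on the Tait datum; ``cs`` is the front speed in the
    laboratory frame.
    """

    p_up: float
    p_down: float
    rho_up: float
    rho_down: float
    u_up: float
    u_down: float
    cs: float


@dataclass(frozen=True)
class ParticleVelocity:
    """Particle velocity behind the front, both closures.

    ``acoustic`` is the linear form ``dp / (rho0 c0)``; ``exact`` is the
    mass-flux form ``(rho - rho0)/rho * cs`` on the isentrope.
    """

    acoustic: float
    exact: float


@dataclass(frozen=True)
class WeakShockSpeed:
    """Front speed from the particle velocity: exact and linearized.

    ``exact`` evaluates ``c0 (1 + gamma u / c0)**((gamma-1)/(2 gamma))``;
    ``linearized`` is its first-order Taylor form
    ``c0 + (gamma-1)/2 * u``.  They differ at O(u^2).
    """

    exact: float
    linearized: float


def shock_speed_isentropic(fluid: FluidSpec, p_behind: float) -> float:
    """Front speed ``sqrt((rho1/rho0) * dp/drho_jump)`` for a jump to ``p_behind``.

    ``p_behind`` is the Tait-datum (gauge) pressure behind the front; the
    density behind is taken on the c0-anchored isentrope.  The result is
    >= c0, tending to c0 in the acoustic limit.
    """
    if p_behind < 0:
        raise ValueError("rarefaction fronts are not supported (p_behind < 0)")
    if p_behind == 0.0:
        return fluid.c0
    rho1 = isentrope_density(fluid, p_behind)
    return float(np.sqrt((rho1 / fluid.rho0) * p_behind / (rho1 - fluid.rho0)))


def particle_velocity(fluid: FluidSpec, p_behind: float) -> ParticleVelocity:
    """Particle velocity behind a front at Tait-datum pressure ``p_behind``."""
    if p_behind < 0:
        raise ValueError("rarefaction fronts are not supported (p_behind < 0)")
    acoustic = p_behind / fluid.impedance
    if p_behind == 0.0:
        return ParticleVelocity(0.0, 0.0)
    rho1 = isentrope_density(fluid, p_behind)
    cs = shock_speed_isentropic(fluid, p_behind)
    exact = (rho1 - fluid.rho0) / rho1 * cs
    return ParticleVelocity(acoustic=acoustic, exact=exact)


def shock_speed_weak(fluid: FluidSpec, u: float) -> WeakShockSpeed:
    """Front speed as a function of particle velocity, weak-shock closure."""
    if u < 0:
        raise ValueError("particle velocity must be nonnegative")
    g = fluid.gamma
    expo = (g - 1.0) / (2.0 * g)
    exact = fluid.c0 * (1.0 + g * u / fluid.c0) ** expo
    linearized = fluid.c0 + 0.5 * (g - 1.0) * u
    return WeakShockSpeed(exact=float(exact), linearized=float(linearized))


def density_ratio(fluid: FluidSpec, p_up: float, p_down: float) -> float:
    """Polytropic Hugoniot density ratio across the front.

    ``((g+1) p1 + (g-1) p0) / ((g+1) p0 + (g-1) p1)`` with absolute
    pressures; equals 1 for no jump and exceeds 1 iff ``p_down > p_up``.
    Kept for completeness — the solver path uses the isentrope forms.
    """
    if p_up <= 0 or p_down <= 0:
        raise ValueError("pressures must be positive (absolute scale)")
    g = fluid.gamma
    return ((g + 1.0) * p_down + (g - 1.0) * p_up) / (
        (g + 1.0) * p_up + (g - 1.0) * p_down
    )


def make_jump_state(fluid: FluidSpec, dp: float) -> ShockState:
    """Build the self-consistent lab-frame jump state for a pressure rise ``dp``."""
    cs = shock_speed_isentropic(fluid, dp)
    u1 = particle_velocity(fluid, dp).exact
    rho1 = isentrope_density(fluid, dp)
    return ShockState(
        p_up=0.0,
        p_down=dp,
        rho_up=fluid.rho0,
        rho_down=float(rho1),
        u_up=0.0,
        u_down=float(u1),
        cs=float(cs),
    )


def _enthalpy(fluid: FluidSpec, p: float) -> float:
    # Isentropic enthalpy h = int dp/rho along the c0-anchored isentrope.
    g = fluid.gamma
    return (fluid.K / (fluid.rho0 * (g - 1.0))) * (
        (1.0 + g * p / fluid.K) ** ((g - 1.0) / g) - 1.0
    )


def jump_residuals(state: ShockState, fluid: FluidSpec) -> tuple[float, float, float]:
    """Normalized (mass, momentum, energy) residuals in the front-fixed frame.

    mass:     rho0 (u0 - cs) - rho1 (u1 - cs), over rho0 * cs
    momentum: [p + rho (u - cs)^2] jump, over rho0 * cs^2
    energy:   [(u - cs)^2 / 2 + h(p)] jump, over cs^2 / 2
    with ``h`` the isentropic enthalpy of the liquid.  A uniform state
    returns exactly (0, 0, 0); a self-consistent weak jump has mass and
    momentum residuals at machine precision and a small energy residual
    of O((dp/K)^3) from the isentropic approximation.
    """
    w0 = state.u_up - state.cs
    w1 = state.u_down - state.cs
    mass = state.rho_up * w0 - state.rho_down * w1
    mom = (state.p_up + state.rho_up * w0**2) - (state.p_down + state.rho_down * w1**2)
    en = (0.5 * w0**2 + _enthalpy(fluid, state.p_up)) - (
        0.5 * w1**2 + _enthalpy(fluid, state.p_down)
    )
    cs = state.cs if state.cs != 0 else fluid.c0
    return (
        mass / (fluid.rho0 * cs),
        mom / (fluid.rho0 * cs**2),
        en / (0.5 * cs**2),
    )
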