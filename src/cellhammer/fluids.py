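"""Tait-equation thermodynamics of the working liquid.

The liquid in the channel is described by the empirical Tait equation of
state ``p = B ((rho/rho0)**gamma - 1)`` with pressure constant ``B`` and
adiabatic exponent ``gamma``.  All equation-of-state operations in this
module work on the *Tait datum*: pressure is measured from the reference
state ``(rho0, p=0)``, and the ambient (absolute) pressure ``p0`` is
carried separately as an explicit offset by the solver and the reports.
This avoids silently counting the ambient pressure twice.

A note on internal consistency: the standard handbook constants
``B = 3.35e8 Pa`` and ``gamma = 7.15`` imply a small-signal sound speed
``sqrt(gamma*B/rho0) ~ 1548 m/s``, which differs from the measured
reference sound speed ``c0 = 1439 m/s`` by ~7%.  The package treats
``(rho0, c0, gamma, B)`` as four independent given constants: the Tait
curve (``tait_pressure`` / ``tait_density``) keeps the literal ``B``,
while everything that controls wave dynamics — the local sound speed,
the isentropic ``dp/dc`` slope and the jump conditions — is anchored to
the measured ``c0``.  ``c0`` is never derived from ``p0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidSpec",
    "WATER",
    "tait_pressure",
    "tait_density",
    "linearized_density",
    "isentrope_density",
    "local_sound_speed",
    "dp_dc_isentropic",
]


@dataclass(frozen=True)
class FluidSpec:
    """Working-liquid state and equation-of-state constants (SI units).

    Parameters
    ----------
    rho0 : float
        Reference density (kg m^-3).
    c0 : float
        Reference (small-signal) sound speed (m s^-1).
    mu : float
        Dynamic viscosity (Pa s).
    B : float
        Tait pressure constant (Pa).
    gamma : float
        Tait adiabatic exponent (dimensionless, > 1).
    p0 : float
        Reference ambient absolute pressure (Pa).

    The bulk modulus ``K = rho0 * c0**2`` is derived, never set
    independently.
    """

    rho0: float
    c0: float
    mu: float
    B: float
    gamma: float
    p0: float
    K: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("rho0", "c0", "mu", "B", "gamma", "p0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FluidSpec.{name} must be strictly positive")
        if self.gamma <= 1:
            raise ValueError("Tait exponent gamma must exceed 1")
        object.__setattr__(self, "K", self.rho0 * self.c0**2)

    @property
    def nu(self) -> float:
        """Kinematic viscosity (m^2 s^-1)."""
        return self.mu / self.rho0

    @property
    def impedance(self) -> float:
        """Acoustic impedance ``rho0 * c0`` (Pa s m^-1)."""
        return self.rho0 * self.c0


#: Water at normal laboratory conditions.  Density, sound speed and the
#: Tait constants are the standard values for water near 10-20 degC;
#: viscosity is 1.0e-3 Pa s (nu = 1.0e-6 m^2/s).
WATER = FluidSpec(
    rho0=999.8,
    c0=1439.0,
    mu=1.0e-3,
    B=3.35e8,
    gamma=7.15,
    p0=101325.0,
)


def tait_pressure(fluid: FluidSpec, rho) -> float | np.ndarray:
    """Tait pressure ``B ((rho/rho0)**gamma - 1)`` on the Tait datum.

    Returns 0 at ``rho == rho0``; raises for non-positive density.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be strictly positive")
    out = fluid.B * ((rho / fluid.rho0) ** fluid.gamma - 1.0)
    return out.item() if out.ndim == 0 else out


def tait_density(fluid: FluidSpec, p) -> float | np.ndarray:
    """Inverse of :func:`tait_pressure`: ``rho0 ((p+B)/B)**(1/gamma)``.

    Strictly increasing in ``p``; the domain is ``p > -B``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= -fluid.B):
        raise ValueError("pressure must exceed -B (Tait domain)")
    out = fluid.rho0 * ((p + fluid.B) / fluid.B) ** (1.0 / fluid.gamma)
    return out.item() if out.ndim == 0 else out


def linearized_density(fluid: FluidSpec, p) -> float | np.ndarray:
    """Acoustic (first-order) density ``rho0 + p / c0**2``.

    Valid for ``|p| << K``; agrees with the isentrope to O((p/K)^2).
    """
    p = np.asarray(p, dtype=float)
    out = fluid.rho0 + p / fluid.c0**2
    return out.item() if out.ndim == 0 else out


def isentrope_density(fluid: FluidSpec, p) -> float | np.ndarray:
    """Density on the c0-anchored isentrope, ``rho0 (1 + gamma p / K)**(1/gamma)``.

    This is the Tait functional form with its small-signal modulus forced
    to equal ``K = rho0 c0**2`` exactly, so that ``sqrt(dp/drho) -> c0``
    as ``p -> 0``.  The wave-dynamics operations (shock jumps, particle
    velocity) use this curve rather than the literal-B Tait curve; see
    the module docstring for why the two cannot both honour ``c0``.
    """
    p = np.asarray(p, dtype=float)
    arg = 1.0 + fluid.gamma * p / fluid.K
    if np.any(arg <= 0):
        raise ValueError("pressure below the isentrope domain")
    out = fluid.rho0 * arg ** (1.0 / fluid.gamma)
    return out.item() if out.ndim == 0 else out


def local_sound_speed(fluid: FluidSpec, p=None, rho=None) -> float | np.ndarray:
    """Local sound speed on the c0-anchored isentrope.

    ``c(p) = c0 (1 + gamma p / K)**((gamma-1)/(2 gamma))``, equivalently
    ``c(rho) = c0 (rho/rho0)**((gamma-1)/2)`` on the same curve, with
    ``p`` on the Tait datum.  At the reference state the speed is exactly
    ``c0`` and ``c**2`` equals ``dp/drho`` of :func:`isentrope_density`;
    monotone nondecreasing in compression.  Give exactly one of ``p`` or
    ``rho``.
    """
    if (p is None) == (rho is None):
        raise ValueError("give exactly one of p or rho")
    expo = (fluid.gamma - 1.0) / (2.0 * fluid.gamma)
    if p is None:
        rho = np.asarray(rho, dtype=float)
        if np.any(rho <= 0):
            raise ValueError("density must be strictly positive")
        out = fluid.c0 * (rho / fluid.rho0) ** ((fluid.gamma - 1.0) / 2.0)
    else:
        p = np.asarray(p, dtype=float)
        arg = 1.0 + fluid.gamma * p / fluid.K
        if np.any(arg <= 0):
            raise ValueError("state outside the equation-of-state domain")
        out = fluid.c0 * arg**expo
    return out.item() if out.ndim == 0 else out


def dp_dc_isentropic(fluid: FluidSpec) -> float:
    """Isentropic slope ``(dp/dc)_s = (2 gamma/(gamma-1)) (p0 + B)/c0``.

    Evaluated once at normal conditions (linear approximation); this is
    the slope that sets the decay constant of the impact pressure pulse.
    For water it is ~5.4e5 Pa per (m/s).
    """
    g = fluid.gamma
    return (2.0 * g / (g - 1.0)) * (fluid.p0 + fluid.B) / fluid.c0
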