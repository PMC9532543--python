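"""Impact-generated inlet pressure pulse.

A projectile of mass ``mp`` and cross-section ``Ap`` strikes the fluid
column at velocity ``up``.  Pressure-velocity (impedance) matching at
the interface sets the initial amplitude

    p(0) = Zf * Zp / (Zf + Zp) * up ,

and Newton's second law for the decelerating projectile, closed with the
linearized isentropic slope ``(dp/dc)_s`` of the liquid, gives an
exponential pulse

    p(t) = p(0) * exp(-lambda * t),
    lambda = (gamma - 1)/2 * (Ap / mp) * (dp/dc)_s .

The buffer plate between projectile and fluid is impedance-matched to
the projectile and therefore not modelled (the projectile strikes the
fluid directly).  ``integrate_projectile_ode`` re-derives the pulse by
explicit step-by-step integration of the projectile's equation of motion
and serves as the independent oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluids import FluidSpec, dp_dc_isentropic
from .materials import SolidMaterial

__all__ = [
    "ProjectileSpec",
    "SourcePulse",
    "impedance",
    "matched_amplitude",
    "decay_constant",
    "pulse",
    "evaluate",
    "integrate_projectile_ode",
]


@dataclass(frozen=True)
class ProjectileSpec:
    """Projectile geometry, material and impact velocity (SI units).

    If ``mass`` is omitted it is derived as ``rho_s * length * area``.
    ``use_bar_speed`` switches the impedance match from the material's
    longitudinal bulk speed to the slender-rod speed ``sqrt(E/rho)``.
    """

    material: SolidMaterial
    length: float
    area: float
    up: float
    mass: float | None = None
    use_bar_speed: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0 or self.area <= 0:
            raise ValueError("projectile length and area must be positive")
        if self.up < 0:
            raise ValueError("impact velocity must be nonnegative")
        if self.mass is None:
            object.__setattr__(
                self, "mass", self.material.rho_s * self.length * self.area
            )
        elif self.mass <= 0:
            raise ValueError("projectile mass must be positive")

    @property
    def wave_speed(self) -> float:
        return self.material.bar_speed if self.use_bar_speed else self.material.c_s

    @property
    def impedance(self) -> float:
        """Acoustic impedance ``rho_s * c`` of the projectile (Pa s m^-1)."""
        return self.material.rho_s * self.wave_speed


@dataclass(frozen=True)
class SourcePulse:
    """Exponential inlet pressure pulse ``p(t) = p_peak exp(-lam t)`` (gauge).

    ``ambient`` records the absolute offset p0 so reports can quote total
    pressure.
    """

    p_peak: float
    lam: float
    ambient: float

    def __post_init__(self) -> None:
        if self.p_peak < 0:
            raise ValueError("pulse amplitude must be nonnegative")
        if self.lam <= 0:
            raise ValueError("decay constant must be strictly positive")

    def __call__(self, t) -> float | np.ndarray:
        return evaluate(self, t)

    @property
    def decay_time(self) -> float:
        """1/e time constant (s)."""
        return 1.0 / self.lam


def impedance(material: SolidMaterial | FluidSpec | ProjectileSpec) -> float:
    """Acoustic impedance rho*c of a solid, fluid or projectile (Pa s m^-1)."""
    return material.impedance


def matched_amplitude(fluid: FluidSpec, proj: ProjectileSpec,
                      fluid_impedance: float | None = None) -> float:
    """Impedance-matched initial pressure jump (gauge, Pa).

    ``Zf Zp / (Zf + Zp) * up``; tends to the rigid-projectile Joukowsky
    value ``Zf * up`` as ``Zp -> inf``.  Pass ``fluid_impedance`` to use
    a conduit-corrected value ``rho0 * cf`` instead of ``rho0 * c0``.
    """
    zf = fluid.impedance if fluid_impedance is None else fluid_impedance
    zp = proj.impedance
    return zf * zp / (zf + zp) * proj.up


def decay_constant(fluid: FluidSpec, proj: ProjectileSpec) -> float:
    """Pulse decay constant ``(gamma-1)/2 * (Ap/mp) * (dp/dc)_s`` (s^-1).

    Independent of the impact velocity; halves when the projectile
    length (hence mass) doubles at fixed cross-section.
    """
    lam = (
        0.5 * (fluid.gamma - 1.0) * (proj.area / proj.mass) * dp_dc_isentropic(fluid)
    )
    if lam <= 0:
        raise ValueError("degenerate projectile gives non-positive decay constant")
    return lam


def pulse(fluid: FluidSpec, proj: ProjectileSpec,
          fluid_impedance: float | None = None) -> SourcePulse:
    """Build the inlet :class:`SourcePulse` for a given fluid and projectile."""
    return SourcePulse(
        p_peak=matched_amplitude(fluid, proj, fluid_impedance),
        lam=decay_constant(fluid, proj),
        ambient=fluid.p0,
    )


def evaluate(src: SourcePulse, t) -> float | np.ndarray:
    """Gauge pulse pressure at time ``t >= 0`` (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("pulse is defined for t >= 0")
    out = src.p_peak * np.exp(-src.lam * t)
    return out.item() if out.ndim == 0 else out


def integrate_projectile_ode(
    fluid: FluidSpec,
    proj: ProjectileSpec,
    t_end: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicitly integrate the projectile deceleration; return (t, p).

    Newton's law ``mp du/dt = -p(t) Ap`` closed with the linearized
    pressure-velocity relation ``p = (gamma-1)/2 * (dp/dc)_s * u`` is
    stepped with a plain midpoint rule.  This is the brute-force oracle
    for the closed-form exponential pulse: same decay constant, with
    interface pressure proportional to the instantaneous projectile
    velocity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    kappa = 0.5 * (fluid.gamma - 1.0) * dp_dc_isentropic(fluid)  # Pa per (m/s)
    n = int(np.ceil(t_end / dt)) + 1
    t = np.arange(n) * dt
    u = np.empty(n)
    u[0] = proj.up
    coef = kappa * proj.area / proj.mass
    for i in range(n - 1):
        # midpoint (RK2) step of du/dt = -coef * u
        u_half = u[i] - 0.5 * dt * coef * u[i]
        u[i + 1] = u[i] - dt * coef * u_half
    return t, kappa * u
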