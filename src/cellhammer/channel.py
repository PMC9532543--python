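"""Conduit acoustics and design criteria for the rectangular channel.

A pressure surge travels along a liquid-filled conduit at a celerity
``cf`` below the free-fluid sound speed ``c0`` because the walls are
compliant: ``1/(rho cf^2) = 1/K + (1/A) dA/dp``.  For a thick-walled
rectangular duct the distensibility ``(1/A) dA/dp`` is evaluated here
from closed-frame mechanics and expressed as a single compliance factor
``Phi(a, b)`` so that

    cf = 1 / sqrt(rho * (1/K + Phi(a, b) / (a b E e^3))).

The module also provides the corrected bulk modulus ``Kmod = rho0 cf^2``
that lets a rigid-wall solver mimic the compliant-wall celerity, the
Pinnington fluid-loading number ``beta`` that justifies the rigid-wall
treatment when << 1, the Knudsen continuum check, and Courant-criterion
grid design.

Derivation of ``Phi`` (the published rendering of this factor is
typographically corrupted, so it is re-derived here from first
principles; each term is labelled):

* wall bending — each wall is a beam strip of flexural rigidity
  E e^3/12 in a closed frame with rigid corners; a uniform internal
  pressure w gives the classic corner moment
  ``M = w (a^3 + b^3) / (12 (a + b))``, and integrating the outward
  deflection of all four walls yields the area gain
  ``(a^5 + b^5)/5 - (a^3 + b^3)^2 / (6 (a + b))`` (over a b E e^3);
* transverse shear — Timoshenko shear deflection with shear area
  (5/6) e adds ``(E/G) e^2 (a^3 + b^3) / 5``;
* membrane stretch — wall tension p*(opposite span)/2 elongates the
  perimeter and adds ``a b (a + b) e^2 / 2``.

All three terms are positive, symmetric under a <-> b, and vanish from
the celerity as E -> inf (rigid limit cf -> c0) or as e grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

from .fluids import FluidSpec
from .materials import SolidMaterial

__all__ = [
    "ChannelSpec",
    "AcousticsReport",
    "GridSpec",
    "phi_thorley",
    "celerity_rect",
    "celerity_general",
    "corrected_bulk_modulus",
    "fluid_loading",
    "knudsen",
    "design_grid",
    "acoustics_report",
]

#: Default mean free path of a liquid (m): molecular scale of water.
DEFAULT_MEAN_FREE_PATH = 3.0e-10

#: "beta << 1" quantified: below this the channel is flagged rigid.
RIGID_BETA_THRESHOLD = 0.1

#: Continuum (Navier-Stokes + no-slip) validity threshold on Kn.
CONTINUUM_KN_THRESHOLD = 1.0e-3


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular conduit: cross-section a x b, wall thickness e, length l.

    ``a`` is the long side (a >= b).  ``delta_cell`` is the average
    height of cultured cells (report-only; the wall is modelled
    hydraulically smooth) and ``rho_cell_note`` a qualitative density
    flag (none/sparse/confluent).
    """

    a: float
    b: float
    e: float
    l: float
    wall: SolidMaterial
    delta_cell: float = 1.0e-5
    rho_cell_note: str = "none"

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")
        if self.e <= 0 or self.l <= 0:
            raise ValueError("wall thickness and length must be positive")

    @property
    def area(self) -> float:
        """Cross-section area a*b (m^2)."""
        return self.a * self.b

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.a + self.b)

    @property
    def hydraulic_diameter(self) -> float:
        """4 A / P (m); equals the side length for a square duct."""
        return 4.0 * self.area / self.perimeter

    @property
    def mean_radius(self) -> float:
        """Round-duct-equivalent mean radius 2 A / P (m)."""
        return 2.0 * self.area / self.perimeter


@dataclass(frozen=True)
class AcousticsReport:
    """Derived conduit acoustics and the design criteria flags."""

    cf: float
    Kmod: float
    beta: float
    Kn: float
    rigid_ok: bool
    continuum_ok: bool


@dataclass(frozen=True)
class GridSpec:
    """Axial/temporal discretization with its Courant number."""

    dz: float
    dt: float
    courant: float
    nz: int
    nt: int


def phi_thorley(a: float, b: float, e: float, wall: SolidMaterial) -> float:
    """Rectangular thick-walled duct compliance factor Phi(a, b) (m^5).

    Defined so that ``(1/A) dA/dp = Phi / (a b E e^3)``.  Positive and
    symmetric in a, b by construction.
    """
    if a <= 0 or b <= 0 or e <= 0:
        raise ValueError("degenerate duct geometry")
    bending = (a**5 + b**5) / 5.0 - (a**3 + b**3) ** 2 / (6.0 * (a + b))
    shear = (wall.E / wall.G) * e**2 * (a**3 + b**3) / 5.0
    stretch = a * b * (a + b) * e**2 / 2.0
    return bending + shear + stretch


def celerity_rect(fluid: FluidSpec, ch: ChannelSpec) -> float:
    """Pressure-wave celerity cf (m/s) in the rectangular channel.

    Reduces to c0 in the rigid-wall limit (E -> inf); increases with
    wall modulus and thickness.
    """
    phi = phi_thorley(ch.a, ch.b, ch.e, ch.wall)
    distensibility = phi / (ch.a * ch.b * ch.wall.E * ch.e**3)
    return celerity_general(fluid, distensibility)


def celerity_general(fluid: FluidSpec, dA_dp_over_A: float) -> float:
    """Celerity for an arbitrary conduit given its distensibility (1/Pa).

    ``cf = 1/sqrt(rho (1/K + (1/A) dA/dp))``; the rigid case
    ``dA/dp = 0`` returns exactly c0.
    """
    if dA_dp_over_A < 0:
        raise ValueError("distensibility must be nonnegative")
    return 1.0 / sqrt(fluid.rho0 * (1.0 / fluid.K + dA_dp_over_A))


def corrected_bulk_modulus(fluid: FluidSpec, cf: float) -> float:
    """Corrected bulk modulus ``Kmod = rho0 cf^2`` (Pa).

    Feeding Kmod to a rigid-wall solver reproduces the compliant-wall
    celerity: sqrt(Kmod/rho0) = cf exactly.
    """
    if cf <= 0:
        raise ValueError("celerity must be positive")
    return fluid.rho0 * cf**2


def fluid_loading(fluid: FluidSpec, ch: ChannelSpec, cf: float | None = None) -> float:
    """Pinnington fluid-loading number beta (dimensionless).

    ``beta = (cf^2/cs^2)(rho_f/rho_s)(2R/e)`` with R the round-duct
    equivalent mean radius of the section; beta << 1 means the channel
    behaves rigidly for the passing surge.
    """
    if cf is None:
        cf = celerity_rect(fluid, ch)
    w = ch.wall
    return (cf**2 / w.c_s**2) * (fluid.rho0 / w.rho_s) * (2.0 * ch.mean_radius / ch.e)


def knudsen(l_char: float, mean_free_path: float = DEFAULT_MEAN_FREE_PATH) -> float:
    """Knudsen number mean_free_path / l_char (dimensionless)."""
    if l_char <= 0 or mean_free_path <= 0:
        raise ValueError("lengths must be positive")
    return mean_free_path / l_char


def design_grid(
    cf: float,
    l: float,
    total_time: float,
    dz: float,
    dt: float | None = None,
    courant_target: float | None = None,
) -> GridSpec:
    """Build a grid from (dz, dt) or from (dz, Courant target).

    With a target, ``dt = target * dz / cf`` exactly (target 1 gives the
    interpolation-free characteristic-aligned step).  ``nz = l/dz`` and
    ``nt = total_time/dt`` are rounded to the nearest integer.
    """
    if min(cf, l, total_time, dz) <= 0:
        raise ValueError("grid inputs must be positive")
    if (dt is None) == (courant_target is None):
        raise ValueError("give exactly one of dt or courant_target")
    if dt is None:
        if courant_target <= 0:
            raise ValueError("Courant target must be positive")
        dt = courant_target * dz / cf
    courant = cf * dt / dz
    return GridSpec(
        dz=dz,
        dt=dt,
        courant=courant,
        nz=int(round(l / dz)),
        nt=int(round(total_time / dt)),
    )


def acoustics_report(
    fluid: FluidSpec,
    ch: ChannelSpec,
    mean_free_path: float = DEFAULT_MEAN_FREE_PATH,
    rigid_walls: bool = False,
) -> AcousticsReport:
    """Assemble celerity, Kmod, beta, Kn and the pass/fail design flags.

    ``rigid_walls=True`` skips the celerity correction (cf = c0), used
    when the wall compliance is unknown and assumed negligible.
    """
    cf = fluid.c0 if rigid_walls else celerity_rect(fluid, ch)
    kn = knudsen(ch.b, mean_free_path)
    beta = fluid_loading(fluid, ch, cf)
    return AcousticsReport(
        cf=cf,
        Kmod=corrected_bulk_modulus(fluid, cf),
        beta=beta,
        Kn=kn,
        rigid_ok=beta < RIGID_BETA_THRESHOLD,
        continuum_ok=kn < CONTINUUM_KN_THRESHOLD,
    )
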