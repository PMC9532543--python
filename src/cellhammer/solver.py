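"""1D transient water-hammer solver (method of characteristics).

The channel is acoustically one-dimensional: rigid walls (compliance
folded into the celerity ``cf``), uniform cross-section, and a weak
compression pulse, so the area-averaged continuity/momentum pair reduces
to the classic water-hammer equations

    dp/dt + rho cf^2 du/dz = 0
    du/dt + (1/rho) dp/dz + F(u) = 0

integrated along the characteristics dz/dt = +/- cf.  On a grid with
Courant number cf*dt/dz = 1 the scheme is interpolation-free and
propagates the d'Alembert solution exactly; for Courant < 1 the
characteristic feet are linearly interpolated (slightly diffusive).
Courant > 1 is refused outright.

``F(u)`` is the quasi-steady laminar wall-friction deceleration
``(Po/2) nu u / Dh^2`` with the rectangular-duct Poiseuille number
(Po = 56.91 for a square section); an unsteady (Zielke
convolution-kernel) closure is available behind a flag.

Boundary conditions: the impact :class:`~cellhammer.source.SourcePulse`
sets the inlet pressure; the outlet is either held at ambient pressure
(reservoir, reflection coefficient -1) or closed (u = 0, reflection
coefficient +1, pressure doubling).  Pressure fields are stored as
*total* (ambient included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ChannelSpec, GridSpec
from .fluids import FluidSpec
from .source import SourcePulse

__all__ = ["WaveField", "MonitorTrace", "solve", "peak_attenuation", "monitor"]


def poiseuille_number(aspect: float) -> float:
    """Laminar f*Re product for a rectangular duct of aspect ratio b/a <= 1.

    Shah-London polynomial fit; 56.91 for a square duct, 96 in the
    parallel-plate limit.
    """
    if not 0 < aspect <= 1:
        raise ValueError("aspect ratio must be in (0, 1]")
    s = aspect
    return 96.0 * (
        1 - 1.3553 * s + 1.9467 * s**2 - 1.7012 * s**3 + 0.9564 * s**4 - 0.2537 * s**5
    )


@dataclass
class WaveField:
    """Discretized p(z, t) (total, Pa) and u(z, t) (m/s) on the grid."""

    z: np.ndarray
    t: np.ndarray
    p: np.ndarray  # shape (nt+1, nz+1), total pressure
    u: np.ndarray  # shape (nt+1, nz+1), axial velocity
    cf: float
    ambient: float
    fluid: FluidSpec
    channel: ChannelSpec
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def peak_pressure(self) -> np.ndarray:
        """Per-node peak total pressure over the run (Pa)."""
        return self.p.max(axis=0)

    def nearest_index(self, z: float) -> int:
        return int(np.argmin(np.abs(self.z - z)))


@dataclass
class MonitorTrace:
    """Time histories at one monitor point on the cell-culture wall.

    ``tau_x`` is identically zero: the 1D model has no transverse flow,
    consistent with transverse shear being negligible in this geometry.
    """

    z: float
    z_frac: float
    t: np.ndarray
    p: np.ndarray       # total pressure (Pa)
    u: np.ndarray       # axial core velocity (m/s)
    tau_x: np.ndarray   # transverse shear, identically 0 (Pa)


_ZIELKE_N = np.array([26.3744, 70.8493, 135.0198, 218.9216, 322.5544])
_ZIELKE_M = np.array([0.282095, -1.25, 1.057855, 0.9375, 0.396696, -0.351563])


def _zielke_weight(tau: np.ndarray) -> np.ndarray:
    """Zielke weighting function W(tau), tau = 4 nu t / Dh^2 > 0."""
    tau = np.asarray(tau, dtype=float)
    w = np.empty_like(tau)
    small = tau <= 0.02
    ts = tau[small]
    w[small] = sum(m * ts ** ((j - 1) / 2.0) for j, m in enumerate(_ZIELKE_M, start=1))
    tl = tau[~small]
    w[~small] = np.exp(-_ZIELKE_N[:, None] * tl[None, :]).sum(axis=0)
    return w


def solve(
    fluid: FluidSpec,
    ch: ChannelSpec,
    pulse: SourcePulse,
    grid: GridSpec,
    outlet: str = "constant_pressure",
    friction: str = "quasi_steady",
    cf: float | None = None,
) -> WaveField:
    """March the characteristics over ``grid`` and return the wave field.

    Parameters
    ----------
    outlet : {"constant_pressure", "closed"}
        Reservoir at ambient pressure, or a dead end.
    friction : {"none", "quasi_steady", "unsteady"}
        Wall-friction closure; "unsteady" adds the Zielke
        convolution-kernel term on top of the quasi-steady part.
    cf : float, optional
        Override the celerity (defaults to ``grid.courant * dz / dt``,
        i.e. the celerity the grid was designed for).
    """
    if outlet not in ("constant_pressure", "closed"):
        raise ValueError(f"unknown outlet type: {outlet!r}")
    if friction not in ("none", "quasi_steady", "unsteady"):
        raise ValueError(f"unknown friction model: {friction!r}")
    if cf is None:
        cf = grid.courant * grid.dz / grid.dt
    C = cf * grid.dt / grid.dz
    if C > 1.0 + 1e-12:
        raise ValueError(
            f"Courant number {C:.4f} exceeds 1: refusing to run (unstable)"
        )

    nz, nt, dt = grid.nz, grid.nt, grid.dt
    z = np.arange(nz + 1) * grid.dz
    t = np.arange(nt + 1) * dt
    rho_cf = fluid.rho0 * cf

    # quasi-steady laminar friction deceleration coefficient k: F = k * u
    if friction == "none":
        k_fric = 0.0
    else:
        po = poiseuille_number(ch.b / ch.a)
        k_fric = 0.5 * po * fluid.nu / ch.hydraulic_diameter**2

    unsteady = friction == "unsteady"
    if unsteady:
        k_unst = 4.0 * fluid.nu / ch.hydraulic_diameter**2  # tau per second
        du_hist = np.zeros((nt, nz + 1))

    # gauge pressure during the march; ambient added at the end.  The
    # fluid starts quiescent; the inlet corner (z=0, t=0) takes the
    # boundary-consistent state u = p(0)/(rho cf) — the impact sets the
    # interface velocity instantaneously, and the C+ invariant leaving
    # the corner then carries the full pulse amplitude.
    p = np.zeros((nt + 1, nz + 1))
    u = np.zeros((nt + 1, nz + 1))
    p[0, 0] = pulse(0.0)
    u[0, 0] = p[0, 0] / rho_cf

    for n in range(nt):
        pn, un = p[n], u[n]
        if unsteady and n > 0:
            tau = k_unst * dt * (np.arange(n, 0, -1) - 0.5)
            conv = _zielke_weight(tau) @ du_hist[:n]  # shape (nz+1,)
            # Zielke deceleration 16 nu/Dh^2 * sum W*du, folded as F*dt
            f_extra = 4.0 * k_unst * conv * dt
        else:
            f_extra = np.zeros(nz + 1)

        # characteristic feet with linear interpolation (exact at C = 1)
        pA = (1.0 - C) * pn[1:] + C * pn[:-1]   # foot of C+ for nodes 1..nz
        uA = (1.0 - C) * un[1:] + C * un[:-1]
        pB = (1.0 - C) * pn[:-1] + C * pn[1:]   # foot of C- for nodes 0..nz-1
        uB = (1.0 - C) * un[:-1] + C * un[1:]
        fA = k_fric * uA * dt
        fB = k_fric * uB * dt
        if unsteady:
            fA = fA + ((1.0 - C) * f_extra[1:] + C * f_extra[:-1])
            fB = fB + ((1.0 - C) * f_extra[:-1] + C * f_extra[1:])

        # interior nodes 1..nz-1: C+ from the left foot, C- from the right
        cp_p, cp_u, cp_f = pA[:-1], uA[:-1], fA[:-1]
        cm_p, cm_u, cm_f = pB[1:], uB[1:], fB[1:]
        p[n + 1, 1:nz] = 0.5 * (
            cp_p + cm_p + rho_cf * (cp_u - cm_u) - rho_cf * (cp_f - cm_f)
        )
        u[n + 1, 1:nz] = 0.5 * (
            (cp_p - cm_p) / rho_cf + cp_u + cm_u - (cp_f + cm_f)
        )

        # inlet: pressure prescribed by the impact pulse, u from C-
        p[n + 1, 0] = pulse(t[n + 1])
        u[n + 1, 0] = uB[0] + (p[n + 1, 0] - pB[0]) / rho_cf - fB[0]

        # outlet
        if outlet == "constant_pressure":
            p[n + 1, nz] = 0.0
            u[n + 1, nz] = uA[-1] + (pA[-1] - p[n + 1, nz]) / rho_cf - fA[-1]
        else:  # closed end
            u[n + 1, nz] = 0.0
            p[n + 1, nz] = pA[-1] + rho_cf * uA[-1] - rho_cf * fA[-1]

        if unsteady:
            du_hist[n] = u[n + 1] - u[n]

    return WaveField(
        z=z,
        t=t,
        p=p + pulse.ambient,
        u=u,
        cf=cf,
        ambient=pulse.ambient,
        fluid=fluid,
        channel=ch,
        grid=grid,
        meta={"outlet": outlet, "friction": friction, "courant": C},
    )


def peak_attenuation(
    field: WaveField,
    dz_window: float,
    z_min: float = 0.0,
    z_max: float | None = None,
) -> float:
    """Average fractional peak-pressure drop per window of length ``dz_window``.

    Peaks of the *total* pressure are sampled at ``z_min``,
    ``z_min + dz_window``, ... up to ``z_max`` (default: the last
    multiple strictly inside the channel, excluding the outlet node);
    the mean of the per-window relative drops is returned (positive =
    attenuation).  Zero, to round-off, for a friction-free run.
    """
    if dz_window <= 0:
        raise ValueError("window must be positive")
    L = field.z[-1]
    if z_max is None:
        z_max = L - field.grid.dz / 2.0
    edges = []
    zk = z_min
    while zk <= z_max + 1e-12:
        edges.append(zk)
        zk += dz_window
    if len(edges) < 2:
        raise ValueError("channel shorter than one window")
    peaks = field.peak_pressure()
    pk = np.array([peaks[field.nearest_index(zz)] for zz in edges])
    drops = (pk[:-1] - pk[1:]) / pk[:-1]
    return float(drops.mean())


def monitor(field: WaveField, positions) -> list[MonitorTrace]:
    """Sample time histories at ``positions`` (m), nearest-grid-point."""
    out = []
    L = field.z[-1]
    for pos in np.atleast_1d(positions):
        if not 0.0 <= pos <= L:
            raise ValueError(f"monitor position {pos} outside the channel")
        i = field.nearest_index(float(pos))
        out.append(
            MonitorTrace(
                z=float(field.z[i]),
                z_frac=float(field.z[i] / L),
                t=field.t,
                p=field.p[:, i].copy(),
                u=field.u[:, i].copy(),
                tau_x=np.zeros_like(field.t),
            )
        )
    return out
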