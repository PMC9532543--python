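"""Axial wall shear stress on the cell-culture wall.

Behind the traveling compression front the core fluid moves at ~m/s
while the no-slip wall holds it at rest, so a boundary layer grows from
the moment the front passes each station.  For a weak front the layer is
laminar and locally well approximated by the impulsively-started plate
(Stokes first problem, Mirels-type shock-induced layer): the wall shear
driven by the instantaneous core velocity ``u_e`` after elapsed time
``te`` since front arrival is

    tau_z(t) = mu * u_e(t) / sqrt(pi * nu * te),
    delta(t) = sqrt(pi * nu * te)          (equivalent layer thickness).

The t^-1/2 divergence at arrival is regularized by a configurable time
``t_reg`` (default: one solver step), which is always reported because
the quoted peak depends on it.  Shear is positive in the propagation
(+z) direction; transverse shear is identically zero in this 1D model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fluids import FluidSpec
from .solver import WaveField

__all__ = ["ShearTrace", "stokes_layer_shear", "stress_components", "StressSample"]


@dataclass
class ShearTrace:
    """Axial wall shear time history at one station."""

    z: float
    t: np.ndarray
    tau_z: np.ndarray       # Pa
    delta: np.ndarray       # boundary-layer thickness (m); 0 before arrival
    t_arrival: float
    t_reg: float


@dataclass
class StressSample:
    """Wall stress components at one station: compression, axial and
    transverse shear."""

    z: float
    sigma: np.ndarray        # total compression pressure at the wall (Pa)
    tau_z: np.ndarray        # axial shear (Pa)
    tau_x: np.ndarray        # transverse shear, identically 0 (Pa)
    viscous_normal: np.ndarray  # 2 mu du/dz correction (Pa), reported
    shear: ShearTrace


def stokes_layer_shear(
    fluid: FluidSpec,
    t: np.ndarray,
    u_e: np.ndarray,
    t_arrival: float,
    t_reg: float,
    z: float = 0.0,
) -> ShearTrace:
    """Stokes-layer wall shear for a core-velocity history ``u_e(t)``.

    ``u_e`` must be zero before ``t_arrival``; times before arrival
    return zero shear (no error).  ``t_reg > 0`` regularizes the
    divergence at zero elapsed time.
    """
    if t_reg <= 0:
        raise ValueError("regularization time must be positive")
    t = np.asarray(t, dtype=float)
    u_e = np.asarray(u_e, dtype=float)
    elapsed = t - t_arrival
    active = elapsed >= 0.0
    delta = np.zeros_like(t)
    tau = np.zeros_like(t)
    delta[active] = np.sqrt(np.pi * fluid.nu * (elapsed[active] + t_reg))
    tau[active] = fluid.mu * u_e[active] / delta[active]
    return ShearTrace(z=z, t=t, tau_z=tau, delta=delta,
                      t_arrival=t_arrival, t_reg=t_reg)


def _arrival_time(field: WaveField, i: int, threshold_frac: float = 0.01) -> float:
    """First time the gauge pressure at node i exceeds a small fraction
    of the inlet peak; falls back to the kinematic estimate z/cf."""
    gauge = field.p[:, i] - field.ambient
    peak0 = field.p[:, 0].max() - field.ambient
    if peak0 <= 0:
        return float(field.z[i] / field.cf)
    hits = np.nonzero(gauge > threshold_frac * peak0)[0]
    if hits.size == 0:
        return float(field.z[i] / field.cf)
    return float(field.t[hits[0]])


def stress_components(
    fluid: FluidSpec,
    field: WaveField,
    position: float,
    t_reg: float | None = None,
) -> StressSample:
    """Wall stress components at ``position`` from a solved wave field.

    Compression is the total pressure at the wall; axial shear comes
    from :func:`stokes_layer_shear` driven by the local core velocity;
    transverse shear is zero by the planar symmetry of the 1D model.
    The viscous normal-stress correction ``2 mu du/dz`` is evaluated by
    finite differences and reported (it is ~Pa against MPa compression).
    """
    i = field.nearest_index(position)
    if t_reg is None:
        t_reg = field.grid.dt
    t_arr = _arrival_time(field, i)
    shear = stokes_layer_shear(
        fluid, field.t, field.u[:, i], t_arr, t_reg, z=float(field.z[i])
    )
    dudz = np.gradient(field.u, field.z, axis=1)[:, i]
    return StressSample(
        z=float(field.z[i]),
        sigma=field.p[:, i].copy(),
        tau_z=shear.tau_z,
        tau_x=np.zeros_like(field.t),
        viscous_normal=2.0 * fluid.mu * dudz,
        shear=shear,
    )
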