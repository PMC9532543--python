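"""Solid materials for projectiles and channel walls.

Handbook values ship as presets (the source publication names the
materials without printing their properties); every field is overridable
through the config layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

__all__ = ["SolidMaterial", "PMMA", "STEEL", "BOROSILICATE", "MATERIALS"]


@dataclass(frozen=True)
class SolidMaterial:
    """Isotropic solid: density, longitudinal wave speed, elastic moduli.

    ``c_s`` is the longitudinal bulk wave speed used for the 1D impedance
    match; the slender-rod (bar) speed ``sqrt(E/rho)`` is available as
    :attr:`bar_speed` for users who prefer it.
    """

    rho_s: float  # kg m^-3
    c_s: float    # m s^-1
    E: float      # Pa
    G: float      # Pa

    def __post_init__(self) -> None:
        for name in ("rho_s", "c_s", "E", "G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SolidMaterial.{name} must be strictly positive")

    @property
    def impedance(self) -> float:
        """Acoustic impedance ``rho_s * c_s`` (Pa s m^-1)."""
        return self.rho_s * self.c_s

    @property
    def bar_speed(self) -> float:
        """Slender-rod longitudinal speed ``sqrt(E/rho_s)`` (m s^-1)."""
        return sqrt(self.E / self.rho_s)


PMMA = SolidMaterial(rho_s=1180.0, c_s=2757.0, E=3.3e9, G=1.2e9)
STEEL = SolidMaterial(rho_s=7850.0, c_s=5900.0, E=200.0e9, G=79.0e9)
#: Stiff chip/wall material representative of a glass microfluidic chip.
BOROSILICATE = SolidMaterial(rho_s=2230.0, c_s=5640.0, E=63.0e9, G=26.0e9)

MATERIALS: dict[str, SolidMaterial] = {
    "pmma": PMMA,
    "steel": STEEL,
    "borosilicate": BOROSILICATE,
}
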