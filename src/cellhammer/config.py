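"""Run configuration: schema-validated, SI units, preset-aware.

A run is described by a single :class:`RunConfig` (loadable from YAML)
naming the fluid, projectile, channel, grid and boundary settings.  Two
presets ship with the package:

``representative``
    The water-filled 3 x 3 x 60 mm glass channel struck by a 1 cm PMMA
    projectile.  The impact velocity defaults to 3.0 m/s, which
    reproduces the ~3 MPa inlet amplitude of the reference design; it is
    an ordinary, overridable input.

``shot62``
    A classic water-hammer validation experiment: a 0.67 kg steel
    projectile at 18.5 m/s striking a water-filled specimen tube of
    38.1 mm bore and 12.74 mm wall, closed at the far end.  The tube
    material is not published, so the preset runs with the celerity
    correction off (near-rigid wall) and says so in the report; the
    bore is modelled as a square section of equal width.

Every output echoes the full configuration for provenance.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .channel import DEFAULT_MEAN_FREE_PATH, ChannelSpec
from .fluids import WATER, FluidSpec
from .materials import MATERIALS, SolidMaterial
from .source import ProjectileSpec

__all__ = ["RunConfig", "preset_config", "load_config", "PRESET_NAMES"]


class FluidConfig(BaseModel):
    preset: Literal["water"] = "water"
    rho0: Optional[float] = None
    c0: Optional[float] = None
    mu: Optional[float] = None
    B: Optional[float] = None
    gamma: Optional[float] = None
    p0: Optional[float] = None

    def build(self) -> FluidSpec:
        base = WATER
        kwargs = {
            f: getattr(self, f) if getattr(self, f) is not None else getattr(base, f)
            for f in ("rho0", "c0", "mu", "B", "gamma", "p0")
        }
        return FluidSpec(**kwargs)


class MaterialConfig(BaseModel):
    preset: Optional[str] = None
    rho_s: Optional[float] = None
    c_s: Optional[float] = None
    E: Optional[float] = None
    G: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "MaterialConfig":
        if self.preset is None:
            missing = [f for f in ("rho_s", "c_s", "E", "G") if getattr(self, f) is None]
            if missing:
                raise ValueError(
                    f"material needs a preset or explicit fields; missing {missing}"
                )
        elif self.preset not in MATERIALS:
            raise ValueError(f"unknown material preset {self.preset!r}")
        return self

    def build(self) -> SolidMaterial:
        if self.preset is not None:
            base = MATERIALS[self.preset]
            kwargs = {
                f: getattr(self, f) if getattr(self, f) is not None else getattr(base, f)
                for f in ("rho_s", "c_s", "E", "G")
            }
            return SolidMaterial(**kwargs)
        return SolidMaterial(rho_s=self.rho_s, c_s=self.c_s, E=self.E, G=self.G)


class ProjectileConfig(BaseModel):
    material: MaterialConfig
    length: float = Field(gt=0)
    area: float = Field(gt=0)
    up: float = Field(ge=0)
    mass: Optional[float] = Field(default=None, gt=0)
    use_bar_speed: bool = False

    def build(self) -> ProjectileSpec:
        return ProjectileSpec(
            material=self.material.build(),
            length=self.length,
            area=self.area,
            up=self.up,
            mass=self.mass,
            use_bar_speed=self.use_bar_speed,
        )


class ChannelConfig(BaseModel):
    a: float = Field(gt=0)
    b: float = Field(gt=0)
    e: float = Field(gt=0)
    l: float = Field(gt=0)
    wall: MaterialConfig
    delta_cell: float = Field(default=1.0e-5, gt=0)
    rho_cell_note: Literal["none", "sparse", "confluent"] = "none"

    def build(self) -> ChannelSpec:
        return ChannelSpec(
            a=self.a,
            b=self.b,
            e=self.e,
            l=self.l,
            wall=self.wall.build(),
            delta_cell=self.delta_cell,
            rho_cell_note=self.rho_cell_note,
        )


class GridConfig(BaseModel):
    dz: float = Field(gt=0)
    dt: Optional[float] = Field(default=None, gt=0)
    courant_target: Optional[float] = Field(default=None, gt=0, le=1.0)
    total_time: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "GridConfig":
        if (self.dt is None) == (self.courant_target is None):
            raise ValueError("give exactly one of dt or courant_target")
        return self


class RunConfig(BaseModel):
    """Complete, validated description of one design/simulation run."""

    name: str = "run"
    fluid: FluidConfig = FluidConfig()
    projectile: ProjectileConfig
    channel: ChannelConfig
    grid: GridConfig
    outlet: Literal["constant_pressure", "closed"] = "constant_pressure"
    friction: Literal["none", "quasi_steady", "unsteady"] = "quasi_steady"
    monitors: list[float] = Field(default=[0.25, 0.5, 0.75])
    rigid_walls: bool = False
    mean_free_path: float = Field(default=DEFAULT_MEAN_FREE_PATH, gt=0)
    t_reg: Optional[float] = Field(default=None, gt=0)
    notes: str = ""

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for m in self.monitors:
            if not 0.0 <= m <= 1.0:
                raise ValueError("monitor positions are fractions of the length")
        return self

    def echo(self) -> dict:
        """Full configuration as plain data, for provenance in reports."""
        return self.model_dump()


def _representative() -> RunConfig:
    return RunConfig(
        name="representative",
        projectile=ProjectileConfig(
            material=MaterialConfig(preset="pmma"),
            length=0.01,
            area=9.0e-6,
            up=3.0,
        ),
        channel=ChannelConfig(
            a=3.0e-3, b=3.0e-3, e=3.0e-3, l=60.0e-3,
            wall=MaterialConfig(preset="borosilicate"),
        ),
        grid=GridConfig(dz=1.0e-4, courant_target=1.0, total_time=4.2e-5),
        outlet="constant_pressure",
        friction="quasi_steady",
        notes="water-filled 3x3x60 mm glass channel, 1 cm PMMA projectile",
    )


def _shot62() -> RunConfig:
    bore = 0.0381
    area = 3.141592653589793 * (bore / 2.0) ** 2
    return RunConfig(
        name="shot62",
        projectile=ProjectileConfig(
            material=MaterialConfig(preset="steel"),
            length=0.0749,
            area=area,
            up=18.5,
            mass=0.67,
        ),
        channel=ChannelConfig(
            a=bore, b=bore, e=0.01274, l=0.9,
            wall=MaterialConfig(preset="steel"),
        ),
        grid=GridConfig(dz=0.9 / 300, courant_target=1.0, total_time=1.4e-3),
        outlet="closed",
        friction="quasi_steady",
        rigid_walls=True,
        notes=(
            "validation case: 0.67 kg steel projectile at 18.5 m/s into a "
            "water-filled 38.1 mm bore, 12.74 mm wall specimen tube, closed "
            "end; tube material unpublished -> near-rigid wall assumed "
            "(celerity correction off), bore modelled as an equal-width "
            "square section; tube length unpublished, 0.9 m assumed"
        ),
    )


_PRESETS = {"representative": _representative, "shot62": _shot62}
PRESET_NAMES = tuple(_PRESETS)


def preset_config(name: str) -> RunConfig:
    """Return a fresh copy of a packaged preset configuration."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {PRESET_NAMES}") from None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    A top-level ``preset:`` key starts from that preset and deep-merges
    any other keys over it.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    preset = data.pop("preset", None)
    if preset is not None:
        base = preset_config(preset).model_dump()
        data = _deep_merge(base, data)
    return RunConfig.model_validate(data)


def _deep_merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
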