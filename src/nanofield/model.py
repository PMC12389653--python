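"""Domain types, defaults and configuration I/O for nanoparticle/membrane
field-amplification scenarios.

The model is the standard 2D continuum picture of a cell in an electroporation
cuvette: a circular cell (radius 10 um) bounded by a thin (5 nm), almost
non-conductive plasma membrane, immersed in extracellular medium between two
parallel plate electrodes.  A nanoparticle (NP) -- a disc or a capsule
(nanorod) -- is placed either a few nanometres outside the membrane ("gap"
mode) or partially sunk into it ("embedded" mode, locally thinning the
membrane).

All lengths are SI metres internally.  Configuration files (TOML) use
nanometres for lengths and volts for the drive, which keeps the files legible
at both the nanometre and micrometre scales; see :func:`load_scenario`.
"""

from __future__ import annotations

import math
import tomllib
from enum import Enum
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

NM = 1e-9
UM = 1e-6

#: Electrical conductivities (S/m) and relative permittivities of the media.
#: The permittivities are parsed and stored but unused: the solve is a
#: stationary current-conduction problem (see :mod:`nanofield.fem`).
DEFAULT_MATERIALS = {
    "cytoplasm": {"conductivity": 0.2, "relative_permittivity": 1.0},
    "membrane": {"conductivity": 5e-7, "relative_permittivity": 11.7},
    "extracellular": {"conductivity": 1.5, "relative_permittivity": 1.0},
    "gold": {"conductivity": 4.11e7, "relative_permittivity": 1.0},
    "silica": {"conductivity": 1e-3, "relative_permittivity": 1.0},
}

#: Default drive: 8 V over the 80 um domain = a nominal applied field of
#: 1 kV/cm (order of the experimental 150 V across a 2 mm cuvette).  Every
#: amplification metric downstream is a ratio and provably drive-invariant.
DEFAULT_VOLTAGE = 8.0
DEFAULT_DOMAIN = 80e-6


class ConfigError(ValueError):
    """Raised when a scenario file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a scenario violates a model invariant."""


class MaterialProps(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    conductivity: float = Field(ge=0.0)
    relative_permittivity: float = Field(default=1.0, ge=1.0)


class CellSpec(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    radius: float = 10e-6
    membrane_thickness: float = 5e-9
    center: tuple[float, float] = (0.0, 0.0)

    @model_validator(mode="after")
    def _check(self) -> "CellSpec":
        if not self.membrane_thickness > 0:
            raise ValueError("membrane_thickness must be positive")
        if self.membrane_thickness / self.radius >= 1e-2:
            raise ValueError("membrane must be thin: thickness/radius < 1e-2")
        return self


class NPShape(str, Enum):
    DISC = "disc"
    CAPSULE = "capsule"


class PlacementMode(str, Enum):
    GAP = "gap"
    EMBEDDED = "embedded"


class NanoparticleSpec(BaseModel):
    """A disc or capsule NP placed relative to the membrane outer surface.

    ``gap_distance`` is the closest NP-surface-to-membrane distance in gap
    mode; ``embed_depth`` is how far the NP surface dips below the membrane
    outer surface in embedded mode (leaving ``membrane_thickness -
    embed_depth`` of membrane beneath the NP centre).  ``angular_position``
    locates the NP on the cell perimeter, measured from the electrode axis
    (+x).  The default pi/4 places the NP where the exterior field retains
    both normal and tangential components; at the pole (0) the exterior
    field stagnates against the insulating membrane and no appreciable
    gap-field structure exists.  ``orientation`` is the capsule long-axis
    angle from the local membrane normal; the default -pi/4 (with the
    default position) aligns the rod with the applied field, so current
    enters through the tip facing the membrane and exits through the
    opposite tip.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    shape: NPShape = NPShape.DISC
    radius: float = 50e-9
    length: Optional[float] = None  # capsule only, tip-to-tip
    material: str = "gold"
    placement_mode: PlacementMode = PlacementMode.GAP
    gap_distance: float = 10e-9
    embed_depth: float = 2e-9
    angular_position: float = math.pi / 4
    orientation: float = -math.pi / 4  # capsule long-axis vs local normal

    @model_validator(mode="after")
    def _check(self) -> "NanoparticleSpec":
        if self.radius <= 0:
            raise ValueError("NP radius must be positive")
        if self.shape is NPShape.CAPSULE:
            if self.length is None or self.length <= 2 * self.radius:
                raise ValueError("capsule requires length > 2*radius")
        if self.placement_mode is PlacementMode.GAP and self.gap_distance <= 0:
            raise ValueError("gap mode requires gap_distance > 0")
        if self.placement_mode is PlacementMode.EMBEDDED and self.embed_depth <= 0:
            raise ValueError("embedded mode requires embed_depth > 0")
        return self


class DomainSpec(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    width: float = DEFAULT_DOMAIN
    height: float = DEFAULT_DOMAIN
    applied_voltage: float = DEFAULT_VOLTAGE

    @model_validator(mode="after")
    def _check(self) -> "DomainSpec":
        if self.applied_voltage < 0:
            raise ValueError("applied_voltage must be >= 0")
        return self


class EvaluationLineSpec(BaseModel):
    """Sampling line for the gap field profile: tangent-parallel segment at
    the gap midline, centred beneath the NP centre."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    anchor: str = "gap_midline"  # or "membrane_interior"
    half_length: float = 200e-9
    n_samples: int = 801

    @model_validator(mode="after")
    def _check(self) -> "EvaluationLineSpec":
        if self.anchor not in ("gap_midline", "membrane_interior"):
            raise ValueError("anchor must be gap_midline or membrane_interior")
        if self.n_samples < 3 or self.n_samples % 2 == 0:
            raise ValueError("n_samples must be odd and >= 3 (centre sample)")
        return self


class MeshControls(BaseModel):
    """Knobs for the graded mesher.

    ``level`` scales all target sizes by 1/level (level 2 = twice as fine).
    ``h_fine`` is the arc spacing on the membrane inside the refined window,
    ``membrane_layers`` the number of element layers across the membrane
    outside the window (the window doubles it), ``window_halfwidth`` the arc
    half-width of the refined window around the NP (None = automatic).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    level: float = 1.0
    h_fine: float = 2e-9
    membrane_layers: int = 3
    window_halfwidth: Optional[float] = None
    growth: float = 1.35
    bl_extent: float = 3e-6
    h_coarse: float = 3e-6

    @model_validator(mode="after")
    def _check(self) -> "MeshControls":
        if self.level <= 0 or self.h_fine <= 0 or self.membrane_layers < 2:
            raise ValueError("invalid mesh controls")
        if not 1.05 <= self.growth <= 2.0:
            raise ValueError("growth ratio must be in [1.05, 2]")
        return self


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    label: str = "scenario"
    cell: CellSpec = CellSpec()
    nanoparticle: Optional[NanoparticleSpec] = None
    domain: DomainSpec = DomainSpec()
    materials: dict[str, MaterialProps] = Field(default_factory=dict)
    mesh_controls: MeshControls = MeshControls()
    evaluation: EvaluationLineSpec = EvaluationLineSpec()

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if not self.materials:
            object.__setattr__(self, "materials", default_materials())
        required = {"exterior", "membrane", "cytoplasm"}
        if self.nanoparticle is not None:
            required.add("nanoparticle")
        missing = required - set(self.materials)
        if missing:
            raise ValueError(f"regions without material: {sorted(missing)}")
        if self.domain.width < 4 * 2 * self.cell.radius or self.domain.height < 4 * 2 * self.cell.radius:
            raise ValueError("domain must be at least 4 cell diameters wide/high")
        np_ = self.nanoparticle
        if np_ is not None and np_.placement_mode is PlacementMode.EMBEDDED:
            if not np_.embed_depth < self.cell.membrane_thickness:
                raise ValueError(
                    "embed_depth must be smaller than the membrane thickness"
                )
        return self

    @property
    def is_baseline(self) -> bool:
        return self.nanoparticle is None


def default_materials(np_material: str = "gold") -> dict[str, MaterialProps]:
    """Region->material binding with the standard conductivity table."""
    m = DEFAULT_MATERIALS
    return {
        "exterior": MaterialProps(name="extracellular", **m["extracellular"]),
        "membrane": MaterialProps(name="membrane", **m["membrane"]),
        "cytoplasm": MaterialProps(name="cytoplasm", **m["cytoplasm"]),
        "nanoparticle": MaterialProps(name=np_material, **m[np_material]),
    }


# --------------------------------------------------------------------------
# Built-in scenario set
# --------------------------------------------------------------------------

def _np_scenario(label, shape, radius, length, material, mode, **kw):
    np_spec = NanoparticleSpec(
        shape=shape, radius=radius, length=length, material=material,
        placement_mode=mode, **kw)
    return ScenarioSpec(label=label, nanoparticle=np_spec,
                        materials=default_materials(material))


def builtin_scenarios() -> list[ScenarioSpec]:
    """The seven study cases: no-NP baseline; Au and silica discs at 10 and
    50 nm radius with a 10 nm gap; the Au capsule (radius 17 nm, length 60 nm)
    with a 10 nm gap; and the 50 nm Au disc embedded 2 nm into the membrane.
    """
    out = [ScenarioSpec(label="baseline", materials=default_materials())]
    for r, tag in ((10e-9, "r10"), (50e-9, "r50")):
        for mat in ("gold", "silica"):
            out.append(_np_scenario(
                f"{mat}_disc_{tag}", NPShape.DISC, r, None, mat,
                PlacementMode.GAP))
    out.append(_np_scenario(
        "gold_capsule", NPShape.CAPSULE, 17e-9, 60e-9, "gold",
        PlacementMode.GAP))
    out.append(_np_scenario(
        "gold_disc_r50_embedded", NPShape.DISC, 50e-9, None, "gold",
        PlacementMode.EMBEDDED))
    return out


def alternate_capsule_scenario() -> ScenarioSpec:
    """Variant nanorod with 50 nm major / 10 nm minor axis (capsule radius
    5 nm, tip-to-tip length 50 nm), an alternative reading of the reported
    rod dimensions."""
    return _np_scenario("gold_capsule_alt", NPShape.CAPSULE, 5e-9, 50e-9,
                        "gold", PlacementMode.GAP)


# --------------------------------------------------------------------------
# TOML configuration I/O (lengths in nm, voltages in V)
# --------------------------------------------------------------------------

_LENGTH_FIELDS_NM = {
    "radius", "membrane_thickness", "length", "gap_distance", "embed_depth",
    "width", "height", "half_length", "h_fine", "window_halfwidth",
    "bl_extent", "h_coarse",
}


def _to_nm(section: dict) -> dict:
    out = {}
    for k, v in section.items():
        if k in _LENGTH_FIELDS_NM and isinstance(v, (int, float)):
            nm = v / NM
            nice = round(nm, 6)
            # prefer the readable form whenever it reproduces the SI value
            out[k] = nice if nice * NM == v else nm
        elif isinstance(v, dict):
            out[k] = _to_nm(v)
        else:
            out[k] = v
    return out


def _from_nm(section: dict) -> dict:
    out = {}
    for k, v in section.items():
        if k in _LENGTH_FIELDS_NM and v is not None and isinstance(v, (int, float)):
            out[k] = float(v) * NM
        elif isinstance(v, dict):
            out[k] = _from_nm(v)
        else:
            out[k] = v
    return out


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    raw = spec.model_dump(mode="json", exclude_none=True)
    if spec.nanoparticle is None:
        raw["nanoparticle"] = "none"
    return _to_nm(raw)


def scenario_from_dict(data: dict) -> ScenarioSpec:
    data = dict(data)
    if data.get("nanoparticle") == "none":
        data.pop("nanoparticle")
    data = _from_nm(data)
    try:
        return ScenarioSpec(**data)
    except (ValueError, TypeError) as exc:
        raise ValidationError(str(exc)) from exc


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Load and validate one scenario from a TOML file (lengths in nm)."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"no such file: {path}")
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return scenario_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _emit_toml(data: dict, prefix: str = "") -> list[str]:
    lines, tables = [], []
    for k, v in data.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {_toml_value(v)}")
    for k, v in tables:
        name = f"{prefix}{k}"
        lines.append("")
        lines.append(f"[{name}]")
        lines.extend(_emit_toml(v, prefix=name + "."))
    return lines


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    """Write a scenario to TOML; ``load_scenario`` round-trips losslessly."""
    text = "\n".join(_emit_toml(scenario_to_dict(spec))) + "\n"
    Path(path).write_text(text)
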