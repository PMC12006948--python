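"""Domain types, physical constants and configuration handling.

All quantities are SI (metres, seconds, mol m^-3, amperes) unless a
docstring says otherwise.  Currents carry their electrochemical sign
(cathodic currents are negative); boundary fluxes are stored as
magnitudes, with the direction fixed by the boundary they act on.

Coordinate convention: ``z = 0`` at the dish floor (the substrate the
cells adhere to), the electrode face parallel to the floor above it,
``r = 0`` (or ``x = y = 0``) on the electrode axis.  The *working
distance* is the gap between the electrode face and the top of the
target cell, so for a cell of cap height ``h`` the electrode face sits
at ``z = h + working_distance``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Faraday constant, C mol^-1.  Shared by every module.
FARADAY = 96485.0


class ConfigurationError(ValueError):
    """A required field is missing or an unknown key was supplied."""


class ValidationError(ValueError):
    """A field value violates a physical invariant."""


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Inlaid platinum microdisk in a flat insulating glass sheath.

    Parameters
    ----------
    disk_radius:
        Radius of the active platinum disk (m).
    sheath_radius:
        Outer radius of the insulating glass body (m).
    working_distance:
        Gap between the electrode face and the top of the target
        cell (m).  The electrode face is therefore at
        ``z = cap_height + working_distance`` above the dish floor.
    domain_radius, domain_height:
        Radial and axial extent of the simulation domain (m).  The far
        boundary carries bulk (Dirichlet) conditions, so it must sit
        many disk radii away; defaults of 40 disk radii keep the
        truncation error of the diffusion-limited current well below a
        percent.
    """

    disk_radius: float = 12.5e-6
    sheath_radius: float = 175e-6
    working_distance: float = 25e-6
    domain_radius: float = 0.0
    domain_height: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("disk_radius", self.disk_radius)
        _require_positive("working_distance", self.working_distance)
        if not self.disk_radius < self.sheath_radius:
            raise ValidationError(
                "sheath_radius must exceed disk_radius "
                f"({self.sheath_radius!r} <= {self.disk_radius!r})"
            )
        if self.domain_radius == 0.0:
            object.__setattr__(
                self,
                "domain_radius",
                max(40.0 * self.disk_radius, 2.0 * self.sheath_radius),
            )
        if self.domain_height == 0.0:
            object.__setattr__(
                self,
                "domain_height",
                self.working_distance + 40.0 * self.disk_radius,
            )
        if self.domain_radius < 25.0 * self.disk_radius:
            raise ValidationError(
                "domain_radius must be at least 25 disk radii "
                f"({self.domain_radius!r} < {25 * self.disk_radius!r})"
            )
        if self.domain_height < self.working_distance + 25.0 * self.disk_radius:
            raise ValidationError(
                "domain_height must be at least working_distance + 25 disk radii"
            )

    @property
    def disk_area(self) -> float:
        """Geometric area of the platinum disk (m^2)."""
        return math.pi * self.disk_radius**2


@dataclass(frozen=True)
class BufferSystem:
    """Single monoprotic buffer (HA <-> H+ + A-), HEPES by default.

    HEPES is zwitterionic; its acid and base forms are the same
    molecule give or take a proton, so their diffusivities are taken
    equal by default.  Values are for ~37 degC aqueous media.
    """

    total_concentration: float = 20.0  # mol m^-3 (20 mM HEPES)
    pKa: float = 7.5
    D_HA: float = 0.7e-9  # m^2 s^-1
    D_A: float = 0.7e-9  # m^2 s^-1
    D_H: float = 9.3e-9  # m^2 s^-1 (free proton, Grotthuss-assisted)

    def __post_init__(self) -> None:
        if self.total_concentration < 0:
            raise ValidationError("total_concentration must be >= 0")
        if not 0 < self.pKa < 14:
            raise ValidationError(f"pKa must lie in (0, 14), got {self.pKa!r}")
        for name in ("D_HA", "D_A", "D_H"):
            _require_positive(name, getattr(self, name))

    @property
    def Ka(self) -> float:
        """Acid dissociation constant in mol m^-3 (= 10^-pKa mol L^-1 * 1e3)."""
        return 10.0 ** (-self.pKa) * 1e3


@dataclass(frozen=True)
class MediumProperties:
    """Transport and acid-base properties of the imaging medium."""

    D_O2: float = 2.1e-9  # m^2 s^-1
    c_O2_bulk: float = 0.26  # mol m^-3 (air-saturated aqueous medium)
    bulk_pH: float = 7.4
    buffer: BufferSystem = field(default_factory=BufferSystem)
    temperature: float = 310.15  # K

    def __post_init__(self) -> None:
        _require_positive("D_O2", self.D_O2)
        _require_positive("c_O2_bulk", self.c_O2_bulk)
        if not 0 < self.bulk_pH < 14:
            raise ValidationError(f"bulk_pH must lie in (0, 14), got {self.bulk_pH!r}")
        _require_positive("temperature", self.temperature)


@dataclass(frozen=True)
class CellModel:
    """Adherent cell approximated as a spherical cap on the dish floor.

    The cap has base radius ``base_radius`` and apex height
    ``cap_height``; respiration is a uniform areal oxygen consumption
    flux over the curved cap surface (mol m^-2 s^-1, stored as a
    magnitude).
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    base_radius: float = 12.5e-6
    cap_height: float = 10e-6
    respiration_flux: float = 2.15e-8  # mol m^-2 s^-1

    def __post_init__(self) -> None:
        _require_positive("base_radius", self.base_radius)
        if not 0 < self.cap_height <= self.base_radius:
            raise ValidationError(
                "cap_height must satisfy 0 < cap_height <= base_radius"
            )
        if self.respiration_flux < 0:
            raise ValidationError("respiration_flux must be >= 0 (consumption)")

    @property
    def sphere_radius(self) -> float:
        """Radius of the sphere the cap is cut from (m)."""
        return (self.base_radius**2 + self.cap_height**2) / (2.0 * self.cap_height)

    @property
    def sphere_center_z(self) -> float:
        """z-coordinate of that sphere's centre (below the floor) (m)."""
        return self.cap_height - self.sphere_radius

    @property
    def cap_area(self) -> float:
        """Curved (lateral) surface area of the cap, 2*pi*R*h (m^2)."""
        return 2.0 * math.pi * self.sphere_radius * self.cap_height

    @property
    def respiration_rate(self) -> float:
        """Whole-cell oxygen consumption, flux * cap area (mol s^-1)."""
        return self.respiration_flux * self.cap_area

    def profile_radius(self, z: float) -> float:
        """Radius of the cap cross-section at height ``z`` (0 outside)."""
        if z < 0 or z > self.cap_height:
            return 0.0
        return math.sqrt(max(self.sphere_radius**2 - (z - self.sphere_center_z) ** 2, 0.0))


@dataclass(frozen=True)
class ChallengeProtocol:
    """Galvanostatic oxygen-reduction challenge applied at the disk."""

    current: float = -7e-9  # A, cathodic negative
    n_electrons: int = 4
    duration: float = 300.0  # s
    baseline_duration: float = 300.0  # s

    def __post_init__(self) -> None:
        if self.current > 0:
            raise ValidationError(
                "current must be cathodic (<= 0); oxidation is not modelled"
            )
        if self.n_electrons not in (2, 4):
            raise ValidationError("n_electrons must be 2 or 4")
        if self.duration <= 0 or self.baseline_duration < 0:
            raise ValidationError("durations must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Fully resolved model configuration (geometry + medium + cells + protocol)."""

    geometry: ElectrodeGeometry = field(default_factory=ElectrodeGeometry)
    medium: MediumProperties = field(default_factory=MediumProperties)
    cells: tuple[CellModel, ...] = ()
    protocol: ChallengeProtocol = field(default_factory=ChallengeProtocol)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cells"] = [dataclasses.asdict(c) for c in self.cells]
        return d


def default_medium() -> MediumProperties:
    """Baseline medium: D_O2 = 2.1e-9 m^2/s, 0.26 mol/m^3 O2, pH 7.4, 20 mM HEPES.

    These are literature-standard values for an air-saturated aqueous
    HEPES-buffered imaging solution; every field can be overridden via
    the configuration file.
    """
    return MediumProperties()


def calibrated_medium() -> MediumProperties:
    """Medium with O2 transport parameters calibrated against the measured
    hindered diffusion-limited current.

    For the default electrode geometry (12.5 um disk, 175 um sheath,
    25 um working distance over a respiring cell) the reference
    diffusion-limited oxygen current is -9.52 nA.  Holding the
    geometry fixed, ``D_O2`` and ``c_O2_bulk`` are set to 37 degC
    physiological values (3.0e-9 m^2/s, 0.206 mol/m^3) whose product
    reproduces that current in the steady Dirichlet solve.
    """
    return MediumProperties(D_O2=3.0e-9, c_O2_bulk=0.206)


# ---------------------------------------------------------------------------
# configuration I/O


_GEOMETRY_KEYS = {f.name for f in dataclasses.fields(ElectrodeGeometry)}
_MEDIUM_KEYS = {f.name for f in dataclasses.fields(MediumProperties)}
_BUFFER_KEYS = {f.name for f in dataclasses.fields(BufferSystem)}
_CELL_KEYS = {f.name for f in dataclasses.fields(CellModel)}
_PROTOCOL_KEYS = {f.name for f in dataclasses.fields(ChallengeProtocol)}

#: keys accepted at the top level of a config file.  Scalar shortcuts
#: (current, duration, ...) are routed into the protocol section.
_TOP_LEVEL_SECTIONS = {"geometry", "medium", "cells", "protocol"}
_PROTOCOL_SHORTCUTS = {"current", "n_electrons", "duration", "baseline_duration"}


def _check_keys(section: str, given: dict[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {section}: {', '.join(sorted(unknown))}"
        )


def _build_medium(raw: dict[str, Any]) -> MediumProperties:
    _check_keys("medium", raw, _MEDIUM_KEYS)
    raw = dict(raw)
    buffer_raw = raw.pop("buffer", None)
    if buffer_raw is not None:
        if not isinstance(buffer_raw, dict):
            raise ConfigurationError("medium.buffer must be a mapping")
        _check_keys("medium.buffer", buffer_raw, _BUFFER_KEYS)
        raw["buffer"] = BufferSystem(**buffer_raw)
    return MediumProperties(**raw)


def config_from_dict(raw: dict[str, Any]) -> ModelConfig:
    """Validate a raw mapping and fill every default.

    Unknown keys are rejected (a typo should fail loudly, not silently
    fall back to a default).  Scalar shortcuts ``current``,
    ``n_electrons``, ``duration`` and ``baseline_duration`` at the top
    level are folded into the ``protocol`` section, so the minimal
    useful config is just ``{current: -7e-9}``.
    """
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")
    raw = dict(raw)
    protocol_raw = dict(raw.pop("protocol", {}) or {})
    for key in list(raw):
        if key in _PROTOCOL_SHORTCUTS:
            protocol_raw.setdefault(key, raw.pop(key))
    _check_keys("top level", raw, _TOP_LEVEL_SECTIONS)
    _check_keys("protocol", protocol_raw, _PROTOCOL_KEYS)

    geometry_raw = raw.get("geometry", {}) or {}
    _check_keys("geometry", geometry_raw, _GEOMETRY_KEYS)
    geometry = ElectrodeGeometry(**geometry_raw)

    medium = _build_medium(raw.get("medium", {}) or {})

    cells_raw = raw.get("cells", None)
    if cells_raw is None:
        cells: tuple[CellModel, ...] = (CellModel(),)
    else:
        if not isinstance(cells_raw, list):
            raise ConfigurationError("cells must be a list of mappings")
        built = []
        for i, cell_raw in enumerate(cells_raw):
            _check_keys(f"cells[{i}]", cell_raw, _CELL_KEYS)
            cell_raw = dict(cell_raw)
            if "center_xy" in cell_raw:
                cell_raw["center_xy"] = tuple(float(v) for v in cell_raw["center_xy"])
            built.append(CellModel(**cell_raw))
        cells = tuple(built)

    protocol = ChallengeProtocol(**protocol_raw)
    return ModelConfig(geometry=geometry, medium=medium, cells=cells, protocol=protocol)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML or JSON configuration file.

    Raises
    ------
    ConfigurationError
        Missing/unknown fields or an unparseable file.
    ValidationError
        A field value that violates a physical invariant.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"invalid JSON in {path}: {exc}") from exc
    else:
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if raw is None:
        raw = {}
    try:
        return config_from_dict(raw)
    except TypeError as exc:  # dataclass signature mismatch
        raise ConfigurationError(str(exc)) from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration so that ``load_config`` round-trips it."""
    path = Path(path)
    d = config.to_dict()
    d["cells"] = [
        {**c, "center_xy": list(c["center_xy"])} for c in d["cells"]
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d))
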