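"""Electrochemical boundary conditions for the oxygen reduction reaction.

The microdisk performs the ORR under galvanostatic (constant-current)
control.  With the four-electron pathway, O2 + 4H+ + 4e- -> 2H2O, each
O2 consumed at the disk removes four protons from the adjacent medium.
A constant current therefore fixes both the total O2 flux and the
total proton flux through the disk face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_core import FARADAY, CellModel, ElectrodeGeometry, MediumProperties


@dataclass(frozen=True)
class BoundaryFluxSet:
    """Uniform consumption flux densities over the disk face (magnitudes).

    ``H_flux_at_disk`` equals ``n_electrons * O2_flux_at_disk``: the
    four-electron ORR consumes one proton per electron.
    """

    O2_flux_at_disk: float  # mol m^-2 s^-1
    H_flux_at_disk: float  # mol m^-2 s^-1
    flux_profile: str = "uniform"

    def __post_init__(self) -> None:
        if self.O2_flux_at_disk < 0 or self.H_flux_at_disk < 0:
            raise ValueError("boundary fluxes are stored as magnitudes (>= 0)")


def galvanostatic_boundary_flux(
    current: float, disk_radius: float, n_electrons: int = 4
) -> BoundaryFluxSet:
    """Convert a cathodic current to uniform disk flux densities.

    The O2 consumption flux magnitude is ``|i| / (n F pi a^2)``; under
    galvanostatic control the integrated flux is fixed, and the
    uniform-flux-density approximation of the constant-current disk is
    used throughout.

    Raises
    ------
    ValueError
        For anodic (positive) currents — oxidation is not modelled —
        or an unsupported electron count.
    """
    if current > 0:
        raise ValueError("anodic (positive) currents are not modelled")
    if n_electrons not in (2, 4):
        raise ValueError("n_electrons must be 2 or 4")
    if disk_radius <= 0:
        raise ValueError("disk_radius must be > 0")
    o2_flux = abs(current) / (n_electrons * FARADAY * math.pi * disk_radius**2)
    return BoundaryFluxSet(
        O2_flux_at_disk=o2_flux, H_flux_at_disk=n_electrons * o2_flux
    )


def analytic_microdisk_limiting_current(
    medium: MediumProperties, disk_radius: float, n_electrons: int = 4
) -> float:
    """Unhindered bulk diffusion-limited current magnitude, 4 n F D c a.

    Closed form for an inlaid disk in an infinite half-space; serves as
    the independent oracle for the numerical solver in the limit of
    large working distance.
    """
    if disk_radius <= 0:
        raise ValueError("disk_radius must be > 0")
    return 4.0 * n_electrons * FARADAY * medium.D_O2 * medium.c_O2_bulk * disk_radius


def diffusion_limited_current(
    geometry: ElectrodeGeometry,
    medium: MediumProperties,
    cells: list[CellModel] | tuple[CellModel, ...] = (),
    n_electrons: int = 4,
    refinement_level: int = 1,
) -> float:
    """Hindered diffusion-limited ORR current (A, negative = cathodic).

    Solves the steady axisymmetric diffusion problem with ``c = 0`` on
    the disk face, no-flux on the glass and the substrate, bulk
    concentration on the far boundary and the cellular respiration
    sinks active, then integrates the O2 flux over the disk:
    ``i_lim = -n F * (total disk O2 flux)``.
    """
    # imported here to avoid a circular module import at load time
    from .rd_solver import build_mesh, steady_limiting_flux

    mesh = build_mesh(geometry, refinement_level=refinement_level, cells=cells)
    total_flux = steady_limiting_flux(mesh, medium, cells=cells)
    return -n_electrons * FARADAY * total_flux


def check_current_admissible(current: float, i_lim: float) -> bool:
    """True iff the galvanostatic set-point stays below the transport limit."""
    if i_lim >= 0:
        raise ValueError("i_lim must be negative (cathodic)")
    return abs(current) < abs(i_lim)
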