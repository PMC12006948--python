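"""Axisymmetric (r, z) finite-volume solver for O2 and buffered proton transport.

The domain is the aqueous gap and surrounding bath between the dish
floor (z = 0) and the microelectrode: a cylinder of radius
``domain_radius`` and height ``domain_height`` minus the electrode
body (disk + glass sheath, occupying ``z > z_face`` for
``r < sheath_radius``) and minus the spherical-cap cell sitting on the
floor at the axis.  Boundary conditions:

* disk face (``z = z_face``, ``r < disk_radius``): either a uniform
  consumption flux (galvanostatic operation) or ``c = 0`` (Dirichlet,
  used for the diffusion-limited current),
* glass sheath underside and side wall, substrate, axis: no flux,
* far boundary (outer radius and top): bulk concentrations,
* cell cap surface: uniform respiration (O2 consumption) flux.

Transport is pure diffusion.  Acid-base chemistry uses the
fast-equilibrium assumption: the species H+, HA and A- diffuse
independently within a time step and are then re-equilibrated locally
(see :func:`equilibrate_buffer`).  The proton consumption of the ORR
(4 H+ per O2) is applied to the HA pool, the dominant proton carrier
at physiological pH; the equilibration step redistributes it.

Concentrations are mol m^-3 throughout; pH = -log10([H+] / (1000 mol m^-3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrochem import BoundaryFluxSet
from .model_core import (
    CellModel,
    ElectrodeGeometry,
    MediumProperties,
    ValidationError,
)


class SolverError(RuntimeError):
    """Steady or transient solve failed or produced an unphysical state."""


# ---------------------------------------------------------------------------
# mesh generation


def _graded(x0: float, x1: float, dx0: float, dx1: float) -> np.ndarray:
    """Points from x0 to x1 with spacing grading geometrically dx0 -> dx1."""
    length = x1 - x0
    if length <= 0:
        raise ValueError("segment must have positive length")
    dx0 = min(dx0, length)
    dx1 = min(dx1, length)
    if abs(dx1 - dx0) < 1e-9 * max(dx0, dx1):
        n = max(1, round(length / dx0))
        return np.linspace(x0, x1, n + 1)
    # n intervals with dx_k = dx0 * g^k and dx_{n-1} = dx1; pick the
    # smallest n whose total span reaches the segment, then rescale.
    n = 2
    for n in range(2, 100000):
        g = (dx1 / dx0) ** (1.0 / (n - 1))
        total = dx0 * (g**n - 1.0) / (g - 1.0)
        if total >= length:
            break
    g = (dx1 / dx0) ** (1.0 / (n - 1))
    dx = dx0 * g ** np.arange(n)
    if n > 2:
        # keep the end spacings exact (they set the local resolution);
        # absorb the length mismatch in the interior spacings
        interior = dx[1:-1].sum()
        target = length - dx[0] - dx[-1]
        if target > 0 and interior > 0:
            dx[1:-1] *= target / interior
        else:
            dx *= length / dx.sum()
    else:
        dx *= length / dx.sum()
    return x0 + np.concatenate([[0.0], np.cumsum(dx)])


def _merge(*segments: np.ndarray) -> np.ndarray:
    pts = [segments[0]]
    for seg in segments[1:]:
        pts.append(seg[1:])
    return np.concatenate(pts)


@dataclass
class Mesh:
    """Structured, graded axisymmetric finite-volume mesh.

    ``active[j, i]`` marks fluid cells (row j = axial index, column
    i = radial index); the electrode body and the cell cap interior are
    inactive.  Boundary faces are pre-classified into the tag lists
    below; every boundary face of the active region carries exactly one
    tag.  Face conductances are stored for unit diffusivity and scale
    linearly with D.
    """

    geometry: ElectrodeGeometry
    r_faces: np.ndarray
    z_faces: np.ndarray
    active: np.ndarray  # bool (nz, nr)
    index: np.ndarray  # int (nz, nr), -1 for inactive
    volumes: np.ndarray  # (n_active,)
    z_face: float  # axial position of the electrode face
    cell: CellModel | None
    # unit-diffusivity interior Laplacian (SPD, conductance form)
    laplacian_unit: sp.csr_matrix = field(repr=False, default=None)
    # Dirichlet (bulk) faces: (cell index, unit conductance)
    bulk_idx: np.ndarray = field(repr=False, default=None)
    bulk_g_unit: np.ndarray = field(repr=False, default=None)
    # disk faces: (cell index, face area, unit conductance)
    disk_idx: np.ndarray = field(repr=False, default=None)
    disk_area: np.ndarray = field(repr=False, default=None)
    disk_g_unit: np.ndarray = field(repr=False, default=None)
    # cell-surface bands: (cell index, true cap band area)
    cell_idx: np.ndarray = field(repr=False, default=None)
    cell_band_area: np.ndarray = field(repr=False, default=None)
    # tag -> face count, for boundary-completeness checks
    boundary_tag_counts: dict = field(default_factory=dict)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a flat active-cell vector onto the (nz, nr) grid."""
        grid = np.full(self.active.shape, fill)
        grid[self.active] = values
        return grid


def build_mesh(
    geometry: ElectrodeGeometry,
    refinement_level: int = 1,
    cells: Sequence[CellModel] = (),
) -> Mesh:
    """Build a graded axisymmetric mesh for the electrode-over-cell domain.

    Refinement is concentrated at the disk edge (r = disk_radius,
    z = z_face), where the flux density of the disk is singular; each
    extra ``refinement_level`` halves the spacing there.  At most one
    cell is supported and it must sit on the axis (off-axis scenes are
    the 3D solver's job).
    """
    if refinement_level < 0:
        raise ValidationError("refinement_level must be >= 0")
    if len(cells) > 1:
        raise ValidationError("the axisymmetric solver supports at most one cell")
    cell = cells[0] if cells else None
    if cell is not None and (cell.center_xy[0] != 0.0 or cell.center_xy[1] != 0.0):
        raise ValidationError("the axisymmetric cell must be centred on the axis")
    if cell is not None and cell.base_radius >= geometry.sheath_radius:
        raise ValidationError("cell base must fit under the sheath")

    a = geometry.disk_radius
    rs = geometry.sheath_radius
    R = geometry.domain_radius
    hc = cell.cap_height if cell is not None else 0.0
    z_face = geometry.working_distance + hc
    H = geometry.domain_height + hc
    scale = 2.0 ** (refinement_level - 1)

    # radial grid: fine inside the disk, finest at the edge, coarsening
    # towards the sheath rim and the far boundary
    dr_edge = a / (30.0 * scale)
    dr_axis = a / (8.0 * scale)
    r_faces = _merge(
        _graded(0.0, a, dr_axis, dr_edge),
        _graded(a, rs, dr_edge, (rs - a) / (10.0 * scale)),
        _graded(rs, R, (rs - a) / (10.0 * scale), (R - rs) / (8.0 * scale)),
    )

    # axial grid: resolve the cap, the gap and the disk face
    dz_face = a / (30.0 * scale)
    gap = z_face - hc
    segs = []
    if hc > 0:
        segs.append(_graded(0.0, hc, hc / (6.0 * scale), hc / (6.0 * scale)))
    segs.append(_graded(hc, z_face, gap / (12.0 * scale), dz_face))
    segs.append(_graded(z_face, H, dz_face, (H - z_face) / (10.0 * scale)))
    z_faces = _merge(*segs)

    rc = 0.5 * (r_faces[:-1] + r_faces[1:])
    zc = 0.5 * (z_faces[:-1] + z_faces[1:])
    nr, nz = len(rc), len(zc)

    active = np.ones((nz, nr), dtype=bool)
    # electrode body (disk + glass) above the face
    body = (zc[:, None] > z_face) & (rc[None, :] < rs)
    active &= ~body
    # cell cap interior
    if cell is not None:
        prof = np.array([cell.profile_radius(z) for z in zc])
        cap = rc[None, :] <= prof[:, None]
        cap &= (zc[:, None] <= hc)
        active &= ~cap

    index = np.full((nz, nr), -1, dtype=np.int64)
    index[active] = np.arange(active.sum())

    dz = np.diff(z_faces)
    ann = np.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)  # annulus areas
    vol_grid = dz[:, None] * ann[None, :]
    volumes = vol_grid[active]

    rows, cols, vals = [], [], []
    diag = np.zeros(active.sum())

    def add_pair(p: int, q: int, g: float) -> None:
        diag[p] += g
        diag[q] += g
        rows.append(p)
        cols.append(q)
        vals.append(-g)
        rows.append(q)
        cols.append(p)
        vals.append(-g)

    # radial interior faces
    for j in range(nz):
        for i in range(nr - 1):
            if active[j, i] and active[j, i + 1]:
                area = 2.0 * np.pi * r_faces[i + 1] * dz[j]
                g = area / (rc[i + 1] - rc[i])
                add_pair(index[j, i], index[j, i + 1], g)
    # axial interior faces
    for j in range(nz - 1):
        for i in range(nr):
            if active[j, i] and active[j + 1, i]:
                g = ann[i] / (zc[j + 1] - zc[j])
                add_pair(index[j, i], index[j + 1, i], g)

    lap = sp.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(len(diag))]),
          np.concatenate([cols, np.arange(len(diag))]))),
        shape=(len(diag), len(diag)),
    ).tocsr()

    tags: dict[str, int] = {
        "axis": 0, "substrate": 0, "glass": 0, "disk": 0, "bulk": 0,
        "cell_surface": 0,
    }

    # classify boundary faces
    bulk_idx, bulk_g = [], []
    disk_idx, disk_area, disk_g = [], [], []
    j_below_face = int(np.searchsorted(z_faces, z_face) - 1)  # row just under the face
    for j in range(nz):
        for i in range(nr):
            if not active[j, i]:
                continue
            p = index[j, i]
            # axis
            if i == 0:
                tags["axis"] += 1
            # outer radius -> bulk Dirichlet
            if i == nr - 1:
                g = 2.0 * np.pi * r_faces[-1] * dz[j] / (r_faces[-1] - rc[i])
                bulk_idx.append(p)
                bulk_g.append(g)
                tags["bulk"] += 1
            # substrate
            if j == 0:
                tags["substrate"] += 1
            # top -> bulk Dirichlet (only open for r > sheath)
            if j == nz - 1:
                g = ann[i] / (z_faces[-1] - zc[j])
                bulk_idx.append(p)
                bulk_g.append(g)
                tags["bulk"] += 1
            # faces against the electrode body
            if j + 1 < nz and not active[j + 1, i] and zc[j + 1] > z_face:
                if rc[i] < a:
                    g = ann[i] / (z_face - zc[j])
                    disk_idx.append(p)
                    disk_area.append(ann[i])
                    disk_g.append(g)
                    tags["disk"] += 1
                else:
                    tags["glass"] += 1
            if i + 1 < nr and not active[j, i + 1] and zc[j] > z_face:
                tags["glass"] += 1  # sheath side wall
            # faces against the cap interior are tagged through the
            # band construction below; count them here
            if cell is not None:
                if i > 0 and not active[j, i - 1] and zc[j] <= hc:
                    tags["cell_surface"] += 1
                if j > 0 and not active[j - 1, i] and zc[j - 1] <= hc and rc[i] < rs:
                    tags["cell_surface"] += 1

    # cell-surface quadrature bands: for every axial slab intersecting
    # [0, cap_height] the true lateral cap area is 2*pi*R_sphere*dz; the
    # representative fluid cell is the first active cell outside the
    # cap profile in that row.  Weights therefore sum to the closed-form
    # cap area exactly.
    cell_idx, cell_area = [], []
    if cell is not None:
        Rs = cell.sphere_radius
        for j in range(nz):
            lo = max(z_faces[j], 0.0)
            hi = min(z_faces[j + 1], hc)
            if hi <= lo:
                continue
            band = 2.0 * np.pi * Rs * (hi - lo)
            zmid = min(zc[j], hc)
            prof = cell.profile_radius(zmid)
            i = int(np.searchsorted(rc, prof))
            while i < nr and not active[j, i]:
                i += 1
            if i >= nr:
                raise SolverError("no fluid cell adjacent to the cap surface")
            cell_idx.append(index[j, i])
            cell_area.append(band)

    mesh = Mesh(
        geometry=geometry,
        r_faces=r_faces,
        z_faces=z_faces,
        active=active,
        index=index,
        volumes=volumes,
        z_face=z_face,
        cell=cell,
        laplacian_unit=lap,
        bulk_idx=np.asarray(bulk_idx, dtype=np.int64),
        bulk_g_unit=np.asarray(bulk_g, dtype=float),
        disk_idx=np.asarray(disk_idx, dtype=np.int64),
        disk_area=np.asarray(disk_area, dtype=float),
        disk_g_unit=np.asarray(disk_g, dtype=float),
        cell_idx=np.asarray(cell_idx, dtype=np.int64),
        cell_band_area=np.asarray(cell_area, dtype=float),
        boundary_tag_counts=tags,
    )
    if mesh.disk_idx.size == 0:
        raise SolverError("mesh has no disk faces; refine the grid")
    return mesh


# ---------------------------------------------------------------------------
# buffer speciation


def equilibrate_buffer(total_H, total_buffer, buffer):
    """Local fast-equilibrium speciation of a monoprotic buffer.

    Given conserved totals ``total_H = [H+] + [HA]`` and
    ``total_buffer = [HA] + [A-]`` (mol m^-3), returns the equilibrium
    ``([H+], [HA], [A-])`` satisfying [H+][A-] = Ka [HA] exactly.

    Uses the numerically stable root of the proton quadratic
    H^2 + (TB - TH + Ka) H - Ka TH = 0 (no catastrophic cancellation
    on either branch), then speciates the buffer from [H+].
    """
    TH = np.asarray(total_H, dtype=float)
    TB = np.asarray(total_buffer, dtype=float)
    if np.any(TH < 0) or np.any(TB < 0):
        raise ValueError("totals must be >= 0")
    Ka = buffer.Ka
    b = TB - TH + Ka
    disc = np.sqrt(b * b + 4.0 * Ka * TH)
    H = np.where(b >= 0, 2.0 * Ka * TH / (b + disc), 0.5 * (disc - b))
    HA = TB * H / (H + Ka)
    A = TB * Ka / (H + Ka)
    # free protons beyond the buffer capacity (only matters for TH > TB)
    H = TH - HA
    if np.ndim(total_H) == 0:
        return float(H), float(HA), float(A)
    return H, HA, A


def bulk_speciation(medium: MediumProperties) -> dict[str, float]:
    """Bulk equilibrium concentrations (mol m^-3) at the configured pH."""
    buf = medium.buffer
    H = 10.0 ** (-medium.bulk_pH) * 1e3
    HA = buf.total_concentration * H / (H + buf.Ka)
    A = buf.total_concentration * buf.Ka / (H + buf.Ka)
    return {"O2": medium.c_O2_bulk, "H": H, "HA": HA, "A": A}


def ph_from_H(H) -> np.ndarray:
    """pH from a free-proton concentration in mol m^-3."""
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("non-positive [H+]")
    return -np.log10(H / 1e3)


# ---------------------------------------------------------------------------
# fields and results


@dataclass
class Field:
    """Concentrations of {O2, H, HA, A} on the active cells of a mesh."""

    mesh: Mesh
    species: dict[str, np.ndarray]

    def ph(self) -> np.ndarray:
        return ph_from_H(self.species["H"])


@dataclass
class TransientResult:
    """Per-probe averages over time from a transient solve."""

    times: np.ndarray
    o2_cell: np.ndarray  # area-weighted cap-surface average, mol m^-3
    ph_cell: np.ndarray  # area-weighted cap-surface average pH
    o2_substrate: np.ndarray  # substrate-surface value on the axis
    snapshots: dict = field(default_factory=dict)


def ph_field(fld: Field) -> np.ndarray:
    """pH on the mesh, -log10([H+] / mol L^-1)."""
    return fld.ph()


def average_cell_surface(obj, cell: CellModel | None = None, quantity: str = "O2"):
    """Area-weighted mean of a quantity over the cell cap surface.

    ``obj`` may be a :class:`Field` (returns a scalar) or a
    :class:`TransientResult` (returns the stored trace for the
    requested quantity, "O2" or "pH").
    """
    if isinstance(obj, TransientResult):
        return obj.o2_cell if quantity == "O2" else obj.ph_cell
    mesh = obj.mesh
    if mesh.cell_idx is None or mesh.cell_idx.size == 0:
        raise SolverError("mesh has no tagged cell surface")
    w = mesh.cell_band_area
    if quantity == "pH":
        vals = ph_from_H(obj.species["H"][mesh.cell_idx])
    else:
        vals = obj.species[quantity][mesh.cell_idx]
    return float(np.sum(w * vals) / np.sum(w))


# ---------------------------------------------------------------------------
# steady solves


def _steady_matrix(mesh: Mesh, D: float, disk_dirichlet: bool) -> sp.csc_matrix:
    diag_add = np.zeros(mesh.n_active)
    np.add.at(diag_add, mesh.bulk_idx, D * mesh.bulk_g_unit)
    if disk_dirichlet:
        np.add.at(diag_add, mesh.disk_idx, D * mesh.disk_g_unit)
    return (D * mesh.laplacian_unit + sp.diags(diag_add)).tocsc()

def _respiration_sink(mesh: Mesh) -> np.ndarray:
    """Cell-surface O2 consumption (mol s^-1) per active cell."""
    q = np.zeros(mesh.n_active)
    if mesh.cell is not None and mesh.cell_idx.size:
        np.add.at(q, mesh.cell_idx, mesh.cell.respiration_flux * mesh.cell_band_area)
    return q


def _solve_species_steady(
    mesh: Mesh,
    D: float,
    c_bulk: float,
    disk_sink_per_area: float,
    extra_sink: np.ndarray | None = None,
    disk_dirichlet: bool = False,
) -> np.ndarray:
    A = _steady_matrix(mesh, D, disk_dirichlet)
    b = np.zeros(mesh.n_active)
    np.add.at(b, mesh.bulk_idx, D * mesh.bulk_g_unit * c_bulk)
    if not disk_dirichlet and disk_sink_per_area:
        np.add.at(b, mesh.disk_idx, -disk_sink_per_area * mesh.disk_area)
    if extra_sink is not None:
        b -= extra_sink
    c = spla.spsolve(A, b)
    return c


def _o2_disk_solve(
    mesh: Mesh,
    D: float,
    c_bulk: float,
    Q_total: float,
    resp_sink: np.ndarray,
    dt: float | None = None,
    c_old: np.ndarray | None = None,
    saturated0: np.ndarray | None = None,
    lu_cache: dict | None = None,
):
    """O2 solve with a saturating galvanostatic disk.

    The galvanostatic boundary is a uniform consumption flux with total
    rate ``Q_total`` (mol s^-1).  Where the uniform draw would drive
    the surface concentration negative — which happens at the disk
    centre when operating close to the transport limit — those faces
    saturate to the Dirichlet condition c = 0 and the flux deficit is
    redistributed uniformly over the unsaturated remainder, as an
    equipotential disk under constant-current control would do.

    Returns ``(c, q_faces, saturated)`` with ``q_faces`` the realised
    per-face consumption (mol s^-1).  Raises :class:`SolverError` when
    the full disk saturates and still cannot deliver ``Q_total``
    (current above the diffusion limit).
    """
    n_faces = mesh.disk_idx.size
    saturated = (
        saturated0.copy() if saturated0 is not None else np.zeros(n_faces, bool)
    )
    areas = mesh.disk_area
    face_cells = mesh.disk_idx

    def factorize(sat: np.ndarray):
        key = (dt, D, sat.tobytes())
        if lu_cache is not None and key in lu_cache:
            return lu_cache[key]
        diag_add = np.zeros(mesh.n_active)
        np.add.at(diag_add, mesh.bulk_idx, D * mesh.bulk_g_unit)
        np.add.at(diag_add, face_cells[sat], D * mesh.disk_g_unit[sat])
        M = D * mesh.laplacian_unit + sp.diags(diag_add)
        if dt is not None:
            M = M + sp.diags(mesh.volumes / dt)
        lu = spla.splu(M.tocsc())
        if lu_cache is not None:
            lu_cache[key] = lu
        return lu

    c = None
    for _outer in range(n_faces + 2):
        lu = factorize(saturated)
        A_unsat = areas[~saturated].sum()
        Q_sat = 0.0
        J_u = 0.0
        for _inner in range(60):
            J_u = max(Q_total - Q_sat, 0.0) / A_unsat if A_unsat > 0 else 0.0
            b = np.zeros(mesh.n_active)
            np.add.at(b, mesh.bulk_idx, D * mesh.bulk_g_unit * c_bulk)
            b -= resp_sink
            np.add.at(b, face_cells[~saturated], -J_u * areas[~saturated])
            if dt is not None:
                b += mesh.volumes / dt * c_old
            c = lu.solve(b)
            Q_sat_new = float(
                np.sum(D * mesh.disk_g_unit[saturated] * c[face_cells[saturated]])
            )
            if abs(Q_sat_new - Q_sat) <= 1e-10 * max(Q_total, 1e-30):
                Q_sat = Q_sat_new
                break
            Q_sat = Q_sat_new
        newly = (~saturated) & (c[face_cells] < 0)
        if newly.any():
            saturated |= newly
            if saturated.all() and Q_total > 0:
                # check whether the fully saturated disk can deliver Q_total
                lu = factorize(saturated)
                b = np.zeros(mesh.n_active)
                np.add.at(b, mesh.bulk_idx, D * mesh.bulk_g_unit * c_bulk)
                b -= resp_sink
                if dt is not None:
                    b += mesh.volumes / dt * c_old
                c = lu.solve(b)
                Q_sat = float(
                    np.sum(D * mesh.disk_g_unit * c[face_cells])
                )
                if Q_sat < Q_total * (1.0 - 1e-6):
                    raise SolverError(
                        "applied current exceeds the diffusion-limited value; "
                        "check diffusion_limited_current"
                    )
                break
            continue
        break
    if c.min() < -1e-6 * c_bulk:
        raise SolverError(
            "O2 went negative away from the disk: current exceeds the "
            "transport limit; check diffusion_limited_current"
        )
    c = np.clip(c, 0.0, None)
    q_faces = np.where(
        saturated,
        D * mesh.disk_g_unit * c[face_cells],
        J_u * areas,
    )
    return c, q_faces, saturated


def steady_limiting_flux(
    mesh: Mesh, medium: MediumProperties, cells: Sequence[CellModel] = ()
) -> float:
    """Total O2 consumption (mol s^-1, > 0) of the disk at c_disk = 0.

    Steady Dirichlet solve with the respiration sinks active; the flux
    is integrated over the disk faces.
    """
    D = medium.D_O2
    c = _solve_species_steady(
        mesh, D, medium.c_O2_bulk, 0.0,
        extra_sink=_respiration_sink(mesh), disk_dirichlet=True,
    )
    return float(np.sum(D * mesh.disk_g_unit * c[mesh.disk_idx]))


def solve_steady(
    mesh: Mesh,
    medium: MediumProperties,
    fluxes: BoundaryFluxSet,
    cells: Sequence[CellModel] = (),
) -> Field:
    """Steady state under a galvanostatic (uniform-flux) disk boundary.

    O2 diffuses with the disk and respiration sinks.  The proton
    balance is solved on the conserved total ``[H+] + [HA]`` with the
    buffer diffusivity (free protons are a ~1e-6 fraction of the total
    at physiological pH, so their faster diffusion is negligible) and
    then speciated against the uniform total buffer concentration.
    """
    bulk = bulk_speciation(medium)
    n_over_1 = (
        fluxes.H_flux_at_disk / fluxes.O2_flux_at_disk
        if fluxes.O2_flux_at_disk > 0
        else 0.0
    )
    Q_total = fluxes.O2_flux_at_disk * float(mesh.disk_area.sum())
    o2, q_faces, _sat = _o2_disk_solve(
        mesh, medium.D_O2, bulk["O2"], Q_total, _respiration_sink(mesh)
    )

    buf = medium.buffer
    th_bulk = bulk["H"] + bulk["HA"]
    # proton consumption follows the realised O2 flux distribution
    h_sink = np.zeros(mesh.n_active)
    np.add.at(h_sink, mesh.disk_idx, n_over_1 * q_faces)
    th = _solve_species_steady(
        mesh, buf.D_HA, th_bulk, 0.0, extra_sink=h_sink,
    )
    if th.min() < 0:
        raise SolverError(
            "total-proton field went negative: proton transport limit exceeded"
        )
    tb = np.full_like(th, buf.total_concentration)
    H, HA, A = equilibrate_buffer(th, tb, buf)
    return Field(mesh=mesh, species={"O2": o2, "H": H, "HA": HA, "A": A})


# ---------------------------------------------------------------------------
# transient solve


def _probe(mesh: Mesh, species: dict[str, np.ndarray]):
    if mesh.cell_idx is not None and mesh.cell_idx.size:
        w = mesh.cell_band_area / mesh.cell_band_area.sum()
        o2c = float(np.sum(w * species["O2"][mesh.cell_idx]))
        phc = float(np.sum(w * ph_from_H(species["H"][mesh.cell_idx])))
    else:
        o2c = np.nan
        phc = np.nan
    # substrate point on the axis (first active cell of the bottom rows)
    j = 0
    while not mesh.active[j, :].any():
        j += 1
    i = int(np.argmax(mesh.active[j, :]))
    p = mesh.index[j, i]
    o2s = float(species["O2"][p])
    return o2c, phc, o2s


def solve_transient(
    mesh: Mesh,
    medium: MediumProperties,
    fluxes: BoundaryFluxSet,
    cells: Sequence[CellModel] = (),
    t_end: float = 300.0,
    output_times: Sequence[float] | None = None,
    dt_initial: float = 1e-3,
    dt_max: float | None = None,
    dt_growth: float = 1.3,
    store_snapshots: bool = False,
    initial_field: Field | None = None,
) -> TransientResult:
    """Implicit (backward-Euler) transient solve of the challenge.

    The initial condition is the respiration-only steady state (the
    pre-challenge situation); at t = 0 the galvanostatic disk fluxes
    switch on.  Each species is diffused implicitly over a step, then
    the buffer is re-equilibrated locally.  The step size ramps
    geometrically from ``dt_initial`` (default 1 ms) to ``dt_max``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt_max is None:
        dt_max = max(t_end / 100.0, dt_initial)
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 61)
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times[0] > 0:
        output_times = np.concatenate([[0.0], output_times])

    bulk = bulk_speciation(medium)
    buf = medium.buffer
    if initial_field is not None:
        species = {k: v.copy() for k, v in initial_field.species.items()}
    else:
        o2_0 = _solve_species_steady(
            mesh, medium.D_O2, bulk["O2"], 0.0, extra_sink=_respiration_sink(mesh)
        )
        species = {
            "O2": np.clip(o2_0, 0.0, None),
            "H": np.full(mesh.n_active, bulk["H"]),
            "HA": np.full(mesh.n_active, bulk["HA"]),
            "A": np.full(mesh.n_active, bulk["A"]),
        }

    diffusivities = {"H": buf.D_H, "HA": buf.D_HA, "A": buf.D_A}
    c_bulk = {"H": bulk["H"], "HA": bulk["HA"], "A": bulk["A"]}
    resp_sink = _respiration_sink(mesh)
    Q_total = fluxes.O2_flux_at_disk * float(mesh.disk_area.sum())
    n_over_1 = (
        fluxes.H_flux_at_disk / fluxes.O2_flux_at_disk
        if fluxes.O2_flux_at_disk > 0
        else 0.0
    )

    lu_cache: dict = {}
    sat_state = np.zeros(mesh.disk_idx.size, bool)

    def step(dt: float) -> None:
        nonlocal sat_state
        o2, q_faces, sat_state = _o2_disk_solve(
            mesh, medium.D_O2, bulk["O2"], Q_total, resp_sink,
            dt=dt, c_old=species["O2"], saturated0=sat_state, lu_cache=lu_cache,
        )
        species["O2"] = o2
        ha_sink = np.zeros(mesh.n_active)
        np.add.at(ha_sink, mesh.disk_idx, n_over_1 * q_faces)
        for name in ("H", "HA", "A"):
            D = diffusivities[name]
            key = (dt, D)
            if key not in lu_cache:
                diag_add = np.zeros(mesh.n_active)
                np.add.at(diag_add, mesh.bulk_idx, D * mesh.bulk_g_unit)
                M = (sp.diags(mesh.volumes / dt)
                     + D * mesh.laplacian_unit
                     + sp.diags(diag_add)).tocsc()
                lu_cache[key] = spla.splu(M)
            b = mesh.volumes / dt * species[name]
            if name == "HA":
                b -= ha_sink
            np.add.at(b, mesh.bulk_idx, D * mesh.bulk_g_unit * c_bulk[name])
            species[name] = lu_cache[key].solve(b)
        th = species["H"] + species["HA"]
        tb = species["HA"] + species["A"]
        if th.min() < 0 or tb.min() < 0:
            raise SolverError("buffer totals went negative during the solve")
        H, HA, A = equilibrate_buffer(th, tb, buf)
        species["H"], species["HA"], species["A"] = H, HA, A

    times_rec, o2c_rec, phc_rec, o2s_rec = [], [], [], []
    snapshots: dict[float, Field] = {}

    def record(t: float) -> None:
        o2c, phc, o2s = _probe(mesh, species)
        times_rec.append(t)
        o2c_rec.append(o2c)
        phc_rec.append(phc)
        o2s_rec.append(o2s)
        if store_snapshots:
            snapshots[t] = Field(
                mesh=mesh, species={k: v.copy() for k, v in species.items()}
            )

    t = 0.0
    if output_times[0] == 0.0:
        record(0.0)
    next_out = iter(output_times[output_times > 0.0])
    t_next = next(next_out, None)
    dt = dt_initial
    min_dt = dt_initial * 1e-6
    while t < t_end - 1e-12:
        target = t_end if t_next is None else min(t_next, t_end)
        dt_step = min(dt, target - t)
        if dt_step < min_dt:
            raise SolverError("time step collapsed below the minimum")
        step(dt_step)
        t += dt_step
        if t_next is not None and t >= t_next - 1e-12:
            record(t)
            t_next = next(next_out, None)
        dt = min(dt * dt_growth, dt_max)

    return TransientResult(
        times=np.asarray(times_rec),
        o2_cell=np.asarray(o2c_rec),
        ph_cell=np.asarray(phc_rec),
        o2_substrate=np.asarray(o2s_rec),
        snapshots=snapshots,
    )


def time_to_steady_state(result: TransientResult, fraction: float = 0.05) -> float:
    """First time the cell-surface O2 is within ``fraction`` of its final change.

    The plateau is the last recorded value; the trace must actually
    have flattened (last two samples within the same band), otherwise
    the run was too short and an error is raised.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    trace = result.o2_cell
    if np.any(np.isnan(trace)):
        trace = result.o2_substrate
    if len(trace) < 3:
        raise ValueError("trace too short")
    change = trace[-1] - trace[0]
    if change == 0:
        return 0.0
    band = fraction * abs(change)
    if abs(trace[-1] - trace[-2]) > band:
        raise SolverError(
            "trace has not plateaued; extend t_end before measuring the "
            "time to steady state"
        )
    within = np.abs(trace - trace[-1]) <= band
    # first index after which the trace stays inside the band
    stay = np.flip(np.logical_and.accumulate(np.flip(within)))
    idx = int(np.argmax(stay))
    return float(result.times[idx])
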