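"""3D Cartesian finite-volume O2 solver for a target cell plus neighbours.

The electrode sits above one *target* cell on the z axis; neighbouring
cells at arbitrary (x, y) positions share the depletion zone, so each
cell sees an exposure that decays with its lateral distance from the
electrode axis.  Only oxygen is transported here (the pH problem is
axisymmetric and solved in :mod:`galvox.rd_solver`).

The grid is a graded tensor-product Cartesian mesh; the electrode body
and the spherical-cap cell interiors are blanked out stair-step
fashion.  Respiration fluxes and surface averages use the exposed
stair-step faces of each cap, with the total respiration scaled to the
closed-form cap area.  This deliberately coarse geometry is gated by
agreement with the axisymmetric solver for a single centred cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import (
    FARADAY,
    CellModel,
    ElectrodeGeometry,
    MediumProperties,
    ValidationError,
)
from .rd_solver import SolverError, _graded, _merge


@dataclass(frozen=True)
class Scene3D:
    """Electrode over a group of adherent cells in a box domain.

    The electrode axis is x = y = 0 and must pass over exactly one
    cell (the target); the working distance is measured from that
    cell's apex.  Cells must not overlap at their bases and must sit
    inside the lateral domain margin.
    """

    geometry: ElectrodeGeometry
    cells: tuple[CellModel, ...]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValidationError("scene needs at least one cell")
        on_axis = [
            c for c in self.cells
            if np.hypot(*c.center_xy) < c.base_radius
        ]
        if len(on_axis) != 1:
            raise ValidationError(
                "the electrode axis must pass over exactly one target cell"
            )
        for i, c1 in enumerate(self.cells):
            for c2 in self.cells[i + 1:]:
                d = np.hypot(c1.center_xy[0] - c2.center_xy[0],
                             c1.center_xy[1] - c2.center_xy[1])
                if d < c1.base_radius + c2.base_radius:
                    raise ValidationError("cell bases overlap")
        half = self.half_width
        for c in self.cells:
            if max(abs(c.center_xy[0]), abs(c.center_xy[1])) + c.base_radius > half:
                raise ValidationError("cell outside the lateral domain margin")

    @property
    def target(self) -> CellModel:
        return next(
            c for c in self.cells if np.hypot(*c.center_xy) < c.base_radius
        )

    @property
    def target_index(self) -> int:
        return next(
            i for i, c in enumerate(self.cells)
            if np.hypot(*c.center_xy) < c.base_radius
        )

    @property
    def z_face(self) -> float:
        return self.geometry.working_distance + self.target.cap_height

    @property
    def half_width(self) -> float:
        span = max(
            abs(c.center_xy[k]) + c.base_radius
            for c in self.cells for k in (0, 1)
        )
        return max(self.geometry.domain_radius, span + 25 * self.geometry.disk_radius)


@dataclass
class Grid3D:
    x_faces: np.ndarray
    y_faces: np.ndarray
    z_faces: np.ndarray
    active: np.ndarray  # (nz, ny, nx)
    index: np.ndarray
    volumes: np.ndarray  # (n_active,)
    laplacian_unit: sp.csr_matrix = field(repr=False, default=None)
    bulk_idx: np.ndarray = field(repr=False, default=None)
    bulk_g_unit: np.ndarray = field(repr=False, default=None)
    disk_idx: np.ndarray = field(repr=False, default=None)
    disk_area: np.ndarray = field(repr=False, default=None)
    # per cell: (sample indices, weights) over the exposed cap faces
    cell_samples: list = field(default_factory=list)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _axis_1d(half: float, fine_extent: float, dx_fine: float) -> np.ndarray:
    """Symmetric graded axis: uniform dx_fine in |x| < fine_extent, coarsening out."""
    n_fine = max(2, int(round(2 * fine_extent / dx_fine)))
    fine = np.linspace(-fine_extent, fine_extent, n_fine + 1)
    wing = _graded(fine_extent, half, dx_fine, (half - fine_extent) / 6.0)
    return _merge(-wing[::-1], fine, wing)


def build_grid(scene: Scene3D, resolution: float = 2.5e-6) -> Grid3D:
    """Stair-step Cartesian grid for a scene; `resolution` is the fine spacing."""
    geo = scene.geometry
    a = geo.disk_radius
    z_face = scene.z_face
    span = max(
        max(abs(c.center_xy[k]) for k in (0, 1)) + c.base_radius
        for c in scene.cells
    )
    fine_extent = max(span, a) + 4 * a
    half = scene.half_width
    H = z_face + geo.domain_height - geo.working_distance

    xf = _axis_1d(half, fine_extent, resolution)
    yf = xf.copy()
    hmax = max(c.cap_height for c in scene.cells)
    dz_fine = min(resolution, hmax / 4 if hmax > 0 else resolution)
    zf = _merge(
        _graded(0.0, z_face, dz_fine, dz_fine),
        _graded(z_face, H, dz_fine, (H - z_face) / 8.0),
    )

    xc = 0.5 * (xf[:-1] + xf[1:])
    yc = 0.5 * (yf[:-1] + yf[1:])
    zc = 0.5 * (zf[:-1] + zf[1:])
    nx, ny, nz = len(xc), len(yc), len(zc)
    X, Y = np.meshgrid(xc, yc, indexing="xy")  # (ny, nx)
    Rxy = np.sqrt(X**2 + Y**2)

    active = np.ones((nz, ny, nx), dtype=bool)
    body = (zc[:, None, None] > z_face) & (Rxy[None, :, :] < geo.sheath_radius)
    active &= ~body
    for c in scene.cells:
        rc2 = (X - c.center_xy[0]) ** 2 + (Y - c.center_xy[1]) ** 2
        prof = np.array([c.profile_radius(z) for z in zc])
        cap = (rc2[None, :, :] <= prof[:, None, None] ** 2) & (
            zc[:, None, None] <= c.cap_height
        )
        active &= ~cap

    index = np.full((nz, ny, nx), -1, dtype=np.int64)
    index[active] = np.arange(active.sum())
    dx = np.diff(xf)
    dy = np.diff(yf)
    dz = np.diff(zf)
    vol_grid = dz[:, None, None] * dy[None, :, None] * dx[None, None, :]
    volumes = vol_grid[active]

    rows, cols, vals = [], [], []
    diag = np.zeros(active.sum())

    def add_faces(pa: np.ndarray, qa: np.ndarray, g: np.ndarray) -> None:
        np.add.at(diag, pa, g)
        np.add.at(diag, qa, g)
        rows.extend([pa, qa])
        cols.extend([qa, pa])
        vals.extend([-g, -g])

    # x-direction faces
    m = active[:, :, :-1] & active[:, :, 1:]
    area = (dz[:, None, None] * dy[None, :, None] * np.ones(nx - 1))[m]
    dist = (np.ones((nz, ny, 1)) * (xc[1:] - xc[:-1]))[m]
    add_faces(index[:, :, :-1][m], index[:, :, 1:][m], area / dist)
    # y-direction faces
    m = active[:, :-1, :] & active[:, 1:, :]
    area = (dz[:, None, None] * np.ones((1, ny - 1, 1)) * dx[None, None, :])[m]
    dist = (np.ones((nz, 1, nx)) * (yc[1:] - yc[:-1])[None, :, None])[m]
    add_faces(index[:, :-1, :][m], index[:, 1:, :][m], area / dist)
    # z-direction faces
    m = active[:-1, :, :] & active[1:, :, :]
    area = (np.ones((nz - 1, 1, 1)) * dy[None, :, None] * dx[None, None, :])[m]
    dist = (np.ones((1, ny, nx)) * (zc[1:] - zc[:-1])[:, None, None])[m]
    add_faces(index[:-1, :, :][m], index[1:, :, :][m], area / dist)

    rows = np.concatenate(rows + [np.arange(len(diag))])
    cols = np.concatenate(cols + [np.arange(len(diag))])
    vals = np.concatenate(vals + [diag])
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(len(diag),) * 2).tocsr()

    # bulk Dirichlet faces: the four side walls and the open top
    bulk_idx, bulk_g = [], []
    # x walls
    for side, i in ((0, 0), (1, nx - 1)):
        m = active[:, :, i]
        areas = (dz[:, None] * dy[None, :])[m]
        d = (xc[i] - xf[0]) if side == 0 else (xf[-1] - xc[i])
        bulk_idx.append(index[:, :, i][m])
        bulk_g.append(areas / d)
    # y walls
    for side, j in ((0, 0), (1, ny - 1)):
        m = active[:, j, :]
        areas = (dz[:, None] * dx[None, :])[m]
        d = (yc[j] - yf[0]) if side == 0 else (yf[-1] - yc[j])
        bulk_idx.append(index[:, j, :][m])
        bulk_g.append(areas / d)
    # top (only open outside the sheath)
    m = active[nz - 1, :, :]
    areas = (dy[:, None] * dx[None, :])[m]
    bulk_idx.append(index[nz - 1, :, :][m])
    bulk_g.append(areas / (zf[-1] - zc[-1]))
    bulk_idx = np.concatenate(bulk_idx)
    bulk_g = np.concatenate(bulk_g)

    # disk faces: fluid cells directly below the electrode face inside r < a
    k_below = int(np.searchsorted(zf, z_face)) - 1
    m = active[k_below, :, :] & ~active[min(k_below + 1, nz - 1), :, :] & (Rxy < a)
    disk_idx = index[k_below, :, :][m]
    disk_area = (dy[:, None] * dx[None, :])[m]
    if disk_idx.size == 0:
        raise SolverError("grid has no disk faces; refine the resolution")

    grid = Grid3D(
        x_faces=xf, y_faces=yf, z_faces=zf,
        active=active, index=index, volumes=volumes,
        laplacian_unit=lap,
        bulk_idx=bulk_idx, bulk_g_unit=bulk_g,
        disk_idx=disk_idx, disk_area=disk_area,
    )

    # exposed cap faces per cell: fluid cells 6-adjacent to that cap's
    # masked interior, weighted by the shared face area
    for c in scene.cells:
        rc2 = (X - c.center_xy[0]) ** 2 + (Y - c.center_xy[1]) ** 2
        prof = np.array([c.profile_radius(z) for z in zc])
        cap = (rc2[None, :, :] <= prof[:, None, None] ** 2) & (
            zc[:, None, None] <= c.cap_height
        )
        samples: dict[int, float] = {}

        def visit(fluid_slice, cap_slice, idx_slice, face_area):
            m = fluid_slice & cap_slice
            ids = idx_slice[m]
            ar = np.broadcast_to(face_area, fluid_slice.shape)[m]
            for p, w in zip(ids, ar):
                samples[p] = samples.get(p, 0.0) + w

        ax = dz[:, None, None] * dy[None, :, None] * np.ones((1, 1, nx))
        ay = dz[:, None, None] * np.ones((1, ny, 1)) * dx[None, None, :]
        az = np.ones((nz, 1, 1)) * dy[None, :, None] * dx[None, None, :]
        visit(active[:, :, :-1], cap[:, :, 1:], index[:, :, :-1], ax[:, :, :-1])
        visit(active[:, :, 1:], cap[:, :, :-1], index[:, :, 1:], ax[:, :, 1:])
        visit(active[:, :-1, :], cap[:, 1:, :], index[:, :-1, :], ay[:, :-1, :])
        visit(active[:, 1:, :], cap[:, :-1, :], index[:, 1:, :], ay[:, 1:, :])
        visit(active[:-1, :, :], cap[1:, :, :], index[:-1, :, :], az[:-1, :, :])
        visit(active[1:, :, :], cap[:-1, :, :], index[1:, :, :], az[1:, :, :])
        if not samples:
            raise SolverError("cap has no exposed faces on this grid")
        ids = np.array(sorted(samples))
        w = np.array([samples[p] for p in ids])
        grid.cell_samples.append((ids, w / w.sum()))

    return grid


def solve_multicell(
    scene: Scene3D,
    medium: MediumProperties,
    current: float,
    output_times: Sequence[float],
    n_electrons: int = 4,
    resolution: float = 2.5e-6,
    dt_initial: float = 5e-2,
    dt_growth: float = 1.6,
    dt_max: float | None = None,
) -> pd.DataFrame:
    """Transient per-cell O2 exposure under a galvanostatic challenge.

    Returns a tidy frame with columns ``time_s``, ``cell``, ``o2`` where
    ``o2`` is the area-weighted average O2 over each cap surface
    (mol m^-3).  The initial condition is the respiration-only steady
    state; the disk flux switches on at t = 0.
    """
    if current > 0:
        raise ValidationError("current must be cathodic (<= 0)")
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times.size == 0 or output_times[-1] <= 0:
        raise ValidationError("output_times must reach past 0")
    t_end = float(output_times[-1])
    if dt_max is None:
        dt_max = max(t_end / 40.0, dt_initial)

    grid = build_grid(scene, resolution=resolution)
    D = medium.D_O2
    c_bulk = medium.c_O2_bulk

    resp = np.zeros(grid.n_active)
    for c, (ids, w) in zip(scene.cells, grid.cell_samples):
        np.add.at(resp, ids, c.respiration_flux * c.cap_area * w)

    diag_add = np.zeros(grid.n_active)
    np.add.at(diag_add, grid.bulk_idx, D * grid.bulk_g_unit)
    A_steady = (D * grid.laplacian_unit + sp.diags(diag_add)).tocsr()
    b_bulk = np.zeros(grid.n_active)
    np.add.at(b_bulk, grid.bulk_idx, D * grid.bulk_g_unit * c_bulk)

    def cg_solve(A: sp.csr_matrix, b: np.ndarray, x0: np.ndarray) -> np.ndarray:
        # SPD system; Jacobi preconditioning + warm start keeps the
        # per-step cost low on the 3D grid
        Minv = sp.diags(1.0 / A.diagonal())
        scale = float(np.linalg.norm(b)) or 1.0
        x, info = spla.cg(A, b, x0=x0, M=Minv, rtol=1e-10, atol=1e-12 * scale,
                          maxiter=20000)
        if info != 0:
            raise SolverError(f"conjugate-gradient solve failed (info={info})")
        return x

    c0 = cg_solve(A_steady, b_bulk - resp, np.full(grid.n_active, c_bulk))

    Q_total = abs(current) / (n_electrons * FARADAY)
    flux_density = Q_total / grid.disk_area.sum()
    sink = resp.copy()
    np.add.at(sink, grid.disk_idx, flux_density * grid.disk_area)

    def probe(cvec: np.ndarray, t: float) -> list[dict]:
        return [
            {"time_s": t, "cell": k, "o2": float(np.sum(w * cvec[ids]))}
            for k, (ids, w) in enumerate(grid.cell_samples)
        ]

    records: list[dict] = []
    cvec = np.clip(c0, 0.0, None)
    t = 0.0
    if output_times[0] == 0.0:
        records.extend(probe(cvec, 0.0))
    pending = iter(output_times[output_times > 0])
    t_next = next(pending, None)
    dt = dt_initial
    matrices: dict[float, sp.csr_matrix] = {}
    while t < t_end - 1e-12:
        target = t_end if t_next is None else min(t_next, t_end)
        dt_step = min(dt, target - t)
        if dt_step not in matrices:
            matrices[dt_step] = (sp.diags(grid.volumes / dt_step)
                                 + D * grid.laplacian_unit
                                 + sp.diags(diag_add)).tocsr()
        b = grid.volumes / dt_step * cvec + b_bulk - sink
        cvec = cg_solve(matrices[dt_step], b, cvec)
        if cvec.min() < -1e-3 * c_bulk:
            raise SolverError(
                "O2 went negative in the 3D solve; the current is too close "
                "to the diffusion limit for the uniform-flux disk model"
            )
        cvec = np.clip(cvec, 0.0, None)
        t += dt_step
        if t_next is not None and t >= t_next - 1e-12:
            records.extend(probe(cvec, t))
            t_next = next(pending, None)
        dt = min(dt * dt_growth, dt_max)

    return pd.DataFrame.from_records(records)


def exposure_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Per-cell initial/final exposure table.

    ``steady_state_fraction`` is the final O2 divided by the initial
    (pre-challenge) O2 at that cell; 1.0 means unperturbed.
    """
    out = []
    for cell_id, grp in series.groupby("cell"):
        grp = grp.sort_values("time_s")
        o2 = grp["o2"].to_numpy()
        out.append({
            "cell": cell_id,
            "initial_o2": o2[0],
            "final_o2": o2[-1],
            "steady_state_fraction": o2[-1] / o2[0] if o2[0] > 0 else np.nan,
        })
    return pd.DataFrame(out)


def three_cell_cluster_scene(
    geometry: ElectrodeGeometry | None = None,
    neighbour_distances: tuple[float, float] = (40e-6, 45e-6),
) -> Scene3D:
    """Target cell on the axis with two neighbours at similar radial distances.

    Emulates a typical three-cell cluster: the target under the
    electrode, the neighbours ~40 and ~45 um away on opposite sides.
    """
    geometry = geometry or ElectrodeGeometry()
    d1, d2 = neighbour_distances
    cells = (
        CellModel(center_xy=(0.0, 0.0)),
        CellModel(center_xy=(d1, 0.0)),
        CellModel(center_xy=(-d2 * 0.5, d2 * 0.866)),
    )
    return Scene3D(geometry=geometry, cells=cells)
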