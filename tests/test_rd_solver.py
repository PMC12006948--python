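import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from galvox import (
    BufferSystem,
    CellModel,
    ElectrodeGeometry,
    MediumProperties,
    SolverError,
    ValidationError,
    average_cell_surface,
    build_mesh,
    equilibrate_buffer,
    galvanostatic_boundary_flux,
    solve_steady,
    solve_transient,
    time_to_steady_state,
)
from galvox.rd_solver import Field, TransientResult, bulk_speciation, ph_from_H


class TestMesh:
    def test_boundary_tags_complete(self, mesh_l1):
        counts = mesh_l1.boundary_tag_counts
        for tag in ("axis", "substrate", "glass", "disk", "bulk", "cell_surface"):
            assert counts[tag] > 0, f"no {tag} faces tagged"

    def test_volumes_positive_and_sum(self, mesh_l1, geometry, cell):
        assert (mesh_l1.volumes > 0).all()
        # active volume < full cylinder (body and cap removed)
        full = np.pi * geometry.domain_radius**2 * (
            geometry.domain_height + cell.cap_height)
        assert 0.5 * full < mesh_l1.volumes.sum() < full

    def test_refinement_increases_resolution_at_disk_edge(self, geometry, cell):
        def edge_dr(level):
            m = build_mesh(geometry, refinement_level=level, cells=(cell,))
            a = geometry.disk_radius
            i = np.searchsorted(m.r_faces, a)
            return np.diff(m.r_faces)[max(i - 1, 0)]

        assert edge_dr(2) <= edge_dr(1) / 2 * 1.01

    def test_off_axis_cell_rejected(self, geometry):
        with pytest.raises(ValidationError):
            build_mesh(geometry, cells=(CellModel(center_xy=(5e-6, 0.0)),))

    def test_two_cells_rejected(self, geometry, cell):
        with pytest.raises(ValidationError):
            build_mesh(geometry, cells=(cell, cell))


class TestBufferSpeciation:
    def test_midpoint_is_pKa(self):
        # equal acid and base at equilibrium -> pH = pKa
        buf = BufferSystem(total_concentration=20.0, pKa=7.5)
        Ka = buf.Ka
        # construct totals that speciate to [HA] = [A]
        H = Ka
        TH, TB = H + 10.0, 20.0
        h, ha, a = equilibrate_buffer(TH, TB, buf)
        assert ha == pytest.approx(a, rel=1e-9)
        assert float(ph_from_H(h)) == pytest.approx(7.5, abs=1e-9)

    def test_removing_protons_raises_ph(self):
        buf = BufferSystem()
        bulk = bulk_speciation(MediumProperties(buffer=buf))
        TH = bulk["H"] + bulk["HA"]
        h0, _, _ = equilibrate_buffer(TH, 20.0, buf)
        h1, _, _ = equilibrate_buffer(TH - 2.0, 20.0, buf)
        assert ph_from_H(h1) > ph_from_H(h0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        TH=st.floats(1e-6, 40.0),
        TB=st.floats(1e-3, 50.0),
        pKa=st.floats(6.0, 9.0),
    )
    def test_matches_brentq_root_oracle(self, TH, TB, pKa):
        """Speciation equals a brute-force 1D root solve of the
        mass/equilibrium balance to 1e-10 relative."""
        buf = BufferSystem(total_concentration=TB, pKa=pKa)
        Ka = buf.Ka

        def residual(H):
            return H + TB * H / (H + Ka) - TH

        H_oracle = brentq(residual, 0.0, TH, xtol=1e-300, rtol=1e-15)
        h, ha, a = equilibrate_buffer(TH, TB, buf)
        assert h == pytest.approx(H_oracle, rel=1e-10)
        # conservation and equilibrium hold exactly
        assert ha + a == pytest.approx(TB, rel=1e-12)
        assert h + ha == pytest.approx(TH, rel=1e-12)
        assert h * a == pytest.approx(Ka * ha, rel=1e-9)

    def test_ph_unit_conversion(self):
        # 1e-4 mol/m^3 = 1e-7 mol/L -> pH 7
        assert float(ph_from_H(1e-4)) == pytest.approx(7.0)

    def test_nonpositive_H_rejected(self):
        with pytest.raises(ValueError):
            ph_from_H(np.array([1e-4, 0.0]))


class TestSteadySolve:
    def test_zero_current_zero_respiration_uniform(self, geometry, medium):
        cell = CellModel(respiration_flux=0.0)
        mesh = build_mesh(geometry, refinement_level=1, cells=(cell,))
        fx = galvanostatic_boundary_flux(0.0, geometry.disk_radius)
        field = solve_steady(mesh, medium, fx, (cell,))
        assert field.species["O2"] == pytest.approx(
            np.full(mesh.n_active, medium.c_O2_bulk), rel=1e-9)
        assert field.ph() == pytest.approx(
            np.full(mesh.n_active, medium.bulk_pH), abs=1e-9)

    def test_minimum_on_disk_and_bounded(self, steady_m7, mesh_l1, medium):
        o2 = steady_m7.species["O2"]
        # normalized concentration field in [0, 1]
        assert o2.min() >= 0.0
        assert o2.max() <= medium.c_O2_bulk * (1 + 1e-9)
        assert np.argmin(o2) in set(mesh_l1.disk_idx)

    def test_steady_flux_balance(self, mesh_l1, medium, flux_m7, steady_m7, cell):
        """Integrated consumption (disk + cell) equals the influx through
        the bulk boundary at steady state."""
        o2 = steady_m7.species["O2"]
        influx = float(np.sum(
            medium.D_O2 * mesh_l1.bulk_g_unit
            * (medium.c_O2_bulk - o2[mesh_l1.bulk_idx])))
        consumption = (flux_m7.O2_flux_at_disk * mesh_l1.disk_area.sum()
                       + cell.respiration_flux * cell.cap_area)
        assert influx == pytest.approx(consumption, rel=5e-3)

    def test_depletion_linear_in_current(self, geometry, medium):
        """With respiration off the depletion field is proportional to |i|."""
        cell = CellModel(respiration_flux=0.0)
        mesh = build_mesh(geometry, refinement_level=2, cells=(cell,))
        deps = []
        currents = [-1e-9, -3e-9, -5e-9, -7e-9]
        for i in currents:
            fx = galvanostatic_boundary_flux(i, geometry.disk_radius)
            f = solve_steady(mesh, medium, fx, (cell,))
            deps.append(medium.c_O2_bulk - f.species["O2"])
        ref = deps[3] / 7.0  # per-nA depletion shape
        for dep, i in zip(deps, currents):
            assert dep == pytest.approx(ref * abs(i) * 1e9, rel=1e-6, abs=1e-12)
        # near the transport limit the disk saturates: O2 stays
        # non-negative and, because the full current is still delivered,
        # the volume-integrated depletion stays on the linear trend
        fx9 = galvanostatic_boundary_flux(-9e-9, geometry.disk_radius)
        f9 = solve_steady(mesh, medium, fx9, (cell,))
        assert f9.species["O2"].min() >= 0.0
        integrated = float(np.sum(mesh.volumes
                                  * (medium.c_O2_bulk - f9.species["O2"])))
        assert integrated == pytest.approx(
            9.0 * float(np.sum(mesh.volumes * ref)), rel=0.01)

    def test_exposure_ordered_by_current(self, geometry, medium, cell, mesh_l1):
        values = []
        for i in [-1e-9, -3e-9, -5e-9, -7e-9, -9e-9]:
            fx = galvanostatic_boundary_flux(i, geometry.disk_radius)
            f = solve_steady(mesh_l1, medium, fx, (cell,))
            values.append(average_cell_surface(f, cell))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_buffered_swing_much_smaller_than_weakly_buffered(
            self, mesh_l1, medium, cell, geometry):
        fx = galvanostatic_boundary_flux(-3e-9, geometry.disk_radius)
        weak = MediumProperties(
            D_O2=medium.D_O2, c_O2_bulk=medium.c_O2_bulk,
            buffer=BufferSystem(total_concentration=2.5))
        strong = solve_steady(mesh_l1, medium, fx, (cell,))
        weakly = solve_steady(mesh_l1, weak, fx, (cell,))
        d_strong = average_cell_surface(strong, cell, "pH") - medium.bulk_pH
        d_weak = average_cell_surface(weakly, cell, "pH") - weak.bulk_pH
        assert d_weak > 5 * d_strong

    def test_inadmissible_current_raises(self, geometry, cell):
        # default (uncalibrated) medium has |i_lim| ~ 8.4 nA
        medium = MediumProperties()
        mesh = build_mesh(geometry, refinement_level=1, cells=(cell,))
        fx = galvanostatic_boundary_flux(-12e-9, geometry.disk_radius)
        with pytest.raises(SolverError, match="diffusion_limited_current"):
            solve_steady(mesh, medium, fx, (cell,))


class TestSurfaceAveraging:
    def test_uniform_field_returns_value(self, mesh_l1, cell):
        field = Field(mesh=mesh_l1, species={
            "O2": np.full(mesh_l1.n_active, 0.17),
            "H": np.full(mesh_l1.n_active, 1e-4),
            "HA": np.zeros(mesh_l1.n_active),
            "A": np.zeros(mesh_l1.n_active),
        })
        assert average_cell_surface(field, cell) == pytest.approx(0.17)
        assert average_cell_surface(field, cell, "pH") == pytest.approx(7.0)

    def test_weights_sum_to_cap_area(self, mesh_l1, cell):
        assert mesh_l1.cell_band_area.sum() == pytest.approx(
            cell.cap_area, rel=1e-3)

    def test_no_cell_surface_raises(self, geometry, medium):
        mesh = build_mesh(geometry, refinement_level=1, cells=())
        field = Field(mesh=mesh, species={
            "O2": np.zeros(mesh.n_active), "H": np.ones(mesh.n_active),
            "HA": np.zeros(mesh.n_active), "A": np.zeros(mesh.n_active)})
        with pytest.raises(SolverError):
            average_cell_surface(field)


class TestTransient:
    def test_cell_o2_monotone_nonincreasing(self, transient_m7):
        assert (np.diff(transient_m7.o2_cell) <= 1e-12).all()

    def test_plateau_matches_steady(self, transient_m7, steady_m7, cell):
        plateau = transient_m7.o2_cell[-1]
        assert plateau == pytest.approx(
            average_cell_surface(steady_m7, cell), rel=1e-2)

    def test_maximum_principle_every_snapshot(
            self, mesh_l1, medium, flux_m7, cell):
        res = solve_transient(
            mesh_l1, medium, flux_m7, (cell,), t_end=30.0,
            output_times=[0.0, 1.0, 5.0, 15.0, 30.0], store_snapshots=True)
        for t, field in res.snapshots.items():
            o2 = field.species["O2"]
            assert o2.min() >= 0.0, f"negative O2 at t={t}"
            assert o2.max() <= medium.c_O2_bulk * (1 + 1e-9)

    def test_zero_current_flat_at_respiration_baseline(
            self, mesh_l1, medium, cell, geometry):
        fx = galvanostatic_boundary_flux(0.0, geometry.disk_radius)
        res = solve_transient(mesh_l1, medium, fx, (cell,), t_end=20.0,
                              output_times=[0.0, 10.0, 20.0])
        assert res.o2_cell == pytest.approx(
            np.full(3, res.o2_cell[0]), rel=1e-9)
        # respiration-only baseline sits just below bulk
        assert res.o2_cell[0] < medium.c_O2_bulk
        assert res.o2_cell[0] > 0.99 * medium.c_O2_bulk

    def test_splitting_dt_consistency(self, mesh_l1, medium, flux_m7, cell):
        """Halving the maximum step changes the pH trace by < 1e-3 units."""
        kw = dict(t_end=60.0, output_times=[30.0, 60.0])
        r1 = solve_transient(mesh_l1, medium, flux_m7, (cell,),
                             dt_max=2.0, **kw)
        r2 = solve_transient(mesh_l1, medium, flux_m7, (cell,),
                             dt_max=1.0, **kw)
        assert np.abs(r1.ph_cell - r2.ph_cell).max() < 1e-3

    def test_mass_conserved_in_closed_domain(self, mesh_l1, medium):
        """Backward-Euler diffusion with all boundaries closed conserves
        total moles to 1e-6 relative over 1000 steps."""
        D = medium.D_O2
        dt = 0.05
        rng = np.random.default_rng(7)
        c = rng.uniform(0.1, 0.3, mesh_l1.n_active)
        total0 = float(np.sum(mesh_l1.volumes * c))
        M = (sp.diags(mesh_l1.volumes / dt) + D * mesh_l1.laplacian_unit).tocsc()
        lu = spla.splu(M)
        for _ in range(1000):
            c = lu.solve(mesh_l1.volumes / dt * c)
        assert np.sum(mesh_l1.volumes * c) == pytest.approx(total0, rel=1e-6)


class TestTimeToSteady:
    def test_exponential_closed_form(self):
        """A single-compartment step response with rate k settles within
        5% of its change at t = ln(20)/k ~ 3/k."""
        k = 0.2
        t = np.linspace(0.0, 60.0, 1201)
        trace = 1.0 - np.exp(-k * t)
        res = TransientResult(times=t, o2_cell=trace,
                              ph_cell=np.zeros_like(t),
                              o2_substrate=trace)
        assert time_to_steady_state(res, 0.05) == pytest.approx(3.0 / k, rel=0.02)

    def test_already_steady_trace(self):
        t = np.linspace(0, 10, 11)
        res = TransientResult(times=t, o2_cell=np.ones(11),
                              ph_cell=np.zeros(11), o2_substrate=np.ones(11))
        assert time_to_steady_state(res) == 0.0

    def test_unfinished_trace_raises(self):
        t = np.linspace(0, 5, 6)
        res = TransientResult(times=t, o2_cell=np.exp(-0.01 * t),
                              ph_cell=np.zeros(6), o2_substrate=t)
        with pytest.raises(SolverError, match="plateau"):
            time_to_steady_state(res)
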