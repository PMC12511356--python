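"""u-p solver: assembly consistency, step behaviour, conservation."""

import numpy as np
import pytest

from cartmech.cohort import LoadingHistory
from cartmech.material import FRPEParameters, LINEAR_TEST_SET
from cartmech.mesh import SurfaceField, build_box_mesh
from cartmech.solver import (
    BoundarySpec,
    NumericsConfig,
    PoroelasticSolver,
    SolverError,
    assemble_system,
    run_stance_simulation,
)


@pytest.fixture(scope="module")
def two_elem_mesh():
    return build_box_mesh(1.0, 1.0, 2.0, 1, 1, 2)


@pytest.fixture(scope="module")
def params():
    return FRPEParameters()


def _uniform_frame(mesh, p):
    fids = mesh.articular_faces()
    return SurfaceField(fids, np.full(len(fids), float(p)))


class TestAssembly:
    def test_zero_state_zero_load_zero_residual(self, two_elem_mesh, params):
        n = two_elem_mesh.n_nodes
        r, _ = assemble_system(
            two_elem_mesh, params, np.zeros((n, 3)), np.zeros(n), None, dt=0.1
        )
        assert np.allclose(r, 0.0, atol=1e-14)

    @pytest.mark.parametrize("tangent", ["analytic", "fd"])
    def test_jacobian_matches_finite_difference_of_residual(self, two_elem_mesh, params, tangent, rng):
        """Assembled Jacobian vs brute-force differentiation of the residual
        on a 2-element mesh."""
        num = NumericsConfig(tangent=tangent)
        solver = PoroelasticSolver(two_elem_mesh, params, BoundarySpec(), num)
        n = two_elem_mesh.n_nodes
        u = 0.01 * rng.standard_normal((n, 3))
        p = 0.05 * rng.standard_normal(n)
        Jn = np.ones((two_elem_mesh.n_elements, 8))
        frame = _uniform_frame(two_elem_mesh, 0.2)
        dt = 0.05
        J = solver.jacobian(u, p, Jn, dt, frame).toarray()
        h = 1e-7
        r0, _ = solver.residual(u, p, Jn, dt, frame)
        J_fd = np.zeros_like(J)
        for d in range(4 * n):
            du = np.zeros(4 * n)
            du[d] = h
            up = u + du[: 3 * n].reshape(-1, 3)
            pp = p + du[3 * n :]
            um = u - du[: 3 * n].reshape(-1, 3)
            pm = p - du[3 * n :]
            rp, _ = solver.residual(up, pp, Jn, dt, frame)
            rm, _ = solver.residual(um, pm, Jn, dt, frame)
            J_fd[:, d] = (rp - rm) / (2 * h)
        scale = np.abs(J_fd).max()
        assert np.abs(J - J_fd).max() / scale < 1e-5

    def test_equal_and_opposite_pressures_balance(self, params):
        """Pressure applied to the top and bottom of a sealed free-floating
        block produces zero net force (Newton's third law of assembly)."""
        mesh = build_box_mesh(1.0, 1.0, 1.0, 2, 2, 1)
        bc = BoundarySpec(fixed_surface_sets=(), drainage={s: "sealed" for s in mesh.surface_sets})
        solver = PoroelasticSolver(mesh, params, bc)
        fids = np.concatenate([mesh.surface_sets["articular"], mesh.surface_sets["bone"]])
        frame = SurfaceField(fids, np.full(len(fids), 1.0))
        n = mesh.n_nodes
        r, _ = solver.residual(np.zeros((n, 3)), np.zeros(n), np.ones((mesh.n_elements, 8)), 0.1, frame)
        net = r[: 3 * n].reshape(-1, 3).sum(axis=0)
        assert np.allclose(net, 0.0, atol=1e-10)

    def test_dt_must_be_positive(self, two_elem_mesh, params):
        n = two_elem_mesh.n_nodes
        with pytest.raises(ValueError):
            assemble_system(two_elem_mesh, params, np.zeros((n, 3)), np.zeros(n), None, dt=0.0)


class TestSolveStep:
    def test_zero_load_from_rest_immediate(self, two_elem_mesh, params):
        solver = PoroelasticSolver(two_elem_mesh, params)
        n = two_elem_mesh.n_nodes
        u, p, diag = solver.solve_step(
            np.zeros((n, 3)), np.zeros(n), np.ones((two_elem_mesh.n_elements, 8)),
            _uniform_frame(two_elem_mesh, 0.0), dt=0.1,
        )
        assert diag["iterations"] == 0
        assert np.allclose(u, 0) and np.allclose(p, 0)

    def test_small_load_linear_regime_fast_convergence(self, two_elem_mesh):
        solver = PoroelasticSolver(
            two_elem_mesh, LINEAR_TEST_SET, numerics=NumericsConfig(small_strain=True)
        )
        n = two_elem_mesh.n_nodes
        u, p, diag = solver.solve_step(
            np.zeros((n, 3)), np.zeros(n), np.ones((two_elem_mesh.n_elements, 8)),
            _uniform_frame(two_elem_mesh, 1e-4), dt=1.0,
        )
        assert diag["iterations"] <= 2
        assert u[:, 2].min() < 0  # compression happened

    def test_inadmissible_load_structured_error(self, two_elem_mesh, params):
        solver = PoroelasticSolver(two_elem_mesh, params, numerics=NumericsConfig(max_cuts=2))
        n = two_elem_mesh.n_nodes
        with pytest.raises(SolverError):
            solver.advance(
                np.zeros((n, 3)), np.zeros(n), np.ones((two_elem_mesh.n_elements, 8)),
                None, _uniform_frame(two_elem_mesh, 500.0), dt=1e3,
            )


class TestStanceSimulation:
    def test_all_zero_loading_stays_at_rest(self, two_elem_mesh, params):
        times = np.linspace(0, 0.5, 6)
        fids = two_elem_mesh.articular_faces()
        frames = [SurfaceField(fids, np.zeros(len(fids)), t) for t in times]
        loading = LoadingHistory(times, frames, np.zeros(6))
        fh = run_stance_simulation(two_elem_mesh, params, loading)
        assert np.allclose(fh.displacements, 0) and np.allclose(fh.pore_pressures, 0)
        assert np.allclose(fh.F_centroid, np.eye(3))

    def test_deterministic_repeat(self, params):
        mesh = build_box_mesh(2.0, 2.0, 1.0, 2, 2, 2)
        times = np.linspace(0, 0.3, 6)
        fids = mesh.articular_faces()
        frames = [
            SurfaceField(fids, np.full(len(fids), 0.5 * np.sin(np.pi * t / 0.3)), t)
            for t in times
        ]
        loading = LoadingHistory(times, frames, np.array([f.values.sum() for f in frames]))
        a = run_stance_simulation(mesh, params, loading)
        b = run_stance_simulation(mesh, params, loading)
        assert np.array_equal(a.displacements, b.displacements)
        assert np.array_equal(a.pore_pressures, b.pore_pressures)
        assert np.array_equal(a.F_centroid, b.F_centroid)
        assert a.provenance["config_hash"] == b.provenance["config_hash"]

    def test_sealed_boundaries_conserve_fluid_volume(self, params):
        """With every boundary sealed the mixture volume cannot change."""
        from cartmech.mesh import element_volumes

        mesh = build_box_mesh(2.0, 2.0, 1.0, 2, 2, 2)
        bc = BoundarySpec(drainage={s: "sealed" for s in mesh.surface_sets})
        times = np.linspace(0, 0.3, 6)
        fids = mesh.articular_faces()
        frames = [
            SurfaceField(fids, np.full(len(fids), 0.4 * t / 0.3), t) for t in times
        ]
        loading = LoadingHistory(times, frames, np.array([f.values.sum() for f in frames]))
        fh = run_stance_simulation(mesh, params, loading, bc)
        v0 = element_volumes(mesh).sum()
        coords = mesh.nodes + fh.displacements[-1]
        v1 = element_volumes(mesh, coords).sum()
        assert abs(v1 - v0) / v0 < 1e-4

    def test_field_history_hdf5_round_trip_and_vtk_export(self, two_elem_mesh, params, tmp_path):
        from cartmech.solver import export_frame_vtk, load_field_history, save_field_history

        times = np.linspace(0, 0.2, 4)
        fids = two_elem_mesh.articular_faces()
        frames = [SurfaceField(fids, np.full(len(fids), 0.1 * t / 0.2), t) for t in times]
        loading = LoadingHistory(times, frames, np.array([f.values.sum() for f in frames]))
        fh = run_stance_simulation(two_elem_mesh, params, loading)
        save_field_history(fh, tmp_path / "f.h5")
        back = load_field_history(tmp_path / "f.h5")
        assert np.array_equal(back.displacements, fh.displacements)
        assert np.array_equal(back.F_centroid, fh.F_centroid)
        export_frame_vtk(two_elem_mesh, fh, 3, tmp_path / "frame3.vtk")
        text = (tmp_path / "frame3.vtk").read_text()
        assert "POINT_DATA" in text and "pore_pressure" in text

    def test_histogram_convergence_utility_runs(self):
        from cartmech.benchmarks import histogram_convergence
        from cartmech.material import LINEAR_TEST_SET

        def loading_for(mesh):
            times = np.linspace(0, 0.2, 4)
            fids = mesh.articular_faces()
            frames = [SurfaceField(fids, np.full(len(fids), 0.02 * t / 0.2), t) for t in times]
            return LoadingHistory(times, frames, np.array([f.values.sum() for f in frames]))

        bc = BoundarySpec(drainage={"articular": "free_draining", "rim": "sealed", "bone": "sealed"})
        out = histogram_convergence(
            build_box_mesh(1, 1, 1, 1, 1, 2),
            build_box_mesh(1, 1, 1, 1, 1, 4),
            LINEAR_TEST_SET,
            loading_for,
            bc=bc,
            numerics=NumericsConfig(small_strain=True),
        )
        assert out["l1_diff_pct"] >= 0.0
        assert len(out["histograms"]) == 2

    def test_diagnostics_complete(self, two_elem_mesh, params):
        times = np.linspace(0, 0.2, 4)
        fids = two_elem_mesh.articular_faces()
        frames = [SurfaceField(fids, np.full(len(fids), 0.2 * t / 0.2), t) for t in times]
        loading = LoadingHistory(times, frames, np.array([f.values.sum() for f in frames]))
        fh = run_stance_simulation(two_elem_mesh, params, loading)
        assert len(fh.diagnostics) == 4
        assert all("iterations" in d for d in fh.diagnostics)
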