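import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberextract.postprocess import mixing_cup
from fiberextract.solver import (
    MeshConvergenceError,
    Resolution,
    SingularSystemError,
    SolverError,
    assemble,
    axial_face_areas,
    build_mesh,
    graded_faces,
    refine_until_converged,
    solve_steady,
)
from fiberextract.transport_model import (
    BoundaryCondition,
    DomainLayer,
    TransportProblem,
)
from fiberextract.verification import annulus_conduction_problem, annulus_exact


def uniform_flow_layer(D=1e-9, v=1e-3, C0=1.0, R=5e-4, wall="insulation"):
    from fiberextract.geometry_hydro import tube_velocity

    return DomainLayer(
        name="tube",
        r_lo=0.0,
        r_hi=R,
        diffusivity=D,
        velocity=lambda r: tube_velocity(r, v, R),
        bc_z0=BoundaryCondition("dirichlet", C0),
        bc_zL=BoundaryCondition("outflow"),
        bc_r_lo=BoundaryCondition("symmetry"),
        bc_r_hi=BoundaryCondition(wall, 0.0),
        grading="hi",
    )


class TestGradedFaces:
    def test_uniform(self):
        f = graded_faces(0.0, 1.0, 10, "none", 1.3)
        np.testing.assert_allclose(np.diff(f), 0.1)

    def test_endpoints_exact(self):
        f = graded_faces(0.2, 0.9, 17, "both", 1.2)
        assert f[0] == 0.2 and f[-1] == 0.9
        assert len(f) == 18

    def test_fine_toward_hi(self):
        f = graded_faces(0.0, 1.0, 20, "hi", 1.2)
        h = np.diff(f)
        assert np.all(np.diff(h) < 0.0)  # strictly shrinking toward b

    def test_fine_toward_lo(self):
        h = np.diff(graded_faces(0.0, 1.0, 20, "lo", 1.2))
        assert np.all(np.diff(h) > 0.0)

    @given(
        n=st.integers(min_value=1, max_value=60),
        ratio=st.floats(min_value=1.0, max_value=1.5),
        side=st.sampled_from(["none", "lo", "hi", "both"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, n, ratio, side):
        f = graded_faces(1.0, 3.0, n, side, ratio)
        assert len(f) == n + 1
        assert np.all(np.diff(f) > 0.0)
        assert f[0] == pytest.approx(1.0) and f[-1] == pytest.approx(3.0)


class TestBuildMesh:
    def test_domains_tile_without_overlap(self, ip_tube_case):
        mesh = build_mesh(ip_tube_case.problem, Resolution((8, 4, 8), 10))
        geom = ip_tube_case.problem.geometry
        assert mesh.domains[0].r_faces[0] == 0.0
        assert mesh.domains[0].r_faces[-1] == pytest.approx(geom.r1)
        assert mesh.domains[1].r_faces[0] == pytest.approx(geom.r1)
        assert mesh.domains[1].r_faces[-1] == pytest.approx(geom.r2)
        assert mesh.domains[2].r_faces[-1] == pytest.approx(geom.r3)

    def test_refinement_bookkeeping(self, ip_tube_case):
        r = Resolution((8, 4, 8), 10)
        m1 = build_mesh(ip_tube_case.problem, r)
        m2 = build_mesh(ip_tube_case.problem, r.refined(2))
        assert m2.total_cells == 4 * m1.total_cells  # 2-D: doubling counts x4 cells

    def test_cell_areas_sum_to_domain_area(self, ip_tube_case):
        # quadrature oracle: sum of axial face areas = (r_hi^2 - r_lo^2)/2 per radian
        mesh = build_mesh(ip_tube_case.problem, Resolution((9, 5, 13), 7))
        for dmesh in mesh.domains:
            expect = 0.5 * (dmesh.r_faces[-1] ** 2 - dmesh.r_faces[0] ** 2)
            assert axial_face_areas(dmesh).sum() == pytest.approx(expect, rel=1e-13)

    def test_grading_refines_toward_interfaces(self, ip_tube_case):
        mesh = build_mesh(ip_tube_case.problem, Resolution((16, 8, 16), 8))
        h_tube = np.diff(mesh.domains[0].r_faces)
        h_shell = np.diff(mesh.domains[2].r_faces)
        assert h_tube[-1] < h_tube[0]  # fine against r1
        assert h_shell[0] < h_shell[-1]  # fine against r2

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            Resolution(nr=(2,), nz=10)

    def test_layer_count_mismatch(self, ip_tube_case):
        with pytest.raises(ValueError, match="radial counts"):
            build_mesh(ip_tube_case.problem, Resolution((8, 8), 10))


class TestAssembleExactness:
    def test_constant_field_is_exact_for_pure_diffusion(self):
        # equal fixed concentrations everywhere -> constant solution
        layer = DomainLayer(
            name="annulus",
            r_lo=1e-4,
            r_hi=2e-4,
            diffusivity=1e-10,
            bc_r_lo=BoundaryCondition("dirichlet", 0.7),
            bc_r_hi=BoundaryCondition("dirichlet", 0.7),
        )
        problem = TransportProblem(layers=(layer,), L=1e-3)
        fld = solve_steady(problem, resolution=Resolution((12,), 6))
        np.testing.assert_allclose(fld.values["annulus"], 0.7, rtol=1e-12)

    def test_annular_conduction_matches_log_profile(self):
        problem = annulus_conduction_problem()
        fld = solve_steady(problem, resolution=Resolution((48,), 4))
        dmesh = fld.mesh.domains[0]
        layer = problem.layers[0]
        exact = annulus_exact(dmesh.r_centers, layer.r_lo, layer.r_hi, 1.0, 0.2)
        num = fld.values["annulus"].mean(axis=1)
        assert np.max(np.abs(num - exact) / np.abs(exact)) < 1e-3

    def test_pure_convection_transports_inlet_unchanged(self):
        # D = 0: nothing crosses streamlines; constant inlet propagates exactly
        problem = TransportProblem(
            layers=(uniform_flow_layer(D=0.0, C0=0.35),), L=0.1, feed_index=0
        )
        fld = solve_steady(problem, resolution=Resolution((16,), 20))
        np.testing.assert_allclose(fld.values["tube"], 0.35, rtol=1e-12)
        assert mixing_cup(fld, problem, "feed") == pytest.approx(0.35, rel=1e-12)

    def test_convection_operator_conserves_constants(self):
        # row sums of interior rows vanish when applied to a constant field
        problem = TransportProblem(
            layers=(uniform_flow_layer(D=0.0, C0=1.0),), L=0.1, feed_index=0
        )
        mesh = build_mesh(problem, Resolution((8,), 12))
        system = assemble(problem, mesh)
        r = system.A @ np.ones(system.A.shape[0]) - system.b
        interior = r.reshape(8, 12)[:, 1:-1]
        assert np.max(np.abs(interior)) < 1e-20


class TestSingularSystems:
    def test_stagnant_zero_diffusivity_raises(self):
        layer = DomainLayer(name="dead", r_lo=1e-4, r_hi=2e-4, diffusivity=0.0)
        problem = TransportProblem(layers=(layer,), L=1e-3)
        with pytest.raises(SingularSystemError):
            solve_steady(problem, resolution=Resolution((4,), 4))

    def test_all_neumann_diffusion_raises(self):
        layer = DomainLayer(
            name="float",
            r_lo=1e-4,
            r_hi=2e-4,
            diffusivity=1e-10,
            bc_r_lo=BoundaryCondition("insulation"),
            bc_r_hi=BoundaryCondition("insulation"),
        )
        problem = TransportProblem(layers=(layer,), L=1e-3)
        with pytest.raises(SolverError):
            solve_steady(problem, resolution=Resolution((4,), 4))


class TestSolveSteady:
    def test_residual_contract(self, ip_tube_field):
        assert ip_tube_field.diagnostics.final_residual <= 1e-10
        assert len(ip_tube_field.diagnostics.residual_norms) >= 1

    def test_discrete_maximum_principle(self, ip_tube_case, ip_tube_field):
        # aqueous side within [0, C0]; organic side within [0, m*C0]
        solute = ip_tube_case.problem.solute
        tol = 1e-9 * solute.C0
        tube = ip_tube_field.values["tube"]
        assert tube.min() >= -tol and tube.max() <= solute.C0 + tol
        for name in ("membrane", "shell"):
            v = ip_tube_field.values[name]
            assert v.min() >= -tol and v.max() <= solute.m * solute.C0 + tol

    def test_solute_ordering_at_base_conditions(self, coarse_res):
        # stronger organic affinity removes more solute
        from fiberextract.scenarios import table1_case

        outs = {}
        for name in ("IP", "4-IBAP"):
            case = table1_case(name)
            fld = solve_steady(case.problem, resolution=coarse_res)
            outs[name] = mixing_cup(fld, case.problem, "feed")
        assert outs["4-IBAP"] < outs["IP"]


class TestRefinement:
    def test_constant_problem_converges_immediately(self):
        problem = TransportProblem(
            layers=(uniform_flow_layer(D=1e-9, C0=1.0),), L=0.1, feed_index=0
        )
        fld, report = refine_until_converged(
            problem, tolerance=1e-6, base_resolution=Resolution((8,), 8)
        )
        assert report.converged
        assert len(report.cell_counts) == 2  # first comparison suffices
        assert report.relative_changes[0] < 1e-6

    def test_base_case_outlet_cauchy_sequence(self, ip_tube_case):
        _, report = refine_until_converged(
            ip_tube_case.problem,
            tolerance=1e-3,
            base_resolution=Resolution((12, 6, 12), 48),
        )
        assert report.converged
        assert all(b > a for a, b in zip(report.cell_counts, report.cell_counts[1:]))

    def test_nonconvergence_raises_with_report(self, ip_tube_case):
        with pytest.raises(MeshConvergenceError) as err:
            refine_until_converged(
                ip_tube_case.problem,
                tolerance=1e-16,
                max_levels=2,
                base_resolution=Resolution((6, 3, 6), 12),
            )
        assert len(err.value.report.cell_counts) == 2
        assert not err.value.report.converged

    def test_observed_order_of_accuracy_at_least_one(self):
        # three-level Richardson estimate on the wall-sink benchmark
        from fiberextract.verification import tube_wall_sink_problem

        problem = tube_wall_sink_problem()
        outs = []
        for nz in (100, 200, 400):
            fld = solve_steady(problem, resolution=Resolution((64,), nz, ratio=1.05))
            outs.append(mixing_cup(fld, problem, "feed"))
        d1, d2 = outs[1] - outs[0], outs[2] - outs[1]
        order = np.log2(abs(d1 / d2))
        assert 0.7 < order < 2.5
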