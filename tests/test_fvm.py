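"""Axisymmetric finite-volume solver: meshing, oracles, conservation."""

import numpy as np
import pytest

from nozzleflow import (
    ConvergenceError,
    DriveCondition,
    Material,
    MeshError,
    NozzleGeometry,
    builtin_material,
)
from nozzleflow import fvm, pipe


@pytest.fixture(scope="module")
def alg():
    return builtin_material("Alginate")


class TestMesh:
    def test_uniform_tube_radial_count(self, tube_geom):
        R = tube_geom.r_small
        mesh = fvm.build_mesh(
            tube_geom,
            options=fvm.MeshOptions(uniform=True, dr_fine=R / 50,
                                    dz_fine=tube_geom.l_lower / 100),
        )
        assert mesh.Nr == 50
        assert np.all(mesh.kw == 50)

    def test_blunted_single_contraction_step(self, alg):
        geom = NozzleGeometry.from_mm("blunted", 0.1, 1.0, 2.0, 1.0)
        mesh = fvm.build_mesh(geom, dr=1e-5, dz=2e-5)
        steps = np.flatnonzero(np.diff(mesh.kw) != 0)
        assert len(steps) == 1
        z_step = mesh.z_edges[steps[0] + 1]
        assert z_step == pytest.approx(geom.l_upper, abs=2 * mesh.dz.max())

    def test_conical_monotone_staircase(self, base_conical):
        mesh = fvm.build_mesh(base_conical)
        assert np.all(np.diff(mesh.kw) <= 0)
        # staircase tracks the true wall within one fine cell near the exit
        j = mesh.Nz - 1
        assert mesh.wall_radius(j) == pytest.approx(base_conical.r_small,
                                                    abs=5e-6)

    def test_coarse_dr_rejected(self, base_conical):
        with pytest.raises(MeshError):
            fvm.build_mesh(base_conical, dr=base_conical.r_small / 2)

    def test_exit_radius_at_least_minimum_cells(self, base_conical):
        mesh = fvm.build_mesh(base_conical)
        assert mesh.kw[-1] >= 6


class TestStraightTubeOracle:
    """FVM vs the closed-form power-law Poiseuille solution at dr=R/50.

    The drive pressures keep the generalized Reynolds number small so the
    fully developed closed form applies over nearly the whole tube.
    """

    @pytest.mark.parametrize(
        "n_idx, K, dp",
        [(0.127, 406.0, 5e3), (0.335, 55.7, 2e3), (0.608, 13.3, 1e3),
         (1.0, 1.0, 2e3)],
    )
    def test_flow_stress_profile_within_2pct(self, tube_geom, tube_spec,
                                             tube_mesh, n_idx, K, dp):
        mat = Material(f"n={n_idx}", 1000.0, K, n_idx)
        field = fvm.solve_fvm(tube_mesh, mat, DriveCondition.pressure(dp))
        s = fvm.summarize(field)
        q_ref = pipe.flow_rate(tube_spec,
                               pipe.mean_velocity(dp, tube_spec, mat))
        assert s.q == pytest.approx(q_ref, rel=0.02)
        assert s.mss == pytest.approx(pipe.wall_shear(dp, tube_spec),
                                      rel=0.02)
        j = tube_mesh.Nz // 2
        u = 0.5 * (field.w[:, j] + field.w[:, j + 1])
        u_ref = pipe.velocity_profile(tube_mesh.rc, dp, tube_spec, mat)
        assert np.max(np.abs(u - u_ref)) <= 0.02 * u_ref.max()

    def test_newtonian_hagen_poiseuille(self, tube_geom, tube_spec,
                                        tube_mesh):
        mu, dp = 1.0, 2e3
        mat = Material("newt", 1000.0, mu, 1.0)
        s = fvm.summarize(fvm.solve_fvm(tube_mesh, mat,
                                        DriveCondition.pressure(dp)))
        q_hp = np.pi * dp * tube_spec.R**4 / (8 * mu * tube_spec.L)
        assert s.q == pytest.approx(q_hp, rel=0.02)

    def test_mss_at_wall(self, tube_mesh, alg):
        s = fvm.summarize(fvm.solve_fvm(tube_mesh, alg,
                                        DriveCondition.pressure(2e3)))
        z, r = s.mss_location
        assert r == pytest.approx(tube_mesh.geom.r_small, rel=0.05)


class TestConservationAndSymmetry:
    def test_mass_conserved_across_sections(self, small_blunted_field):
        _, mesh, field = small_blunted_field
        q = fvm.cross_section_flux(field)
        assert np.all(np.abs(q / q[-1] - 1.0) < 0.005)

    def test_axis_symmetry(self, small_blunted_field):
        _, mesh, field = small_blunted_field
        assert np.all(field.v[0, :] == 0.0)
        # discrete dw/dr ~ 0 at the axis relative to the wall gradient
        j = mesh.Nz - 2
        dwdr_axis = abs(field.w[1, j] - field.w[0, j]) / (mesh.rc[1] - mesh.rc[0])
        dwdr_wall = field.w[mesh.kw[j] - 1, j] / (
            mesh.wall_radius(j) - mesh.rc[mesh.kw[j] - 1]
        )
        assert dwdr_axis < 0.05 * abs(dwdr_wall)

    def test_no_slip_wall_stress_positive(self, small_blunted_field):
        _, mesh, field = small_blunted_field
        s = fvm.summarize(field)
        assert np.all(s.tau_wall[:, 1] > 0)
        assert s.mss >= s.tau_wall[:, 1].max() - 1e-12

    def test_deterministic_reruns_bit_identical(self, tube_mesh, alg):
        f1 = fvm.solve_fvm(tube_mesh, alg, DriveCondition.pressure(2e3))
        f2 = fvm.solve_fvm(tube_mesh, alg, DriveCondition.pressure(2e3))
        assert np.array_equal(f1.w, f2.w)
        assert np.array_equal(f1.p, f2.p)

    def test_unit_rescaling_invariance(self, alg):
        """The same physical tube built from mm-converted inputs gives the
        same flow (inputs are converted, not reinterpreted)."""
        g1 = NozzleGeometry.blunted(2e-4, 2.0000002e-4, 1e-3, 1e-9)
        g2 = NozzleGeometry.from_mm("blunted", 0.2, 0.20000002, 1.0, 1e-6)
        opts = fvm.MeshOptions(uniform=True, dr_fine=2e-4 / 30,
                               dz_fine=1e-3 / 40)
        s1 = fvm.summarize(fvm.solve_fvm(fvm.build_mesh(g1, options=opts),
                                         alg, DriveCondition.pressure(2e3)))
        s2 = fvm.summarize(fvm.solve_fvm(fvm.build_mesh(g2, options=opts),
                                         alg, DriveCondition.pressure(2e3)))
        assert s1.q == pytest.approx(s2.q, rel=1e-9)


class TestFlowModeAndSummaries:
    def test_flow_mode_recovers_pressure(self, alg):
        """Pressure-driven then flow-driven at the resulting Q returns the
        applied pressure within a few percent (discretization-level)."""
        geom = NozzleGeometry.from_mm("blunted", 0.1, 1.0, 2.0, 1.0)
        mesh = fvm.build_mesh(geom, dr=1e-5, dz=2e-5)
        s1 = fvm.summarize(fvm.solve_fvm(mesh, alg,
                                         DriveCondition.pressure(100e3)))
        s2 = fvm.summarize(fvm.solve_fvm(mesh, alg,
                                         DriveCondition.flowrate(s1.q)))
        assert s2.delta_p == pytest.approx(100e3, rel=0.05)
        assert s2.q == pytest.approx(s1.q, rel=1e-9)

    def test_summarize_refuses_unconverged(self, small_blunted_field, alg):
        _, mesh, field = small_blunted_field
        import copy

        bad = copy.copy(field)
        bad.converged = False
        with pytest.raises(ConvergenceError):
            fvm.summarize(bad)

    def test_blunted_high_shear_spans_lower_tube(self, small_blunted_field):
        """For the blunted shape the wall stress is near-uniformly high
        along the whole lower tube (not just at the exit)."""
        geom, mesh, field = small_blunted_field
        s = fvm.summarize(field)
        lower = s.tau_wall[mesh.zc > geom.l_upper + 3e-4, 1]
        assert lower.min() > 0.6 * lower.max()

    def test_conical_mss_at_exit_region(self, alg):
        geom = NozzleGeometry.from_mm("conical", 0.1, 1.0, 2.0, 1.0,
                                      r_middle=0.5)
        mesh = fvm.build_mesh(geom, dr=1e-5, dz=2e-5)
        s = fvm.summarize(fvm.solve_fvm(mesh, alg,
                                        DriveCondition.pressure(150e3)))
        z_mss, _ = s.mss_location
        assert z_mss > geom.length - 0.25 * geom.l_lower

    def test_gamma_dot_floor_insensitivity(self, alg):
        """MSS changes by <1% when the regularization floor moves between
        1e-2 and 1e-4 s^-1."""
        geom = NozzleGeometry.from_mm("blunted", 0.1, 1.0, 2.0, 1.0)
        mesh = fvm.build_mesh(geom, dr=1e-5, dz=2e-5)
        vals = [
            fvm.summarize(fvm.solve_fvm(
                mesh, alg, DriveCondition.pressure(100e3),
                fvm.NumericsOptions(gamma_dot_min=g))).mss
            for g in (1e-2, 1e-4)
        ]
        assert abs(vals[0] / vals[1] - 1.0) < 0.01


class TestGridRefinement:
    def test_tube_error_decreases_monotonically(self, alg, tube_geom,
                                                tube_spec):
        dp = 2e3
        q_ref = pipe.flow_rate(tube_spec,
                               pipe.mean_velocity(dp, tube_spec, alg))
        R, L = tube_spec.R, tube_spec.L
        errs = []
        for frac in (10, 20, 40):
            mesh = fvm.build_mesh(
                tube_geom,
                options=fvm.MeshOptions(uniform=True, dr_fine=R / frac,
                                        dz_fine=L / 50),
            )
            s = fvm.summarize(fvm.solve_fvm(mesh, alg,
                                            DriveCondition.pressure(dp)))
            errs.append(abs(s.q / q_ref - 1.0))
        assert errs[0] > errs[1] > errs[2]

    def test_refinement_study_table(self, alg):
        geom = NozzleGeometry.from_mm("blunted", 0.1, 1.0, 2.0, 1.0)
        levels = [(2.5e-5, 5e-5), (1.6e-5, 3.2e-5), (1e-5, 2e-5)]
        df = fvm.grid_refinement_study(geom, alg,
                                       DriveCondition.pressure(100e3), levels)
        assert len(df) == 3
        assert df.converged.all()
        assert "q_richardson" in df.attrs
        # MSS near the step approaches its limit from below on refinement
        assert df.mss.iloc[0] <= df.mss.iloc[-1] * 1.05

    def test_requires_three_levels(self, alg, base_blunted):
        with pytest.raises(ValueError):
            fvm.grid_refinement_study(base_blunted, alg,
                                      DriveCondition.pressure(1e5),
                                      [(1e-5, 2e-5)])
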