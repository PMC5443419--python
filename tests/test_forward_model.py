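"""Diffusion forward model: physics identities and discretization checks."""

import numpy as np
import pytest

from ccodot.forward_model import (DiffusionSolver, Geometry, Grid,
                                  OpticalProperties, OptodeArray,
                                  boundary_profile, coarsen_grid,
                                  compute_jacobian, layered_slab,
                                  load_tissue_optics, project_jacobian,
                                  project_to_grid, reflection_parameter,
                                  solve_diffusion)


def homogeneous(shape, spacing, mua=0.01, musp=1.0):
    grid = Grid(shape, spacing)
    geometry = Geometry(grid, np.ones(grid.shape, int), {1: "medium"})
    return geometry, OpticalProperties.homogeneous(mua, musp)


@pytest.fixture(scope="module")
def cube20():
    """Homogeneous 20³ domain (2 mm spacing) with one channel on top."""
    geometry, props = homogeneous((20, 20, 20), 2.0)
    array = OptodeArray([[14.0, 20.0, 0.0]], [[26.0, 20.0, 0.0]], [(0, 0)])
    return geometry, props, array


class TestDiffusionSolve:
    def test_source_linearity(self):
        geometry, props = homogeneous((12, 12, 8), 2.0)
        solver = DiffusionSolver(geometry, props, 800.0)
        q = boundary_profile(geometry, (12.0, 12.0, 0.0), 2.0)
        assert np.allclose(solver.solve(2.0 * q), 2.0 * solver.solve(q),
                           rtol=1e-10)

    def test_fluence_positive(self):
        geometry, props = homogeneous((12, 12, 8), 2.0)
        phi = solve_diffusion(geometry, props, 800.0,
                              boundary_profile(geometry, (12.0, 12.0, 0.0), 2.0))
        assert np.all(phi > 0)

    def test_added_absorption_decreases_fluence(self):
        geometry, _ = homogeneous((12, 12, 8), 2.0)
        lo = OpticalProperties.homogeneous(0.01, 1.0)
        hi = OpticalProperties.homogeneous(0.02, 1.0)
        q = boundary_profile(geometry, (12.0, 12.0, 0.0), 2.0)
        phi_lo = solve_diffusion(geometry, lo, 800.0, q)
        phi_hi = solve_diffusion(geometry, hi, 800.0, q)
        assert np.all(phi_hi < phi_lo)

    def test_semi_infinite_greens_function_decay(self):
        # point source at the effective depth 1/musp'; the on-axis decay
        # must match the extrapolated-boundary CW Green's function
        mua, musp = 0.01, 2.0 / 3.0  # 1/musp = 1.5 mm lies on a voxel center
        geometry, props = homogeneous((50, 50, 30), 1.0, mua, musp)
        solver = DiffusionSolver(geometry, props, 800.0)
        grid = geometry.grid
        zc = grid.axis_centers(2)
        q = np.zeros(grid.shape)
        q[25, 25, np.argmin(np.abs(zc - 1.5))] = 1.0
        prof = solver.solve(q)[25, 25, :]

        kappa = 1.0 / (3.0 * (mua + musp))
        mueff = np.sqrt(mua / kappa)
        zb = 2.0 * reflection_parameter(1.4) * kappa
        z0 = 1.5
        r1 = np.maximum(np.abs(zc - z0), 1e-9)
        r2 = zc + z0 + 2.0 * zb
        analytic = (np.exp(-mueff * r1) / r1
                    - np.exp(-mueff * r2) / r2) / (4.0 * np.pi * kappa)
        iref = np.argmin(np.abs(zc - 4.5))
        ratio = (prof / prof[iref]) / (analytic / analytic[iref])
        sel = (zc >= 3.0) & (zc <= 20.0)
        assert np.abs(ratio[sel] - 1.0).max() < 0.10

    def test_neumann_boundary_gives_higher_fluence(self):
        # removing boundary loss (pure Neumann) keeps more light inside
        geometry, props = homogeneous((12, 12, 8), 2.0)
        q = boundary_profile(geometry, (12.0, 12.0, 0.0), 2.0)
        phi_r = solve_diffusion(geometry, props, 800.0, q, boundary="robin")
        phi_n = solve_diffusion(geometry, props, 800.0, q, boundary="neumann")
        assert np.all(phi_n > phi_r)

    def test_neumann_zero_absorption_singular(self):
        geometry, _ = homogeneous((8, 8, 6), 2.0)
        props = OpticalProperties.homogeneous(0.0, 1.0)
        with pytest.raises(np.linalg.LinAlgError):
            DiffusionSolver(geometry, props, 800.0, boundary="neumann")


class TestJacobian:
    def test_reciprocity_under_source_detector_swap(self, cube20):
        geometry, props, array = cube20
        fwd = compute_jacobian(geometry, props, array, 800.0)
        swapped = OptodeArray(array.detectors, array.sources, [(0, 0)])
        rev = compute_jacobian(geometry, props, swapped, 800.0)
        denom = np.abs(fwd.matrix).max()
        assert np.abs(fwd.matrix - rev.matrix).max() / denom < 1e-8

    def test_entries_nonnegative_homogeneous(self, cube20):
        geometry, props, array = cube20
        jac = compute_jacobian(geometry, props, array, 800.0)
        assert np.all(jac.matrix >= 0)

    def test_uniform_perturbation_matches_resolve(self, cube20):
        geometry, props, array = cube20
        jac = compute_jacobian(geometry, props, array, 800.0)
        qs = boundary_profile(geometry, array.sources[0], 2.0)
        qd = boundary_profile(geometry, array.detectors[0], 2.0)
        y0 = float(qd.ravel() @ DiffusionSolver(
            geometry, props, 800.0).solve(qs).ravel())
        dmu = 1e-4
        pert = DiffusionSolver(geometry, props, 800.0,
                               mua=np.full(geometry.shape, 0.01 + dmu))
        y1 = float(qd.ravel() @ pert.solve(qs).ravel())
        dA_nonlinear = np.log10(y0 / y1)
        dA_linear = jac.matrix.sum() * dmu
        assert dA_linear == pytest.approx(dA_nonlinear, rel=0.02)

    def test_random_sparse_perturbation_within_5pct(self, cube20):
        geometry, props, array = cube20
        jac = compute_jacobian(geometry, props, array, 800.0)
        qs = boundary_profile(geometry, array.sources[0], 2.0)
        qd = boundary_profile(geometry, array.detectors[0], 2.0)
        y0 = float(qd.ravel() @ DiffusionSolver(
            geometry, props, 800.0).solve(qs).ravel())
        rng = np.random.default_rng(0)
        pert = np.zeros(geometry.grid.n_voxels)
        idx = rng.choice(pert.size, 200, replace=False)
        pert[idx] = rng.uniform(0.0, 1e-3, idx.size)
        solver = DiffusionSolver(geometry, props, 800.0,
                                 mua=0.01 + pert.reshape(geometry.shape))
        y1 = float(qd.ravel() @ solver.solve(qs).ravel())
        dA_nonlinear = np.log10(y0 / y1)
        dA_linear = float((jac.matrix @ pert)[0])
        assert dA_linear == pytest.approx(dA_nonlinear, rel=0.05)

    def test_refinement_forms_cauchy_sequence(self):
        # modeled channel data on successively refined grids converge
        props = OpticalProperties.homogeneous(0.01, 1.0)
        ys = []
        for spacing in (4.0, 2.0, 1.0):
            n = int(round(40 / spacing))
            geometry = Geometry(Grid((n, n, int(round(24 / spacing))), spacing),
                                np.ones((n, n, int(round(24 / spacing))), int),
                                {1: "medium"})
            solver = DiffusionSolver(geometry, props, 800.0)
            qs = boundary_profile(geometry, (12.0, 20.0, 0.0), 2.0)
            qd = boundary_profile(geometry, (28.0, 20.0, 0.0), 2.0)
            ys.append(float(qd.ravel() @ solver.solve(qs).ravel()))
        d = np.abs(np.diff(ys))
        assert d[1] < d[0]


class TestGridProjection:
    def test_identity_grid(self):
        grid = Grid((6, 5, 4), 2.0)
        rng = np.random.default_rng(1)
        f = rng.standard_normal(grid.shape)
        assert np.allclose(project_to_grid(f, grid, grid), f, atol=1e-12)

    def test_constant_field_preserved(self):
        src = Grid((12, 12, 8), 2.0)
        dst = coarsen_grid(src, 3.0)
        out = project_to_grid(np.full(src.shape, 2.5), src, dst)
        covered = out != 0
        assert np.allclose(out[covered], 2.5, atol=1e-12)

    def test_mass_conserved_within_half_percent(self):
        src = Grid((12, 12, 8), 2.0)
        dst = coarsen_grid(src, 3.0)
        rng = np.random.default_rng(2)
        f = rng.uniform(0.5, 1.5, src.shape)
        out = project_to_grid(f, src, dst, conserve="integral")
        assert (out.sum() * src.voxel_volume
                == pytest.approx(f.sum() * src.voxel_volume, rel=5e-3))

    def test_down_up_recovers_smooth_field(self):
        fine = Grid((16, 16, 12), 1.0)
        coarse = coarsen_grid(fine, 2.0)
        x, y, z = np.meshgrid(*[fine.axis_centers(i) for i in range(3)],
                              indexing="ij")
        f = np.sin(x / 12.0) * np.cos(y / 15.0) + z / 24.0
        down = project_to_grid(f, fine, coarse)
        up = project_to_grid(down, coarse, fine)
        rms = np.sqrt(np.mean((up - f) ** 2)) / np.sqrt(np.mean(f ** 2))
        assert rms < 0.05

    def test_non_covering_target_rejected(self):
        src = Grid((10, 10, 10), 2.0)
        with pytest.raises(ValueError, match="cover"):
            project_to_grid(np.zeros(src.shape), src, Grid((4, 4, 4), 2.0))

    def test_jacobian_projection_preserves_action(self, cube20):
        # J_coarse @ dmu equals J_fine @ dmu for piecewise-constant dmu
        geometry, props, array = cube20
        jac = compute_jacobian(geometry, props, array, 800.0)
        dst = coarsen_grid(jac.grid, 4.0)
        jc = project_jacobian(jac, dst)
        rng = np.random.default_rng(3)
        dmu_c = rng.uniform(0.0, 1e-3, dst.shape)
        dmu_f = project_to_grid(dmu_c, dst, jac.grid)  # exact prolongation
        assert np.allclose(jc.matrix @ dmu_c.ravel(),
                           jac.matrix @ dmu_f.ravel(), rtol=1e-10)


class TestGeometryAndProps:
    def test_layered_slab_layers(self):
        geometry = layered_slab((60.0, 60.0, 40.0), 2.0)
        names = geometry.tissue_map()
        z = geometry.grid.axis_centers(2)
        assert set(np.unique(names)) == {"scalp_skull", "csf", "brain"}
        assert np.all(names[:, :, z < 12.0] == "scalp_skull")
        assert np.all(names[:, :, z > 14.0] == "brain")

    def test_packaged_optics_cover_band(self):
        props = load_tissue_optics()
        for tissue in ("scalp", "skull", "csf", "gm", "wm", "brain"):
            for wl in (740.0, 800.0, 900.0):
                assert props.mua(tissue, wl) >= 0
                assert props.musp(tissue, wl) > 0

    def test_boundary_profile_unit_power_and_truncation(self):
        geometry, _ = homogeneous((20, 20, 10), 2.0)
        q = boundary_profile(geometry, (20.0, 20.0, 0.0), 2.0)
        assert q.sum() == pytest.approx(1.0)
        assert np.all(q[:, :, 1:] == 0.0)  # confined to the top face
        centers = geometry.grid.centers().reshape(*geometry.shape, 3)
        r = np.linalg.norm(centers[:, :, 0, :2] - 20.0, axis=-1)
        assert np.all(q[:, :, 0][r > 6.0 + 1e-9] == 0.0)  # 3 sigma cut
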