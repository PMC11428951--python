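import numpy as np
import pytest

from xlct.forward import (
    DetectorModel,
    ProjectionSet,
    XRaySource,
    add_gaussian_noise,
    assemble_diffusion_system,
    boundary_projection,
    emission_source,
    solve_fluence,
    xray_intensity_field,
)
from xlct.geometry import OpticalProperties, Target, ValidationError, make_cylinder_phantom
from xlct.mesh import mesh_cylinder


class TestXRayIntensity:
    def test_zero_attenuation_gives_source_intensity(self, phantom):
        ph = make_cylinder_phantom(3.0, 2.3, OpticalProperties(0.02, 10.0), 0.0)
        pts = np.array([[0, 0, 0], [1.0, 0.5, 0.3], [-1.2, 0, -0.8]])
        X = xray_intensity_field(XRaySource(intensity=3.5), ph, pts)
        assert np.allclose(X, 3.5)

    def test_lambert_beer_closed_form(self):
        # ray along +x enters the cylinder at x=-R; 1 cm of path at x=-0.5
        ph = make_cylinder_phantom(3.0, 2.3, OpticalProperties(0.02, 10.0), 0.2)
        X = xray_intensity_field(XRaySource(), ph, np.array([[-0.5, 0, 0]]),
                                 view_angle_deg=0.0)
        assert X[0] == pytest.approx(np.exp(-0.2 * 1.0), rel=1e-9)

    def test_monotone_decay_along_ray(self, phantom):
        xs = np.linspace(-1.4, 1.4, 30)
        pts = np.column_stack([xs, np.zeros(30), np.zeros(30)])
        X = xray_intensity_field(XRaySource(), phantom, pts, view_angle_deg=0.0)
        assert np.all(np.diff(X) <= 1e-12)


class TestEmission:
    def test_pointwise_product_toy(self):
        S = emission_source(np.array([1.0, 0.5, 0.25]), np.array([10.0, 0.0, 4.0]),
                            gamma=2.0)
        assert np.allclose(S, [20.0, 0.0, 2.0])

    def test_zero_concentration_and_linearity(self):
        X = np.array([1.0, 2.0, 3.0])
        assert not emission_source(X, np.zeros(3)).any()
        n = np.array([1.0, 2.0, 0.5])
        assert np.allclose(emission_source(X, 2 * n), 2 * emission_source(X, n))

    def test_negative_concentration_raises(self):
        with pytest.raises(ValidationError):
            emission_source(np.ones(2), np.array([1.0, -0.1]))


class TestDiffusionSystem:
    def test_system_is_symmetric_positive_definite(self, phantom):
        mesh = mesh_cylinder(phantom, 0.45)
        system = assemble_diffusion_system(mesh, phantom.optical)
        A = system.A.toarray()
        assert np.abs(A - A.T).max() < 1e-12 * np.abs(A).max()
        eigmin = np.linalg.eigvalsh(A).min()
        assert eigmin > 0

    def test_zero_source_gives_zero_fluence(self, phantom, coarse_mesh):
        system = assemble_diffusion_system(coarse_mesh, phantom.optical)
        phi = solve_fluence(system, np.zeros(coarse_mesh.n_nodes))
        assert not phi.any()

    def test_solution_linearity(self, phantom, coarse_mesh):
        system = assemble_diffusion_system(coarse_mesh, phantom.optical)
        rng = np.random.default_rng(0)
        S = rng.uniform(0, 1, coarse_mesh.n_nodes)
        assert np.allclose(solve_fluence(system, 3.0 * S),
                           3.0 * solve_fluence(system, S), rtol=1e-9)

    def test_fluence_near_nonnegative_for_physical_source(self, coarse_forward):
        # P1 FEM has no discrete maximum principle; for a compact physical
        # source the undershoot stays a small fraction of the peak
        conc = coarse_forward.node_concentration(
            [Target((0, 0, 0), 4.0, 4.0, 50.0)])
        S = emission_source(coarse_forward.xray_at_nodes(0), conc)
        phi = solve_fluence(coarse_forward.system, S)
        assert phi.min() >= -2e-3 * phi.max()

    def test_reciprocity_of_symmetrized_system(self, phantom, coarse_mesh):
        system = assemble_diffusion_system(coarse_mesh, phantom.optical)
        i, j = 10, coarse_mesh.n_nodes - 5
        ei = np.zeros(coarse_mesh.n_nodes)
        ej = np.zeros(coarse_mesh.n_nodes)
        ei[i] = ej[j] = 1.0
        a = system.solve(ei)[j]
        b = system.solve(ej)[i]
        assert a == pytest.approx(b, rel=1e-8)


class TestBoundaryProjection:
    def test_view_periodicity(self, phantom, coarse_mesh, coarse_forward):
        conc = coarse_forward.node_concentration([Target((3, 2, 0), 4.0, 4.0, 50.0)])
        S = emission_source(coarse_forward.xray_at_nodes(0), conc)
        phi = solve_fluence(coarse_forward.system, S)
        det = coarse_forward.detector
        img0 = boundary_projection(phi, coarse_mesh, 0.0, det)
        img360 = boundary_projection(phi, coarse_mesh, 360.0, det)
        assert np.allclose(img0, img360)

    def test_centered_target_left_right_symmetry(self, coarse_forward):
        ps = coarse_forward.simulate_projections([Target((0, 0, 0), 4.0, 4.0, 50.0)])
        img = ps.images[0]
        assert np.linalg.norm(img - img[:, ::-1]) <= 0.02 * np.linalg.norm(img)

    def test_default_detector_is_24_views_of_128(self, phantom):
        det = DetectorModel.for_phantom(phantom)
        assert det.n_views == 24 and (det.n_u, det.n_v) == (128, 128)
        assert np.allclose(np.diff(det.angles_deg), 15.0)


class TestSimulateProjections:
    def test_no_targets_gives_zero_projections(self, coarse_forward):
        ps = coarse_forward.simulate_projections([])
        assert not ps.images.any()

    def test_linearity_in_concentration(self, coarse_forward):
        t1 = [Target((3, 0, 0), 4.0, 4.0, 50.0)]
        t2 = [Target((3, 0, 0), 4.0, 4.0, 100.0)]
        p1 = coarse_forward.simulate_projections(t1).images
        p2 = coarse_forward.simulate_projections(t2).images
        assert np.allclose(p2, 2 * p1, rtol=1e-10)

    def test_whole_chain_linearity_in_voxel_fields(self, coarse_forward):
        rng = np.random.default_rng(3)
        n_vox = coarse_forward.grid.n_voxels
        n1 = rng.uniform(0, 1, n_vox)
        n2 = rng.uniform(0, 1, n_vox)
        lhs = coarse_forward.forward_voxels(2.0 * n1 + 0.5 * n2).images
        rhs = (2.0 * coarse_forward.forward_voxels(n1).images
               + 0.5 * coarse_forward.forward_voxels(n2).images)
        assert np.allclose(lhs, rhs, rtol=1e-8, atol=1e-12)


class TestWeightMatrix:
    def test_matches_direct_forward_chain(self, coarse_forward, coarse_weight_matrix):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.uniform(0, 1, coarse_forward.grid.n_voxels)
            y_w = coarse_weight_matrix @ x
            y_direct = coarse_forward.forward_voxels(x).stacked()
            assert np.linalg.norm(y_w - y_direct) <= 1e-6 * np.linalg.norm(y_direct)

    def test_adjoint_equals_direct_assembly(self, coarse_forward, coarse_weight_matrix):
        W_direct = coarse_forward.build_weight_matrix_direct()
        scale = np.abs(W_direct).max()
        assert np.abs(coarse_weight_matrix - W_direct).max() <= 1e-6 * scale

    def test_entries_nonnegative_up_to_fem_undershoot(self, coarse_weight_matrix):
        # P1 FEM has no discrete maximum principle: allow a small relative
        # undershoot, mirroring the fluence tolerance
        W = coarse_weight_matrix
        assert W.max() > 0
        assert W.min() >= -5e-3 * W.max()
        assert np.isfinite(W).all()

    def test_column_outside_phantom_is_zero(self, coarse_forward, coarse_weight_matrix):
        # voxels beyond the trilinear support of any mesh node cannot emit
        grid = coarse_forward.grid
        centers = grid.voxel_centers_mm().reshape(-1, 3)
        margin = np.hypot(grid.dx_mm, grid.dy_mm)
        outside = np.hypot(centers[:, 0], centers[:, 1]) > \
            coarse_forward.phantom.radius_mm + margin
        assert outside.any()
        assert not coarse_weight_matrix[:, outside].any()


class TestGaussianNoise:
    def test_infinite_snr_is_identity(self):
        ps = ProjectionSet(np.random.default_rng(0).uniform(0, 1, (4, 8, 8)),
                           np.arange(4) * 90.0)
        out = add_gaussian_noise(ps, np.inf, 0)
        assert np.array_equal(out.images, ps.images)

    @pytest.mark.parametrize("snr_db", [30.0, 25.0, 20.0, 15.0])
    def test_realized_snr_matches_request(self, snr_db):
        rng = np.random.default_rng(1)
        ps = ProjectionSet(rng.uniform(0, 1, (24, 128, 128)), np.arange(24) * 15.0)
        noisy = add_gaussian_noise(ps, snr_db, 7)
        realized = 10 * np.log10(np.mean(ps.images**2)
                                 / np.mean((noisy.images - ps.images) ** 2))
        assert realized == pytest.approx(snr_db, abs=0.5)

    def test_seed_reproducibility(self):
        ps = ProjectionSet(np.ones((2, 4, 4)), np.array([0.0, 180.0]))
        a = add_gaussian_noise(ps, 20, 5)
        b = add_gaussian_noise(ps, 20, 5)
        assert np.array_equal(a.images, b.images)


class TestDetectorValidation:
    def test_angles_must_increase(self):
        with pytest.raises(ValidationError):
            DetectorModel(16, 16, 3.6, (0.0, 10.0, 5.0))

    def test_needs_at_least_one_view(self):
        with pytest.raises(ValidationError):
            DetectorModel(16, 16, 3.6, ())
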