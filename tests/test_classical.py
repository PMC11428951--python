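import numpy as np
import pytest
from scipy.optimize import nnls

from xlct.classical import (
    LinearInverseProblem,
    ReconSettings,
    adfista,
    admlem,
    grid_neighbors,
    gmrf_prior_energy,
    map_gmrf_icd,
    map_objective,
    poisson_loglik,
    soft_threshold,
    t_fista,
)
from xlct.geometry import ValidationError, VoxelGrid


@pytest.fixture()
def small_problem():
    rng = np.random.default_rng(42)
    W = rng.normal(size=(20, 10))
    x_true = np.abs(rng.normal(size=10))
    return LinearInverseProblem(W, W @ x_true), x_true


@pytest.fixture()
def grid_problem():
    """Well-posed problem on a tiny 3D grid (for MAP's neighborhood prior)."""
    rng = np.random.default_rng(3)
    grid = VoxelGrid(nx=4, ny=3, nz=2, dx_mm=1, dy_mm=1, dz_mm=1)
    W = rng.uniform(0, 1, size=(40, grid.n_voxels))
    x_true = np.abs(rng.normal(size=grid.n_voxels))
    return LinearInverseProblem(W, W @ x_true, grid), x_true


class TestSoftThreshold:
    @pytest.mark.parametrize("v,t,expected", [
        (0.5, 0.2, 0.3),
        (-0.1, 0.2, 0.0),
        (-0.7, 0.2, -0.5),
        (0.3, 0.0, 0.3),
    ])
    def test_examples(self, v, t, expected):
        assert soft_threshold(v, t) == pytest.approx(expected)

    def test_negative_threshold_raises(self):
        with pytest.raises(ValidationError):
            soft_threshold(1.0, -0.1)


class TestFista:
    def test_zero_data_with_sparsity_gives_zero(self, small_problem):
        prob, _ = small_problem
        zero = LinearInverseProblem(prob.W, np.zeros(prob.W.shape[0]))
        res = adfista(zero, ReconSettings(lam=0.5, step=0.01, max_iter=200, tol=1e-10))
        assert not res.x.any()

    def test_lambda_zero_matches_nnls(self, small_problem):
        prob, _ = small_problem
        res = adfista(prob, ReconSettings(lam=0.0, step=0.01,
                                          max_iter=5000, tol=1e-12))
        x_ref, _ = nnls(prob.W, prob.y)
        assert np.linalg.norm(res.x - x_ref) <= 1e-4 * max(np.linalg.norm(x_ref), 1)

    def test_net_descent(self, small_problem):
        prob, _ = small_problem
        res = adfista(prob)
        assert res.objective[-1] <= res.objective[0]

    def test_tfista_runs_exactly_300_iterations_by_default(self, small_problem):
        prob, _ = small_problem
        res = t_fista(prob)
        assert res.iterations == 300

    def test_tfista_equals_adfista_with_matched_settings(self, small_problem):
        prob, _ = small_problem
        s = ReconSettings(lam=0.1, step=0.01, max_iter=150, tol=0.0)
        a = adfista(prob, s)
        b = t_fista(prob, s)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.objective, b.objective)

    @pytest.mark.parametrize("seed", range(20))
    def test_objective_decreases_over_fixed_budget(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(15, 8))
        y = W @ np.abs(rng.normal(size=8))
        res = t_fista(LinearInverseProblem(W, y),
                      ReconSettings(lam=0.1, step=0.01, max_iter=300, tol=0.0))
        assert res.objective[300] <= res.objective[1]

    def test_float32_operator_stays_float32(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, (30, 12)).astype(np.float32)
        prob = LinearInverseProblem(W, (W @ np.ones(12)).astype(np.float32))
        res = t_fista(prob, ReconSettings(lam=0.01, step=0.01, max_iter=50, tol=0.0))
        assert res.x.dtype == np.float32


@pytest.fixture()
def mlem_toy():
    """Noiseless well-conditioned 30x30 system with positive truth."""
    rng = np.random.default_rng(7)
    n = 30
    W = 0.1 * rng.uniform(0, 1, size=(n, n)) + np.eye(n)
    x_true = rng.uniform(0.5, 2.0, size=n)
    return LinearInverseProblem(W, W @ x_true), x_true


class TestAdmlem:
    def test_noiseless_toy_converges_below_one_percent(self, mlem_toy):
        prob, x_true = mlem_toy
        res = admlem(prob, ReconSettings(max_iter=800))
        assert np.linalg.norm(res.x - x_true) <= 0.01 * np.linalg.norm(x_true)

    def test_poisson_likelihood_monotone(self, mlem_toy):
        prob, _ = mlem_toy
        res = admlem(prob, ReconSettings(max_iter=800))
        ll = res.objective
        assert np.all(np.diff(ll) >= -1e-9 * np.maximum(np.abs(ll[:-1]), 1.0))

    def test_iterates_stay_nonnegative(self, mlem_toy):
        prob, _ = mlem_toy
        res = admlem(prob, ReconSettings(max_iter=50))
        assert (res.x >= 0).all()

    def test_negative_measurements_clipped(self, mlem_toy, caplog):
        prob, _ = mlem_toy
        y = prob.y.copy()
        y[0] = -0.5
        res = admlem(LinearInverseProblem(prob.W, y), ReconSettings(max_iter=20))
        assert (res.x >= 0).all()

    def test_dead_columns_frozen_at_zero(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 1, (12, 6))
        W[:, 2] = 0.0
        y = W @ np.ones(6)
        res = admlem(LinearInverseProblem(W, y), ReconSettings(max_iter=100))
        assert res.x[2] == 0.0


class TestMapGmrfIcd:
    def test_vanishing_prior_reduces_to_nnls(self, grid_problem):
        prob, _ = grid_problem
        res = map_gmrf_icd(prob, ReconSettings(max_iter=3000, tol=0.0, sigma2=1.0,
                                               p2=1e12, estimate_hyperparams=False))
        x_ref, _ = nnls(prob.W, prob.y)
        assert np.linalg.norm(res.x.reshape(-1) - x_ref) \
            <= 1e-3 * max(np.linalg.norm(x_ref), 1)

    def test_sweeps_monotone_at_fixed_hyperparameters(self, grid_problem):
        prob, _ = grid_problem
        res = map_gmrf_icd(prob, ReconSettings(max_iter=40, tol=0.0, sigma2=0.5,
                                               p2=2.0, estimate_hyperparams=False))
        assert np.all(np.diff(res.objective) <= 1e-9 * np.abs(res.objective[:-1]) + 1e-12)

    def test_prior_energy_is_shift_invariant(self, grid_problem):
        prob, _ = grid_problem
        nb = grid_neighbors(prob.grid)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, prob.n_voxels)
        assert gmrf_prior_energy(x, nb) == pytest.approx(
            gmrf_prior_energy(x + 3.7, nb), rel=1e-9)

    def test_deterministic_rerun(self, grid_problem):
        prob, _ = grid_problem
        a = map_gmrf_icd(prob, ReconSettings(max_iter=10, tol=0.0))
        b = map_gmrf_icd(prob, ReconSettings(max_iter=10, tol=0.0))
        assert np.array_equal(a.x, b.x)

    def test_alternating_estimation_reports_finite_hyperparameters(self, grid_problem):
        prob, _ = grid_problem
        res = map_gmrf_icd(prob, ReconSettings(max_iter=20, tol=1e-8))
        assert np.isfinite(res.info["sigma2"]) and np.isfinite(res.info["p2"])


class TestGridNeighbors:
    def test_six_connectivity_and_symmetry(self):
        grid = VoxelGrid(nx=3, ny=3, nz=2, dx_mm=1, dy_mm=1, dz_mm=1)
        nb = grid_neighbors(grid)
        assert nb.shape == (18, 6)
        for j in range(nb.shape[0]):
            for k in nb[j]:
                if k >= 0:
                    assert j in nb[k]
        # interior voxel of the 3x3 face has 5 neighbours (one z face missing)
        assert (nb[4] >= 0).sum() == 5


class TestResultInvariants:
    def test_all_solvers_nonnegative_with_finite_traces(self, grid_problem):
        prob, _ = grid_problem
        rng = np.random.default_rng(11)
        noisy = LinearInverseProblem(
            prob.W, prob.y + 0.01 * rng.normal(size=prob.y.size), prob.grid)
        for solver, settings in [
            (adfista, ReconSettings(lam=0.05, step=0.01, max_iter=300, tol=1e-8)),
            (t_fista, None),
            (admlem, ReconSettings(max_iter=100)),
            (map_gmrf_icd, ReconSettings(max_iter=15, tol=1e-6)),
        ]:
            res = solver(noisy, settings)
            assert (res.x >= 0).all()
            assert np.isfinite(res.objective).all()


class TestSoftThresholdProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    @given(v=st.floats(-1e6, 1e6), t=st.floats(0, 1e6))
    @settings(derandomize=True, max_examples=200)
    def test_shrinkage_and_sign(v, t):
        out = soft_threshold(v, t)
        assert abs(out) <= abs(v) + 1e-12
        assert out * v >= 0
        if abs(v) > t:
            assert abs(out) == pytest.approx(abs(v) - t, abs=1e-9 * max(t, 1))
        else:
            assert out == 0.0
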