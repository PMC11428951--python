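"""Classical iterative reconstructors for y = W x, x >= 0.

Four solver families for the regularized inverse problem
``argmin_{x>=0} ||W x - y||_2^2 + lambda ||x||_beta``:

* ``adfista``  — FISTA with an L1 proximal step, nonnegativity projection and
  an adaptive stopping rule (relative iterate change).
* ``t_fista``  — the same iteration with a fixed budget (default lambda 0.1,
  300 iterations).
* ``admlem``   — multiplicative MLEM for Poisson-distributed projections
  (default 800 iterations).
* ``map_gmrf_icd`` — MAP estimation under a Gaussian Markov random-field
  prior, minimized by voxel-wise iterative coordinate descent with
  closed-form alternating re-estimation of the noise and prior variances.

All solvers are deterministic for a given problem and settings (fixed raster
sweep order) and return nonnegative volumes with finite objective traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numba
import numpy as np
import scipy.sparse as sp

from .geometry import ValidationError, VoxelGrid

logger = logging.getLogger(__name__)


@dataclass
class LinearInverseProblem:
    """Discretized measurement model: stacked y (view-major, row-major) = W x."""

    W: np.ndarray
    y: np.ndarray
    grid: VoxelGrid | None = None

    def __post_init__(self) -> None:
        # solvers work in W's dtype: a float32 operator stays float32 end to
        # end (large dense W must never be promoted per-iteration)
        self.y = np.asarray(self.y, dtype=self.W.dtype).reshape(-1)
        if self.W.shape[0] != self.y.size:
            raise ValidationError(
                f"W has {self.W.shape[0]} rows but y has {self.y.size} entries")

    @property
    def n_voxels(self) -> int:
        return self.W.shape[1]

    def volume(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(self.grid.shape) if self.grid is not None else x


@dataclass
class ReconSettings:
    """Solver parameters (see module docstring for per-algorithm defaults)."""

    lam: float = 0.1
    beta: int = 1
    step: float = 0.01
    max_iter: int = 2000
    tol: float = 1e-6
    seed: int | None = None
    # MAP/GMRF extras
    sigma2: float | None = None
    p2: float | None = None
    estimate_hyperparams: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0 or self.step <= 0 or self.max_iter < 1:
            raise ValidationError("invalid solver settings")


@dataclass
class ReconResult:
    x: np.ndarray
    objective: np.ndarray
    iterations: int
    converged: bool
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.x < 0):
            raise AssertionError("solver returned negative voxels")
        if not np.all(np.isfinite(self.objective)):
            raise AssertionError("non-finite objective trace")


def soft_threshold(v: np.ndarray | float, t: float) -> np.ndarray | float:
    """sign(v) * max(|v| - t, 0)."""
    if t < 0:
        raise ValidationError("threshold must be nonnegative")
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


# ----------------------------------------------------------------------------
# FISTA family
# ----------------------------------------------------------------------------

def _l1_objective(W, y, x, lam) -> float:
    r = W @ x - y
    return float(r @ r + lam * np.abs(x).sum())


def _fista(problem: LinearInverseProblem, lam: float, step: float,
           max_iter: int, tol: float) -> ReconResult:
    """FISTA with nonnegative soft-threshold prox and a divergence safeguard.

    The gradient step is fixed (the method's characteristic setting); if the
    objective blows past its best value the step is halved and momentum
    restarted, since stability at a fixed step depends on ||W||.
    """
    W, y = problem.W, problem.y
    n = problem.n_voxels
    x = np.zeros(n, dtype=W.dtype)
    x_prev2 = x
    t = 1.0
    Wx = W @ x
    Wx_prev = Wx
    beta = 0.0
    obj = [float((Wx - y) @ (Wx - y))]
    best_obj, best_x = obj[0], x.copy()
    converged = False
    halvings = 0
    it = 0
    for it in range(1, max_iter + 1):
        x_prev = x
        # z = x + beta (x - x_prev2), so W z combines the two cached products
        # and each iteration costs one forward and one adjoint matvec
        z = x + beta * (x - x_prev2) if it > 1 else x
        Wz = Wx + beta * (Wx - Wx_prev) if it > 1 else Wx
        grad = 2.0 * (W.T @ (Wz - y))
        x_new = np.maximum(z - step * grad - step * lam, 0.0)
        Wx_new = W @ x_new
        r = Wx_new - y
        o = float(r @ r + lam * np.abs(x_new).sum())
        if not np.isfinite(o) or o > 10.0 * max(best_obj, 1e-300):
            step *= 0.5
            halvings += 1
            logger.info("FISTA objective diverging; halving step to %.3e", step)
            x = best_x.copy()
            Wx = W @ x
            Wx_prev = Wx
            t = 1.0
            beta = 0.0
            obj.append(best_obj)
            continue
        # momentum factors stay Python floats: a numpy float64 scalar would
        # silently promote the (possibly float32) iterates and the operator
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        beta = (t - 1.0) / t_new
        dx = np.linalg.norm(x_new - x_prev) / max(np.linalg.norm(x_new), 1e-30)
        x_prev2 = x_prev
        x, t = x_new, t_new
        Wx_prev = Wx
        Wx = Wx_new
        obj.append(o)
        if o < best_obj:
            best_obj, best_x = o, x.copy()
        if dx < tol:
            converged = True
            break
    if obj[-1] > obj[0]:
        x = best_x  # guarantee net descent even on pathological problems
        obj.append(best_obj)
    return ReconResult(problem.volume(x), np.array(obj), it, converged,
                       {"step_halvings": halvings, "final_step": step})


def adfista(problem: LinearInverseProblem,
            settings: ReconSettings | None = None) -> ReconResult:
    """Adaptive-stop FISTA: gradient step 0.01, stops when the relative
    iterate change drops below ``tol`` (default 1e-6) or at 2000 iterations."""
    s = settings or ReconSettings(lam=0.1, step=0.01, max_iter=2000, tol=1e-6)
    return _fista(problem, s.lam, s.step, s.max_iter, s.tol)


def t_fista(problem: LinearInverseProblem,
            settings: ReconSettings | None = None) -> ReconResult:
    """Fixed-budget FISTA: lambda = 0.1, exactly 300 iterations by default."""
    s = settings or ReconSettings(lam=0.1, step=0.01, max_iter=300, tol=0.0)
    return _fista(problem, s.lam, s.step, s.max_iter, tol=0.0)


# ----------------------------------------------------------------------------
# MLEM (Poisson model)
# ----------------------------------------------------------------------------

def poisson_loglik(W, y, x, eps: float = 1e-12) -> float:
    """Poisson log-likelihood sum(y log(Wx) - Wx), constants dropped."""
    m = W @ x
    return float(y @ np.log(m + eps) - m.sum())


def admlem(problem: LinearInverseProblem,
           settings: ReconSettings | None = None) -> ReconResult:
    """Multiplicative MLEM: x <- x * (W^T (y / Wx)) / (W^T 1).

    Negative measurements (possible under additive Gaussian noise) are
    clipped to zero with a warning; W is clipped to its nonnegative part for
    the multiplicative update.  All-zero columns are frozen.
    """
    s = settings or ReconSettings(max_iter=800)
    W = np.maximum(problem.W, 0.0) if not sp.issparse(problem.W) \
        else problem.W.maximum(0)
    y = problem.y
    if np.any(y < 0):
        logger.warning("clipping %d negative measurements to 0 for MLEM",
                       int(np.sum(y < 0)))
        y = np.maximum(y, 0.0)
    colsum = np.asarray(W.sum(axis=0)).reshape(-1)
    dead = colsum <= 0
    if np.any(dead):
        logger.warning("%d all-zero columns excluded from MLEM update",
                       int(dead.sum()))
    denom = np.where(dead, 1.0, colsum).astype(W.dtype)
    x = np.ones(problem.n_voxels, dtype=W.dtype)
    x[dead] = 0.0
    trace = [poisson_loglik(W, y, x)]
    for _ in range(s.max_iter):
        m = W @ x
        ratio = np.divide(y, m, out=np.zeros_like(y), where=m > 0)
        x = x * (W.T @ ratio) / denom
        x[dead] = 0.0
        trace.append(poisson_loglik(W, y, x))
    return ReconResult(problem.volume(x), np.array(trace), s.max_iter, True)


# ----------------------------------------------------------------------------
# MAP with GMRF prior, ICD minimization
# ----------------------------------------------------------------------------

def grid_neighbors(grid: VoxelGrid) -> np.ndarray:
    """6-connected neighbor table, shape (n_voxels, 6), -1 where absent."""
    nz, ny, nx = grid.shape
    idx = np.arange(grid.n_voxels).reshape(nz, ny, nx)
    nb = -np.ones((nz, ny, nx, 6), dtype=np.int64)
    nb[1:, :, :, 0] = idx[:-1]
    nb[:-1, :, :, 1] = idx[1:]
    nb[:, 1:, :, 2] = idx[:, :-1]
    nb[:, :-1, :, 3] = idx[:, 1:]
    nb[:, :, 1:, 4] = idx[:, :, :-1]
    nb[:, :, :-1, 5] = idx[:, :, 1:]
    return nb.reshape(-1, 6)


def gmrf_prior_energy(x: np.ndarray, neighbors: np.ndarray,
                      b: float = 1.0 / 6.0) -> float:
    """(1/2) sum_{i~j} b (x_i - x_j)^2 over unordered neighbor pairs."""
    x = x.reshape(-1)
    e = 0.0
    for k in range(neighbors.shape[1]):
        nb = neighbors[:, k]
        ok = nb >= 0
        e += 0.5 * b * float(np.sum((x[ok] - x[nb[ok]]) ** 2))
    return 0.5 * e  # each unordered pair appears twice in the table


@numba.njit(cache=True)
def _icd_sweep(WT, colnorm2, r, x, neighbors, b, sigma2, p2):  # pragma: no cover
    n = x.size
    for j in range(n):
        nb_sum = 0.0
        nb_cnt = 0.0
        for k in range(neighbors.shape[1]):
            idx = neighbors[j, k]
            if idx >= 0:
                nb_sum += x[idx]
                nb_cnt += 1.0
        wj = WT[j]
        wr = 0.0
        for i in range(wj.size):
            wr += wj[i] * r[i]
        num = (wr + colnorm2[j] * x[j]) / sigma2 + b * nb_sum / p2
        den = colnorm2[j] / sigma2 + b * nb_cnt / p2
        if den <= 0.0:
            continue
        xn = num / den
        if xn < 0.0:
            xn = 0.0
        d = x[j] - xn
        if d != 0.0:
            for i in range(wj.size):
                r[i] += wj[i] * d
            x[j] = xn
    return x


def map_objective(W, y, x, neighbors, b, sigma2, p2) -> float:
    r = W @ x.reshape(-1) - y
    return float(r @ r / (2 * sigma2)
                 + gmrf_prior_energy(x, neighbors, b) / p2)


def map_gmrf_icd(problem: LinearInverseProblem,
                 settings: ReconSettings | None = None,
                 neighbors: np.ndarray | None = None) -> ReconResult:
    """MAP reconstruction with a 6-connected GMRF prior.

    Minimizes ``||Wx-y||^2/(2 sigma^2) + (1/(2 p^2)) sum b (x_i-x_j)^2`` over
    x >= 0 by exact voxel-wise coordinate descent (fixed raster order); after
    each full sweep the hyperparameters are re-estimated in closed form
    (sigma^2 from the residual, p^2 from the prior energy) unless frozen via
    settings.  Stops when the relative objective change drops below ``tol``.
    """
    s = settings or ReconSettings(max_iter=50, tol=1e-5)
    W = np.ascontiguousarray(np.asarray(problem.W, dtype=np.float64))
    y = np.asarray(problem.y, dtype=np.float64)
    if neighbors is None:
        if problem.grid is None:
            raise ValidationError("map_gmrf_icd needs a grid or explicit neighbors")
        neighbors = grid_neighbors(problem.grid)
    b = 1.0 / 6.0
    WT = np.ascontiguousarray(W.T)
    colnorm2 = np.einsum("ij,ij->i", WT, WT)
    n = problem.n_voxels
    x = np.zeros(n)
    r = (y - W @ x).astype(np.float64)
    sigma2 = s.sigma2 if s.sigma2 is not None else max(float(r @ r) / len(y), 1e-30)
    p2 = s.p2 if s.p2 is not None else 1.0
    trace = [map_objective(W, y, x, neighbors, b, sigma2, p2)]
    converged = False
    it = 0
    for it in range(1, s.max_iter + 1):
        x_prev = x.copy()
        x = _icd_sweep(WT, colnorm2, r, x, neighbors, b, sigma2, p2)
        if s.estimate_hyperparams:
            r = y - W @ x  # refresh (avoids drift of the running residual)
            sigma2 = max(float(r @ r) / len(y), 1e-30)
            pe = gmrf_prior_energy(x, neighbors, b)
            p2 = max(2.0 * pe / n, 1e-30) if pe > 0 else p2
        if not (np.isfinite(sigma2) and np.isfinite(p2)):
            raise ValidationError("non-finite hyperparameters in MAP estimation")
        trace.append(map_objective(W, y, x, neighbors, b, sigma2, p2))
        # hyperparameters move between sweeps, so convergence is judged on
        # the iterate, not on objectives evaluated under different (s2, p2)
        dx = np.linalg.norm(x - x_prev) / max(np.linalg.norm(x_prev), 1e-30)
        if dx <= s.tol:
            converged = True
            break
    return ReconResult(problem.volume(x), np.array(trace), it, converged,
                       {"sigma2": sigma2, "p2": p2})


SOLVERS = {
    "adfista": adfista,
    "tfista": t_fista,
    "admlem": admlem,
    "map": map_gmrf_icd,
}


def reconstruct_classical(method: str, problem: LinearInverseProblem,
                          settings: ReconSettings | None = None) -> ReconResult:
    if method not in SOLVERS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(SOLVERS)}")
    return SOLVERS[method](problem, settings)
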