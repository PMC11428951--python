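"""Cone-beam XLCT physics: X-ray excitation, FEM diffusion transport, projection.

The measurement chain is linear in nanoparticle concentration:

1. X-ray excitation  X(r) = X(r0) exp(-mu_t * path)  (Lambert-Beer through the
   homogeneous cylinder, analytic ray-cylinder intersection).
2. Emission           S(r) = Gamma * X(r) * n(r).
3. Light transport    -div(D grad Phi) + mu_a Phi = S with the Robin condition
   Phi + 2 kappa D (nu . grad Phi) = 0, discretized with P1 finite elements.
4. Detection          boundary exitance J = Phi / (2 kappa) splatted
   orthographically onto the camera grid with a Lambertian facing factor.

The object rotates between views; equivalently the source/camera direction is
rotated in the phantom frame.  Stacking all views gives y = W x, with W
assembled either column-by-column (small problems) or via reciprocity solves
from the boundary nodes (one factorized solve per boundary node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MM_PER_CM, OpticalProperties, Phantom, Target, ValidationError, VoxelGrid
from .mesh import Mesh


@dataclass(frozen=True)
class XRaySource:
    """Cone-beam X-ray source.

    The focal spot sits on the rotation plane at ``source_to_axis_cm`` from
    the phantom axis, opposite the camera.  ``intensity`` is X(r0) in
    arbitrary units; voltage/current are metadata.
    """

    source_to_axis_cm: float = 20.0
    intensity: float = 1.0
    voltage_kv: float = 40.0
    current_ma: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValidationError("X-ray intensity must be positive")
        if self.source_to_axis_cm <= 0:
            raise ValidationError("source-to-axis distance must be positive")

    def focal_position_cm(self, view_angle_deg: float) -> np.ndarray:
        th = np.deg2rad(view_angle_deg)
        return -self.source_to_axis_cm * np.array([np.cos(th), np.sin(th), 0.0])


def default_view_angles(n_views: int = 24) -> np.ndarray:
    return np.arange(n_views) * (360.0 / n_views)


@dataclass(frozen=True)
class DetectorModel:
    """Orthographic optical camera: pixel grid, physical extent, view angles.

    ``psf_sigma_cm`` is a Gaussian point-spread blur applied in the detector
    plane.  It models finite camera resolution and, numerically, smooths the
    point-splat texture of the discrete boundary mesh so images reflect the
    boundary radiance rather than the node lattice.
    """

    n_u: int = 128
    n_v: int = 128
    extent_cm: float = 3.6
    angles_deg: tuple[float, ...] = tuple(default_view_angles(24))
    psf_sigma_cm: float = 0.1

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if len(a) < 1:
            raise ValidationError("need at least one view angle")
        wrapped = np.mod(a, 360.0)
        if len(a) > 1 and not np.all(np.diff(wrapped) > 0):
            raise ValidationError("view angles must be strictly increasing in [0, 360)")
        if self.n_u < 1 or self.n_v < 1 or self.extent_cm <= 0:
            raise ValidationError("invalid detector geometry")

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    @property
    def n_pixels(self) -> int:
        return self.n_u * self.n_v

    @classmethod
    def for_phantom(cls, phantom: Phantom, n_pix: int = 128,
                    n_views: int = 24, margin: float = 1.2) -> "DetectorModel":
        return cls(n_pix, n_pix, phantom.diameter_cm * margin,
                   tuple(default_view_angles(n_views)))


# ----------------------------------------------------------------------------
# X-ray excitation
# ----------------------------------------------------------------------------

def _cylinder_path_length(src: np.ndarray, pts: np.ndarray, R: float, H: float,
                          t_stop: np.ndarray) -> np.ndarray:
    """Length of ray [src -> pts] inside the finite cylinder, truncated at t_stop."""
    d = pts - src
    seg = np.linalg.norm(d, axis=-1)
    if np.any(seg <= 0):
        raise ValidationError("evaluation point coincides with the X-ray focal spot")
    u = d / seg[:, None]
    a = u[:, 0] ** 2 + u[:, 1] ** 2
    b = 2.0 * (src[0] * u[:, 0] + src[1] * u[:, 1])
    c = src[0] ** 2 + src[1] ** 2 - R**2
    disc = b**2 - 4 * a * c
    t1 = np.full(len(pts), np.inf)
    t2 = np.full(len(pts), -np.inf)
    hit = (disc > 0) & (a > 1e-30)
    sq = np.sqrt(np.maximum(disc[hit], 0.0))
    t1[hit] = (-b[hit] - sq) / (2 * a[hit])
    t2[hit] = (-b[hit] + sq) / (2 * a[hit])
    # axial rays: inside iff radial position within R
    axial = a <= 1e-30
    if np.any(axial):
        inside_r = c <= 0
        t1[axial & inside_r] = -np.inf
        t2[axial & inside_r] = np.inf
    # z-slab
    uz = u[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (-H / 2 - src[2]) / uz
        tb = (H / 2 - src[2]) / uz
    z1 = np.where(np.abs(uz) > 1e-30, np.minimum(ta, tb), -np.inf)
    z2 = np.where(np.abs(uz) > 1e-30, np.maximum(ta, tb), np.inf)
    flat = np.abs(uz) <= 1e-30
    if np.any(flat):
        in_slab = np.abs(src[2]) <= H / 2
        z1[flat] = -np.inf if in_slab else np.inf
        z2[flat] = np.inf if in_slab else -np.inf
    lo = np.maximum(np.maximum(t1, z1), 0.0)
    hi = np.minimum(np.minimum(t2, z2), t_stop)
    return np.maximum(hi - lo, 0.0)


def xray_intensity_field(source: XRaySource, phantom: Phantom,
                         points_cm: np.ndarray,
                         view_angle_deg: float = 0.0) -> np.ndarray:
    """X-ray intensity X(p) at points (cm) for one view, Lambert-Beer attenuated.

    The line integral of mu_t runs along the straight ray from the focal spot
    to each point; for the homogeneous phantom it is mu_t times the analytic
    ray-cylinder intersection length.
    """
    pts = np.atleast_2d(np.asarray(points_cm, dtype=float))
    src = source.focal_position_cm(view_angle_deg)
    t_stop = np.linalg.norm(pts - src, axis=-1)
    L = _cylinder_path_length(src, pts, phantom.radius_cm, phantom.height_cm, t_stop)
    return source.intensity * np.exp(-phantom.xray_mu_t_cm * L)


def emission_source(xray_field: np.ndarray, concentration: np.ndarray,
                    gamma: float = 1.0) -> np.ndarray:
    """Emission density S = gamma * X * n, pointwise on mesh nodes."""
    x = np.asarray(xray_field, dtype=float)
    n = np.asarray(concentration, dtype=float)
    if x.shape != n.shape:
        raise ValidationError("X-ray field and concentration must share node sampling")
    if np.any(n < 0):
        raise ValidationError("negative concentration")
    return gamma * x * n


# ----------------------------------------------------------------------------
# FEM diffusion
# ----------------------------------------------------------------------------

class AssemblyError(RuntimeError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass
class DiffusionSystem:
    """Assembled FEM system A Phi = M S with Robin boundary absorbed into A."""

    A: sp.csc_matrix
    M: sp.csr_matrix
    mesh: Mesh
    optics: OpticalProperties
    _lu: object | None = field(default=None, repr=False)

    #: above this node count single solves go through preconditioned CG
    #: instead of a (fill-heavy) direct factorization
    direct_limit: int = 20_000

    @property
    def lu(self):
        if self._lu is None:
            self._lu = spla.splu(self.A)
        return self._lu

    def solve(self, rhs: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
        rhs = np.asarray(rhs, dtype=float)
        nrm = np.linalg.norm(rhs)
        if nrm == 0:
            return np.zeros_like(rhs)
        if self.A.shape[0] <= self.direct_limit or self._lu is not None:
            phi = self.lu.solve(rhs)
        else:
            d = self.A.diagonal()
            M = spla.LinearOperator(self.A.shape, lambda x: x / d)
            phi, info = spla.cg(self.A, rhs, rtol=0.1 * rtol, maxiter=10_000, M=M)
            if info != 0:
                raise SolverError(f"CG did not converge (info={info})")
        res = np.linalg.norm(self.A @ phi - rhs) / nrm
        if not np.isfinite(res) or res > rtol:
            raise SolverError(f"diffusion solve residual {res:.2e} exceeds {rtol:.0e}")
        return phi


def _tet_gradients(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric gradients and volumes for tets with corner coords p (n,4,3)."""
    v0 = p[:, 0]
    J = np.stack([p[:, 1] - v0, p[:, 2] - v0, p[:, 3] - v0], axis=-1)
    detJ = np.linalg.det(J)
    vol = np.abs(detJ) / 6.0
    invJ = np.linalg.inv(J)
    # lambda_k(x) solves J lambda = x - p0, so grad lambda_k is row k of J^-1;
    # lambda0 = 1 - sum
    g123 = invJ
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (n, 4, 3)
    return grads, vol


def assemble_diffusion_system(mesh: Mesh, optics: OpticalProperties) -> DiffusionSystem:
    """Assemble A = D*stiffness + mu_a*mass + boundary mass/(2 kappa), and the
    interior mass matrix M used to couple nodal source densities.
    """
    p = mesh.nodes[mesh.tets]
    grads, vol = _tet_gradients(p)
    if np.any(vol <= 0) or not np.all(np.isfinite(grads)):
        raise AssemblyError("degenerate element in mesh")
    D = optics.diffusion
    mu_a = optics.mu_a

    n_t = len(mesh.tets)
    Ke = D * np.einsum("tid,tjd,t->tij", grads, grads, vol)
    base = (np.ones((4, 4)) + np.eye(4)) / 20.0
    Me = mu_a * vol[:, None, None] * base
    Mass_e = vol[:, None, None] * base

    rows = np.repeat(mesh.tets, 4, axis=1).reshape(n_t, 4, 4)
    cols = np.tile(mesh.tets[:, None, :], (1, 4, 1))
    ij = (rows.ravel(), cols.ravel())
    n = mesh.n_nodes
    A = sp.coo_matrix(((Ke + Me).ravel(), ij), shape=(n, n))
    M = sp.coo_matrix((Mass_e.ravel(), ij), shape=(n, n))

    # Robin term: surface mass / (2 kappa)
    fa = mesh.boundary_face_areas()
    tb = (np.ones((3, 3)) + np.eye(3)) / 12.0
    Be = (fa / (2.0 * optics.kappa))[:, None, None] * tb
    brows = np.repeat(mesh.boundary_faces, 3, axis=1).reshape(-1, 3, 3)
    bcols = np.tile(mesh.boundary_faces[:, None, :], (1, 3, 1))
    B = sp.coo_matrix((Be.ravel(), (brows.ravel(), bcols.ravel())), shape=(n, n))

    A = (A + B).tocsc()
    if not np.all(np.isfinite(A.data)):
        raise AssemblyError("non-finite entries in assembled system")
    return DiffusionSystem(A, M.tocsr(), mesh, optics)


def solve_fluence(system: DiffusionSystem, S_nodal: np.ndarray,
                  rtol: float = 1e-8) -> np.ndarray:
    """Solve the diffusion system for a nodal source density S (per cm^3)."""
    rhs = system.M @ np.asarray(S_nodal, dtype=float)
    return system.solve(rhs, rtol=rtol)


def infinite_medium_fluence(r_cm: np.ndarray, optics: OpticalProperties) -> np.ndarray:
    """Analytic diffusion Green's function for a unit point source:
    Phi(r) = exp(-mu_eff r) / (4 pi D r)."""
    r = np.asarray(r_cm, dtype=float)
    D = optics.diffusion
    return np.exp(-optics.mu_eff * r) / (4.0 * np.pi * D * r)


# ----------------------------------------------------------------------------
# Boundary -> camera projection
# ----------------------------------------------------------------------------

def _splat_matrix(mesh: Mesh, bnodes: np.ndarray, bnormals: np.ndarray,
                  bareas: np.ndarray, view_angle_deg: float,
                  detector: DetectorModel) -> sp.csr_matrix:
    """Sparse (n_pixels x n_boundary_nodes) bilinear splat for one view."""
    th = np.deg2rad(view_angle_deg)
    cam = np.array([np.cos(th), np.sin(th), 0.0])
    u_axis = np.array([-np.sin(th), np.cos(th), 0.0])
    facing = np.maximum(bnormals @ cam, 0.0)
    w_node = bareas * facing

    pos = mesh.nodes[bnodes]
    u = pos @ u_axis
    v = pos[:, 2]
    half = 0.5 * detector.extent_cm
    pu = (u + half) / detector.extent_cm * detector.n_u - 0.5
    pv = (v + half) / detector.extent_cm * detector.n_v - 0.5

    i0 = np.floor(pu).astype(int)
    j0 = np.floor(pv).astype(int)
    fu = pu - i0
    fv = pv - j0
    rows, cols, vals = [], [], []
    for di, dj, wf in (
        (0, 0, (1 - fu) * (1 - fv)),
        (1, 0, fu * (1 - fv)),
        (0, 1, (1 - fu) * fv),
        (1, 1, fu * fv),
    ):
        ii = i0 + di
        jj = j0 + dj
        ok = (ii >= 0) & (ii < detector.n_u) & (jj >= 0) & (jj < detector.n_v)
        ok &= w_node > 0
        rows.append(jj[ok] * detector.n_u + ii[ok])
        cols.append(np.flatnonzero(ok))
        vals.append((wf * w_node)[ok])
    G = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(detector.n_pixels, len(bnodes)),
    )
    blur = _psf_matrix(detector)
    return (blur @ G).tocsr() if blur is not None else G


def _gauss_kernel_1d(n: int, sigma_px: float) -> sp.csr_matrix:
    radius = max(1, int(np.ceil(3.0 * sigma_px)))
    offsets = np.arange(-radius, radius + 1)
    taps = np.exp(-0.5 * (offsets / sigma_px) ** 2)
    taps /= taps.sum()
    rows, cols, vals = [], [], []
    for off, t in zip(offsets, taps):
        idx = np.arange(n)
        j = idx + off
        ok = (j >= 0) & (j < n)
        rows.append(idx[ok])
        cols.append(j[ok])
        vals.append(np.full(ok.sum(), t))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))


def _psf_matrix(detector: DetectorModel) -> sp.csr_matrix | None:
    """Separable Gaussian PSF as a sparse (n_pixels x n_pixels) operator."""
    if detector.psf_sigma_cm <= 0:
        return None
    sigma_px = detector.psf_sigma_cm / (detector.extent_cm / detector.n_u)
    ku = _gauss_kernel_1d(detector.n_u, sigma_px)
    kv = _gauss_kernel_1d(detector.n_v, sigma_px)
    return sp.kron(kv, ku).tocsr()


def boundary_projection(fluence: np.ndarray, mesh: Mesh, view_angle_deg: float,
                        detector: DetectorModel, kappa: float = 1.0) -> np.ndarray:
    """Project boundary exitance J = Phi/(2 kappa) onto the camera for one view.

    Only camera-facing boundary nodes (outward normal . camera direction > 0)
    contribute; each node is splatted bilinearly with an area x cosine weight.
    Returns an (n_v, n_u) image.
    """
    bnodes = mesh.boundary_nodes()
    bnormals, bareas = mesh.boundary_node_normals_areas()
    G = _splat_matrix(mesh, bnodes, bnormals, bareas, view_angle_deg, detector)
    J = np.asarray(fluence, dtype=float)[bnodes] / (2.0 * kappa)
    return (G @ J).reshape(detector.n_v, detector.n_u)


@dataclass
class ProjectionSet:
    """Stack of angle-indexed camera images, shape (n_views, n_v, n_u)."""

    images: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.images.ndim != 3 or len(self.images) != len(self.angles_deg):
            raise ValidationError("projection stack must be (n_views, H, W)")
        if not np.all(np.isfinite(self.images)):
            raise ValidationError("non-finite projection values")

    def stacked(self) -> np.ndarray:
        """View-major, row-major measurement vector (the y of y = W x)."""
        return self.images.reshape(-1)


def add_gaussian_noise(projections: ProjectionSet, snr_db: float,
                       rng: np.random.Generator | int | None = None) -> ProjectionSet:
    """Add i.i.d. zero-mean white Gaussian noise at a stack-wide SNR (dB).

    sigma = sqrt(mean(p^2) / 10^(snr_db/10)) over the whole stack; an infinite
    SNR returns the input unchanged.
    """
    if np.isinf(snr_db):
        return ProjectionSet(projections.images.copy(), projections.angles_deg.copy())
    rng = np.random.default_rng(rng)
    p = projections.images
    sigma = float(np.sqrt(np.mean(p**2) / 10.0 ** (snr_db / 10.0)))
    noisy = p + rng.normal(0.0, sigma, size=p.shape)
    return ProjectionSet(noisy, projections.angles_deg.copy())


# ----------------------------------------------------------------------------
# Full forward operator
# ----------------------------------------------------------------------------

class ForwardModel:
    """Caches everything needed to run the forward chain repeatedly.

    One FEM factorization, per-view X-ray fields and splat matrices, and the
    voxel->node interpolation are computed once; simulating a sample is then a
    handful of triangular back-substitutions.
    """

    def __init__(self, phantom: Phantom, mesh: Mesh, detector: DetectorModel,
                 source: XRaySource | None = None, grid: VoxelGrid | None = None,
                 gamma: float = 1.0):
        self.phantom = phantom
        self.mesh = mesh
        self.detector = detector
        self.source = source or XRaySource()
        self.grid = grid
        self.gamma = gamma
        self.system = assemble_diffusion_system(mesh, phantom.optical)
        self.bnodes = mesh.boundary_nodes()
        self.bnormals, self.bareas = mesh.boundary_node_normals_areas()
        self._G: dict[int, sp.csr_matrix] = {}
        self._X: dict[int, np.ndarray] = {}
        self._B: sp.csr_matrix | None = None

    # -- cached pieces ------------------------------------------------------
    def splat(self, view: int) -> sp.csr_matrix:
        if view not in self._G:
            self._G[view] = _splat_matrix(
                self.mesh, self.bnodes, self.bnormals, self.bareas,
                self.detector.angles_deg[view], self.detector)
        return self._G[view]

    def xray_at_nodes(self, view: int) -> np.ndarray:
        if view not in self._X:
            self._X[view] = xray_intensity_field(
                self.source, self.phantom, self.mesh.nodes,
                self.detector.angles_deg[view])
        return self._X[view]

    @property
    def voxel_to_node(self) -> sp.csr_matrix:
        """Trilinear interpolation matrix B: node value = (B x) for voxel field x."""
        if self.grid is None:
            raise ValidationError("ForwardModel was built without a voxel grid")
        if self._B is None:
            self._B = _build_voxel_to_node(self.mesh, self.grid)
        return self._B

    # -- forward chains -----------------------------------------------------
    def node_concentration(self, targets: list[Target]) -> np.ndarray:
        """Analytic nodal concentration field (mg/mL) from target cylinders."""
        pts_mm = self.mesh.nodes * MM_PER_CM
        conc = np.zeros(self.mesh.n_nodes)
        for t in targets:
            conc[t.contains_mm(pts_mm)] += t.concentration
        return conc

    def project_node_concentration(self, conc: np.ndarray,
                                   gamma: float | None = None) -> ProjectionSet:
        """Run excitation -> emission -> diffusion -> camera for every view."""
        gamma = self.gamma if gamma is None else gamma
        kappa = self.phantom.optical.kappa
        images = np.empty((self.detector.n_views, self.detector.n_v, self.detector.n_u))
        for v in range(self.detector.n_views):
            S = emission_source(self.xray_at_nodes(v), conc, gamma)
            phi = solve_fluence(self.system, S)
            J = phi[self.bnodes] / (2.0 * kappa)
            images[v] = (self.splat(v) @ J).reshape(self.detector.n_v, self.detector.n_u)
        return ProjectionSet(images, np.asarray(self.detector.angles_deg))

    def simulate_projections(self, targets: list[Target]) -> ProjectionSet:
        """Noise-free projections of cylindrical targets.

        With a voxel grid attached, targets are rasterized onto it and
        interpolated to the mesh nodes — sub-node-resolution shapes survive
        and the chain is exactly the one W discretizes.  Direct nodal
        sampling (much coarser on coarse meshes) is the fallback without a
        grid.
        """
        if self.grid is not None:
            from .geometry import rasterize_targets

            truth, _ = rasterize_targets(targets, self.grid)
            return self.forward_voxels(truth)
        return self.project_node_concentration(self.node_concentration(targets))

    def forward_voxels(self, x: np.ndarray) -> ProjectionSet:
        """Forward-project a voxel concentration field through the same chain
        used for weight-matrix assembly (voxel -> node interpolation)."""
        conc = self.voxel_to_node @ np.asarray(x, dtype=float).reshape(-1)
        return self.project_node_concentration(conc)

    # -- weight matrix ------------------------------------------------------
    def build_weight_matrix(self, dtype=np.float32) -> np.ndarray:
        """Assemble W (n_views*n_pixels x n_voxels) via reciprocity.

        One factorized solve per boundary node gives K0 = R A^-1; each view's
        block is then G_v K0 M diag(gamma X_v) B / (2 kappa).
        """
        if self.grid is None:
            raise ValidationError("need a voxel grid to build W")
        kappa = self.phantom.optical.kappa
        n = self.mesh.n_nodes
        rhs = np.zeros((n, len(self.bnodes)))
        rhs[self.bnodes, np.arange(len(self.bnodes))] = 1.0
        K0 = self.system.lu.solve(rhs).T  # (n_bnodes, n_nodes)

        B = self.voxel_to_node
        n_pix = self.detector.n_pixels
        W = np.empty((self.detector.n_views * n_pix, self.grid.n_voxels), dtype=dtype)
        for v in range(self.detector.n_views):
            PK = (self.splat(v) @ K0) / (2.0 * kappa)  # (n_pix, n_nodes)
            C = self.system.M @ sp.diags(self.gamma * self.xray_at_nodes(v)) @ B
            block = (C.T @ PK.T).T  # (n_pix, n_vox)
            W[v * n_pix:(v + 1) * n_pix] = block.astype(dtype)
        return W

    def build_weight_matrix_direct(self, dtype=np.float64) -> np.ndarray:
        """Column-by-column assembly (one forward chain per voxel).

        Exact but O(n_voxels) solves -- intended for coarse cross-checks of
        the reciprocity assembly.
        """
        if self.grid is None:
            raise ValidationError("need a voxel grid to build W")
        n_vox = self.grid.n_voxels
        W = np.empty((self.detector.n_views * self.detector.n_pixels, n_vox),
                     dtype=dtype)
        x = np.zeros(n_vox)
        for j in range(n_vox):
            x[j] = 1.0
            W[:, j] = self.forward_voxels(x).stacked()
            x[j] = 0.0
        return W


def _build_voxel_to_node(mesh: Mesh, grid: VoxelGrid) -> sp.csr_matrix:
    """Trilinear voxel-centre -> mesh-node interpolation (nodes outside the
    grid's z-band or in-plane extent receive zero)."""
    xs, ys, zs = grid.axis_centers_mm()
    pts = mesh.nodes * MM_PER_CM
    rows, cols, vals = [], [], []

    def locate(coords, centers):
        idx = np.searchsorted(centers, coords) - 1
        idx = np.clip(idx, 0, len(centers) - 2)
        frac = (coords - centers[idx]) / (centers[idx + 1] - centers[idx])
        inside = (coords >= centers[0]) & (coords <= centers[-1])
        return idx, np.clip(frac, 0.0, 1.0), inside

    ix, fx, okx = locate(pts[:, 0], xs)
    iy, fy, oky = locate(pts[:, 1], ys)
    iz, fz, okz = locate(pts[:, 2], zs)
    ok = okx & oky & okz
    node_ids = np.flatnonzero(ok)
    for dz in (0, 1):
        wz = np.where(dz, fz, 1 - fz)[ok]
        for dy in (0, 1):
            wy = np.where(dy, fy, 1 - fy)[ok]
            for dx in (0, 1):
                wx = np.where(dx, fx, 1 - fx)[ok]
                w = wx * wy * wz
                col = ((iz[ok] + dz) * grid.ny + (iy[ok] + dy)) * grid.nx + (ix[ok] + dx)
                keep = w > 0
                rows.append(node_ids[keep])
                cols.append(col[keep])
                vals.append(w[keep])
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_nodes, grid.n_voxels),
    )
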