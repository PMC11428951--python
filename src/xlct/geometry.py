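"""Imaging geometry: cylindrical phantom, luminescent targets, reconstruction grid.

Unit conventions
----------------
The optical/FEM side of the package works in centimetres (phantom dimensions,
optical coefficients in cm^-1, mesh node coordinates).  Target placement and
the reconstruction voxel grid are specified in millimetres, matching how
edge-to-edge distances and target sizes are usually quoted for this modality.
Conversions happen explicitly at module boundaries via ``MM_PER_CM``.

The coordinate frame is right-handed with the origin on the phantom axis at
mid-height and z along the cylinder axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MM_PER_CM = 10.0


class ValidationError(ValueError):
    """Raised when a geometry or configuration precondition is violated."""


class PlacementError(RuntimeError):
    """Raised when random target placement cannot satisfy its constraints."""


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the scattering medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, cm^-1.
    kappa : float
        Boundary refractive-index mismatch parameter (dimensionless);
        1 corresponds to an index-matched boundary.
    """

    mu_a: float
    mu_s_prime: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0 or self.kappa <= 0:
            raise ValidationError(
                "mu_a, mu_s_prime and kappa must all be positive, got "
                f"({self.mu_a}, {self.mu_s_prime}, {self.kappa})"
            )

    @property
    def diffusion(self) -> float:
        """Diffusion coefficient D = 1 / (3 (mu_s' + mu_a)), in cm."""
        return 1.0 / (3.0 * (self.mu_s_prime + self.mu_a))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(mu_a / D) = sqrt(3 mu_a (mu_a + mu_s')), cm^-1."""
        return float(np.sqrt(self.mu_a / self.diffusion))


@dataclass(frozen=True)
class Phantom:
    """Homogeneous cylindrical imaging object.

    ``diameter_cm``/``height_cm`` describe the cylinder, ``optical`` the light
    transport medium, and ``xray_mu_t_cm`` the (homogeneous) X-ray attenuation
    coefficient used by the excitation model.
    """

    diameter_cm: float
    height_cm: float
    optical: OpticalProperties
    xray_mu_t_cm: float = 0.3

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0 or self.height_cm <= 0:
            raise ValidationError("phantom dimensions must be positive")
        if self.xray_mu_t_cm < 0:
            raise ValidationError("X-ray attenuation must be nonnegative")

    @property
    def radius_cm(self) -> float:
        return 0.5 * self.diameter_cm

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_cm * MM_PER_CM

    @property
    def height_mm(self) -> float:
        return self.height_cm * MM_PER_CM

    def contains_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean mask of points (``(..., 3)``, mm) strictly inside the cylinder."""
        p = np.asarray(points_mm, dtype=float)
        r2 = p[..., 0] ** 2 + p[..., 1] ** 2
        return (r2 <= self.radius_mm**2) & (np.abs(p[..., 2]) <= 0.5 * self.height_mm)


def make_cylinder_phantom(
    diameter_cm: float,
    height_cm: float,
    optics: OpticalProperties,
    xray_mu_t_cm: float = 0.3,
) -> Phantom:
    """Construct a homogeneous cylinder phantom (validates all dimensions)."""
    return Phantom(diameter_cm, height_cm, optics, xray_mu_t_cm)


@dataclass(frozen=True)
class Target:
    """Axis-aligned luminescent cylinder embedded in the phantom.

    center_mm is (x, y, z) in phantom-centred coordinates; ``concentration``
    is the nanophosphor concentration in mg/mL and ``light_yield`` the number
    of optical photons emitted per unit concentration per unit X-ray
    intensity (arbitrary units; it acts as a global scale).
    """

    center_mm: tuple[float, float, float]
    diameter_mm: float
    height_mm: float
    concentration: float = 50.0
    light_yield: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError("concentration must be nonnegative")
        if self.light_yield <= 0:
            raise ValidationError("light yield must be positive")
        if self.diameter_mm <= 0 or self.height_mm <= 0:
            raise ValidationError("target dimensions must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    def contains_mm(self, points_mm: np.ndarray) -> np.ndarray:
        """Mask of points (``(..., 3)``, mm) inside this target cylinder.

        The axial interval is half-open ([z_lo, z_hi)), the usual
        rasterization convention: when cylinder faces fall exactly on voxel
        centres the voxel count stays close to volume / voxel-volume instead
        of being inflated by double-counted boundary planes.
        """
        p = np.asarray(points_mm, dtype=float)
        cx, cy, cz = self.center_mm
        r2 = (p[..., 0] - cx) ** 2 + (p[..., 1] - cy) ** 2
        dz = p[..., 2] - cz
        return (r2 <= self.radius_mm**2) & (dz >= -0.5 * self.height_mm) \
            & (dz < 0.5 * self.height_mm)

    def inside_phantom(self, phantom: Phantom) -> bool:
        cx, cy, cz = self.center_mm
        radial_ok = np.hypot(cx, cy) + self.radius_mm < phantom.radius_mm
        axial_ok = abs(cz) + 0.5 * self.height_mm < 0.5 * phantom.height_mm
        return bool(radial_ok and axial_ok)


def compute_eed(t1: Target, t2: Target) -> float:
    """Edge-to-edge distance (mm) between two axis-aligned cylindrical targets.

    Defined in-plane: centre distance minus both radii.  A negative value
    signals radial overlap.
    """
    d = np.hypot(
        t1.center_mm[0] - t2.center_mm[0], t1.center_mm[1] - t2.center_mm[1]
    )
    # grouped subtraction keeps the result exactly symmetric in (t1, t2)
    return float(d - (t1.radius_mm + t2.radius_mm))


def sample_targets(
    rng: np.random.Generator | int,
    phantom: Phantom,
    n_targets: int = 2,
    diam_choices_mm: tuple[float, ...] = (3.0, 4.0),
    height_mm: float = 4.0,
    center_range_mm: float = 10.0,
    eed_range_mm: tuple[float, float] = (0.3, 2.5),
    concentration: float = 50.0,
    light_yield: float = 1.0,
    z_jitter_mm: float = 1.0,
    max_attempts: int = 10_000,
) -> list[Target]:
    """Rejection-sample ``n_targets`` cylinders with pairwise EED constraints.

    Target x/y centres are uniform in ``[-center_range_mm, center_range_mm]``;
    every pairwise edge-to-edge distance must fall in ``eed_range_mm`` and
    every target must lie strictly inside the phantom.  z centres get a
    uniform jitter of +-``z_jitter_mm`` around mid-height so the output slab
    always contains the targets.

    Raises
    ------
    PlacementError
        If no admissible configuration is found within ``max_attempts``.
    ValidationError
        For infeasible parameterizations (e.g. negative EED range).
    """
    if n_targets < 1:
        raise ValidationError("n_targets must be >= 1")
    lo, hi = eed_range_mm
    if lo < 0 or hi < lo:
        raise ValidationError(f"invalid EED range {eed_range_mm}")
    if center_range_mm <= 0:
        raise ValidationError("center_range_mm must be positive")
    rng = np.random.default_rng(rng)

    def draw(diam: float, around: Target | None) -> Target:
        # first target: uniform over the admissible square; partners: uniform
        # over the EED annulus of an existing target (keeps the first-target
        # marginal uniform instead of biasing it away from the box edges)
        if around is None:
            cx, cy = rng.uniform(-center_range_mm, center_range_mm, size=2)
        else:
            r_lo = around.radius_mm + 0.5 * diam + lo
            r_hi = around.radius_mm + 0.5 * diam + hi
            rr = float(np.sqrt(rng.uniform(r_lo**2, r_hi**2)))
            phi = float(rng.uniform(0.0, 2.0 * np.pi))
            cx = around.center_mm[0] + rr * np.cos(phi)
            cy = around.center_mm[1] + rr * np.sin(phi)
        cz = float(rng.uniform(-z_jitter_mm, z_jitter_mm)) if z_jitter_mm > 0 else 0.0
        return Target((float(cx), float(cy), cz), diam, height_mm,
                      concentration, light_yield)

    def admissible(cand: Target, placed: list[Target]) -> bool:
        return (cand.inside_phantom(phantom)
                and abs(cand.center_mm[0]) <= center_range_mm
                and abs(cand.center_mm[1]) <= center_range_mm
                and all(lo <= compute_eed(cand, t) <= hi for t in placed))

    attempts = 0
    while attempts < max_attempts:
        # the anchor target is accepted purely on its own constraints, so its
        # marginal stays uniform; partner failures restart the configuration
        # only after a generous retry budget (keeps anchor bias negligible)
        targets: list[Target] = []
        while attempts < max_attempts:
            attempts += 1
            cand = draw(float(rng.choice(diam_choices_mm)), None)
            if admissible(cand, []):
                targets.append(cand)
                break
        ok = len(targets) == 1
        for i in range(1, n_targets):
            for _ in range(200):
                attempts += 1
                anchor = targets[int(rng.integers(i))]
                cand = draw(float(rng.choice(diam_choices_mm)), anchor)
                if admissible(cand, targets):
                    targets.append(cand)
                    break
            else:
                ok = False
                break
        if ok and len(targets) == n_targets:
            return targets
    raise PlacementError(
        f"could not place {n_targets} targets with EED in {eed_range_mm} "
        f"within {max_attempts} attempts"
    )


@dataclass(frozen=True)
class VoxelGrid:
    """Regular reconstruction grid, phantom-centred, spacings in mm.

    The canonical full-scale grid is 128 x 128 in-plane (spacing = phantom
    diameter / 128) by 7 axial slices at 1 mm; smaller shapes are first-class
    for scaled-down runs and are recorded in configuration.
    """

    nx: int = 128
    ny: int = 128
    nz: int = 7
    dx_mm: float = 30.0 / 128
    dy_mm: float = 30.0 / 128
    dz_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValidationError("grid shape must be positive")
        if min(self.dx_mm, self.dy_mm, self.dz_mm) <= 0:
            raise ValidationError("grid spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx): volumes are stored slice-major."""
        return (self.nz, self.ny, self.nx)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    def axis_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along x, y, z (each centred on the origin)."""
        def centers(n: int, d: float) -> np.ndarray:
            return (np.arange(n) - (n - 1) / 2.0) * d

        return (centers(self.nx, self.dx_mm),
                centers(self.ny, self.dy_mm),
                centers(self.nz, self.dz_mm))

    def voxel_centers_mm(self) -> np.ndarray:
        """All voxel centres, shape ``(nz, ny, nx, 3)`` in mm."""
        xs, ys, zs = self.axis_centers_mm()
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    @classmethod
    def for_phantom(cls, phantom: Phantom, nx: int = 128, ny: int = 128,
                    nz: int = 7, dz_mm: float = 1.0) -> "VoxelGrid":
        d = phantom.diameter_cm * MM_PER_CM
        return cls(nx, ny, nz, d / nx, d / ny, dz_mm)


def rasterize_targets(
    targets: list[Target],
    grid: VoxelGrid,
    roi_margin_voxels: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize targets onto ``grid``.

    Returns
    -------
    truth_volume : ndarray, shape (nz, ny, nx)
        Concentration (mg/mL) at voxels whose centres fall inside any target.
        Overlapping targets sum.
    roi_mask : ndarray of bool
        Union of per-target axis-aligned bounding boxes, dilated by
        ``roi_margin_voxels`` voxels.
    """
    truth = np.zeros(grid.shape, dtype=float)
    roi = np.zeros(grid.shape, dtype=bool)
    if not targets:
        return truth, roi
    centers = grid.voxel_centers_mm()
    xs, ys, zs = grid.axis_centers_mm()
    m = roi_margin_voxels
    for t in targets:
        inside = t.contains_mm(centers)
        truth[inside] += t.concentration
        cx, cy, cz = t.center_mm
        ix = np.flatnonzero(np.abs(xs - cx) <= t.radius_mm)
        iy = np.flatnonzero(np.abs(ys - cy) <= t.radius_mm)
        iz = np.flatnonzero(np.abs(zs - cz) <= 0.5 * t.height_mm)
        if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
            continue
        sl = (
            slice(max(iz[0] - m, 0), min(iz[-1] + m + 1, grid.nz)),
            slice(max(iy[0] - m, 0), min(iy[-1] + m + 1, grid.ny)),
            slice(max(ix[0] - m, 0), min(ix[-1] + m + 1, grid.nx)),
        )
        roi[sl] = True
    return truth, roi


def simulation_phantom() -> Phantom:
    """The 3.0 cm diameter x 2.3 cm cylinder with mu_a=0.02, mu_s'=10 cm^-1."""
    return make_cylinder_phantom(3.0, 2.3, OpticalProperties(0.02, 10.0))
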