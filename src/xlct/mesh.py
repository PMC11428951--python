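"""Tetrahedral meshing of the cylinder phantom for the diffusion FEM solve.

The mesh is built structurally: concentric rings of points on each axial
layer are triangulated (2D Delaunay), and each triangular prism between
consecutive layers is split into three tetrahedra with the classic
minimum-global-index diagonal rule, which guarantees a conforming, watertight
mesh.  Node coordinates are in centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .geometry import Phantom, ValidationError


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """P1 tetrahedral mesh.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, cm.
    tets : (n_tets, 4) int array of node indices.
    boundary_faces : (n_faces, 3) int array of surface triangles.
    boundary_normals : (n_faces, 3) outward unit normals.
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_normals: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        v = np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0
        return np.abs(v)

    def boundary_face_areas(self) -> np.ndarray:
        p = self.nodes[self.boundary_faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def boundary_nodes(self) -> np.ndarray:
        """Sorted unique indices of nodes on the surface."""
        return np.unique(self.boundary_faces)

    def boundary_node_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Area-weighted outward unit normal and lumped area per boundary node.

        Returns arrays aligned with :meth:`boundary_nodes` ordering.
        """
        bnodes = self.boundary_nodes()
        pos = {n: i for i, n in enumerate(bnodes)}
        normals = np.zeros((len(bnodes), 3))
        areas = np.zeros(len(bnodes))
        face_areas = self.boundary_face_areas()
        for f, nrm, a in zip(self.boundary_faces, self.boundary_normals, face_areas):
            for n in f:
                i = pos[n]
                normals[i] += a * nrm
                areas[i] += a / 3.0
        norms = np.linalg.norm(normals, axis=1)
        norms[norms == 0] = 1.0
        return normals / norms[:, None], areas


def _disk_points(radius: float, edge: float) -> np.ndarray:
    """Concentric-ring point set covering a disk, typical spacing ``edge``.

    Ring point counts are rounded up to multiples of 8 with no angular
    stagger, so the point set is invariant under the dihedral symmetries of
    the square (90-degree rotations and axis mirrors) — the FEM operator
    then respects the scene symmetries up to triangulation differences.
    """
    n_r = max(2, int(round(radius / edge)))
    pts = [(0.0, 0.0)]
    for k in range(1, n_r + 1):
        r = radius * k / n_r
        m = max(8, int(np.ceil(2.0 * np.pi * r / edge / 8.0)) * 8)
        # stagger alternate rings by half a step (pi/m offsets map to
        # themselves under 90-degree rotations and axis mirrors when m is a
        # multiple of 8, so the dihedral symmetry survives) — this avoids the
        # radially aligned sliver tetrahedra of unstaggered rings
        offset = (np.pi / m) * (k % 2)
        ang = offset + 2.0 * np.pi * np.arange(m) / m
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.array(pts)


def _split_prism(bottom: np.ndarray, top: np.ndarray) -> list[tuple[int, int, int, int]]:
    # order by bottom global index; bottom ids < top ids by construction, so
    # each quad's diagonal runs from its smallest bottom vertex
    order = np.argsort(bottom)
    b = bottom[order]
    t = top[order]
    return [
        (b[0], b[1], b[2], t[2]),
        (b[0], b[1], t[1], t[2]),
        (b[0], t[0], t[1], t[2]),
    ]


def mesh_cylinder(phantom: Phantom, target_edge_cm: float) -> Mesh:
    """Mesh the phantom cylinder with tetrahedra of typical edge ``target_edge_cm``.

    Raises :class:`MeshingError` on degenerate elements (volume < 1e-12 cm^3)
    and :class:`~xlct.geometry.ValidationError` on an out-of-range edge.
    """
    R = phantom.radius_cm
    H = phantom.height_cm
    if not (0 < target_edge_cm < phantom.diameter_cm / 4):
        raise ValidationError(
            f"target_edge_cm must lie in (0, diameter/4), got {target_edge_cm}"
        )
    disk = _disk_points(R, target_edge_cm)
    tri = Delaunay(disk)
    triangles = tri.simplices
    # drop any degenerate (zero-area) triangles qhull may emit on boundaries
    p = disk[triangles]
    areas2 = np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    triangles = triangles[areas2 > 1e-14]

    n_layers = max(2, int(round(H / target_edge_cm)))
    # even layer count puts a node plane at z = 0 (useful for centred sources)
    if n_layers % 2:
        n_layers += 1
    z_levels = np.linspace(-H / 2.0, H / 2.0, n_layers + 1)
    n_disk = len(disk)
    nodes = np.concatenate(
        [np.column_stack([disk, np.full(n_disk, z)]) for z in z_levels]
    )

    tets = []
    for layer in range(n_layers):
        lo = layer * n_disk
        hi = (layer + 1) * n_disk
        for t in triangles:
            tets.extend(_split_prism(t + lo, t + hi))
    tets = np.array(tets, dtype=np.int64)

    mesh = Mesh(nodes, tets, np.empty((0, 3), dtype=np.int64), np.empty((0, 3)))
    vols = mesh.tet_volumes()
    if np.any(vols < 1e-12):
        raise MeshingError(
            f"{int(np.sum(vols < 1e-12))} degenerate tetrahedra "
            f"(min volume {vols.min():.3e} cm^3)"
        )

    faces, normals = _extract_boundary(nodes, tets)
    mesh.boundary_faces = faces
    mesh.boundary_normals = normals
    return mesh


def _extract_boundary(nodes: np.ndarray, tets: np.ndarray):
    """Faces appearing in exactly one tet, with outward unit normals."""
    local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    all_faces = np.concatenate([tets[:, f] for f in local])
    opposite = np.concatenate([tets[:, 3 - i] for i, _ in enumerate(local)])
    key = np.sort(all_faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    faces = all_faces[on_boundary]
    opp = opposite[on_boundary]
    p = nodes[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    # orient away from the opposite vertex of the owning tet
    to_opp = nodes[opp] - p[:, 0]
    flip = np.einsum("ij,ij->i", n, to_opp) > 0
    n[flip] *= -1.0
    return faces, n


def check_watertight(mesh: Mesh) -> bool:
    """True iff every face is shared by exactly 1 (surface) or 2 (interior) tets."""
    local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    all_faces = np.concatenate([mesh.tets[:, f] for f in local])
    key = np.sort(all_faces, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    return bool(np.all((counts == 1) | (counts == 2)))


def write_vtk(mesh: Mesh, path: str, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional per-node scalar fields) as legacy ASCII VTK."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nxlct mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        n_t = len(mesh.tets)
        fh.write(f"CELLS {n_t} {5 * n_t}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {n_t}\n")
        fh.write("\n".join(["10"] * n_t) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(vals)) + "\n")
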