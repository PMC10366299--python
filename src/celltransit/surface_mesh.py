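"""Closed triangulated sphere meshes for cell and nucleus membranes.

The membranes are discretised into flat triangular elements obtained by
recursive 4-to-1 midpoint subdivision of a regular octahedron, with every
new vertex projected radially onto the sphere.  Five subdivision levels
give the production mesh of 8192 faces connecting 4098 vertices.  The
stress-free reference configuration is the initial sphere itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriMesh", "make_sphere_mesh", "mesh_geometry", "MeshGeometry",
           "write_off", "write_vtk"]

#: refuse to build meshes beyond this many vertices (size guard)
MAX_VERTICES = 2_000_000


@dataclass
class TriMesh:
    """Closed, outward-oriented triangulated surface.

    Attributes
    ----------
    vertices : (V, 3) float array
        Current vertex positions, micrometres.
    triangles : (F, 3) int array
        Vertex index triples, ordered so the right-hand normal points
        outward.
    ref_vertices : (V, 3) float array
        Vertex positions in the stress-free reference configuration.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    ref_vertices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.ref_vertices is None:
            self.ref_vertices = self.vertices.copy()
        else:
            self.ref_vertices = np.ascontiguousarray(self.ref_vertices,
                                                     dtype=np.float64)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) index array."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.edges().shape[0] + self.n_faces

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.triangles.copy(),
                       self.ref_vertices.copy())


def _octahedron() -> tuple[np.ndarray, np.ndarray]:
    verts = np.array([[1, 0, 0], [-1, 0, 0],
                      [0, 1, 0], [0, -1, 0],
                      [0, 0, 1], [0, 0, -1]], dtype=np.float64)
    # outward orientation (right-hand rule)
    faces = np.array([[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
                      [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]],
                     dtype=np.int64)
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One 4-to-1 midpoint subdivision; midpoints are shared across faces."""
    edge_mid: dict[tuple[int, int], int] = {}
    vlist = [v for v in verts]

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = edge_mid.get(key)
        if idx is None:
            idx = len(vlist)
            vlist.append(0.5 * (verts[i] + verts[j]))
            edge_mid[key] = idx
        return idx

    new_faces = np.empty((4 * faces.shape[0], 3), dtype=np.int64)
    for k, (a, b, c) in enumerate(faces):
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces[4 * k:4 * k + 4] = [[a, ab, ca], [ab, b, bc],
                                      [ca, bc, c], [ab, bc, ca]]
    return np.array(vlist), new_faces


def make_sphere_mesh(radius: float, level: int,
                     center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0)
                     ) -> TriMesh:
    """Triangulated sphere from recursive octahedron subdivision.

    Parameters
    ----------
    radius : float
        Sphere radius in micrometres; must be positive.
    level : int
        Number of 4-to-1 subdivisions; ``8 * 4**level`` faces and
        ``2 + 4**(level + 1)`` vertices.  Level 5 yields the production
        resolution (8192 faces, 4098 vertices).
    center : 3-sequence
        Sphere centre in micrometres.

    Returns
    -------
    TriMesh with ``ref_vertices`` equal to the generated sphere
    (stress-free reference state).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if level < 0:
        raise ValueError(f"level must be non-negative, got {level}")
    n_verts = 2 + 4 ** (level + 1)
    if n_verts > MAX_VERTICES:
        raise ValueError(
            f"level {level} would create {n_verts} vertices "
            f"(limit {MAX_VERTICES})")

    verts, faces = _octahedron()
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    verts = radius * verts + np.asarray(center, dtype=np.float64)
    return TriMesh(verts, faces)


@dataclass
class MeshGeometry:
    """Per-face and aggregate geometric measures of a closed mesh."""

    face_normals: np.ndarray     # (F, 3) unit outward normals
    face_areas: np.ndarray       # (F,)
    total_area: float
    volume: float                # signed; positive for outward orientation
    vertex_normals: np.ndarray   # (V, 3) area-weighted unit normals


def mesh_geometry(mesh: TriMesh) -> MeshGeometry:
    """Normals, areas, enclosed volume (divergence theorem), vertex normals.

    A negative volume signals an inverted (inward) orientation; the value
    is still returned so callers can diagnose the mesh.
    """
    v, t = mesh.vertices, mesh.triangles
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    cross = np.cross(p1 - p0, p2 - p0)
    areas2 = np.linalg.norm(cross, axis=1)       # 2 * area
    if np.any(areas2 <= 0):
        raise ValueError("degenerate triangle (zero area) in mesh")
    mean_a = areas2.mean()
    if np.any(areas2 < 1e-12 * mean_a):
        raise ValueError("degenerate triangle below area guard")
    normals = cross / areas2[:, None]
    areas = 0.5 * areas2
    # V = (1/3) sum over faces of centroid . (area * normal)
    centroid = (p0 + p1 + p2) / 3.0
    volume = float(np.einsum("ij,ij->", centroid, cross) / 6.0)

    vnorm = np.zeros_like(v)
    np.add.at(vnorm, t[:, 0], cross)
    np.add.at(vnorm, t[:, 1], cross)
    np.add.at(vnorm, t[:, 2], cross)
    lens = np.linalg.norm(vnorm, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    vnorm = vnorm / lens
    return MeshGeometry(normals, areas, float(areas.sum()), volume, vnorm)


def triangle_area(p0, p1, p2) -> float:
    """Area of a single (possibly open-patch) triangle."""
    return 0.5 * float(np.linalg.norm(np.cross(np.asarray(p1) - p0,
                                               np.asarray(p2) - p0)))


# ---------------------------------------------------------------------------
# plain-text mesh export (OFF and legacy-ASCII VTK), positions in micrometres

def write_off(mesh: TriMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for f in mesh.triangles:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_off(path: str) -> TriMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4:4 + 3 * nv], dtype=np.float64).reshape(nv, 3)
    rest = tokens[4 + 3 * nv:]
    faces = []
    i = 0
    for _ in range(nf):
        k = int(rest[i])
        faces.append([int(x) for x in rest[i + 1:i + 1 + k]])
        i += k + 1
    return TriMesh(data, np.array(faces, dtype=np.int64))


def write_vtk(mesh: TriMesh, path: str,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK polydata with optional per-vertex scalar/vector data."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncelltransit membrane mesh\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.triangles:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for x in arr:
                        fh.write(f"{x:.9g}\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for p in arr:
                        fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
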