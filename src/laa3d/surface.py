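"""Surface generation from the blood-pool mask and LAA submesh cropping.

The left-atrial surface is extracted from the binary mask by marching cubes
and the appendage is isolated by a reproducible plane cut (a scriptable
replacement for interactive freehand cropping): triangles crossing the
cutting plane are split exactly along it, and the connected open submesh on
the appendage side is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

from .core import BinaryMask, Plane, TriangleMesh

__all__ = ["CropSpec", "extract_surface", "mesh_volume", "crop_mesh"]

log = logging.getLogger(__name__)

#: points closer than this to a cutting plane are considered on it (mm)
PLANE_TOL = 1e-6

#: symbolic perturbation for vertices exactly on a plane (mm)
ZERO_DIST = 1e-12


def plane_vertex_distances(plane: Plane, vertices: np.ndarray) -> np.ndarray:
    """Signed vertex-plane distances with exact zeros nudged to +ZERO_DIST.

    The deterministic perturbation makes sign tests unambiguous and keeps
    cropping and contour extraction consistent with each other: both see
    the same crossing edges and interpolate the same points.
    """
    d = plane.signed_distance(vertices)
    return np.where(d == 0.0, ZERO_DIST, d)


@dataclass
class CropSpec:
    """Plane cut keeping the side that contains ``keep_seed``."""

    plane: Plane
    keep_seed: np.ndarray

    def __post_init__(self) -> None:
        self.keep_seed = np.asarray(self.keep_seed, dtype=float).reshape(3)
        d = float(self.plane.signed_distance(self.keep_seed)[0])
        if abs(d) <= PLANE_TOL:
            raise ValueError("keep_seed lies on the cutting plane; cannot pick a side")


def extract_surface(mask: BinaryMask, smoothing_iterations: int = 0) -> TriangleMesh:
    """Closed isosurface of a binary mask, in world mm.

    Marching cubes at iso-level 0.5 on the {0, 1} grid, padded by one false
    voxel layer so the surface always closes.  Optional Laplacian smoothing
    (default off, since smoothing biases enclosed volume; the volume change
    is logged when enabled).
    """
    if mask.count == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    # undo the one-voxel pad and move to world coordinates
    verts = verts - mask.spacing + mask.origin
    mesh = TriangleMesh(verts, faces)
    if _signed_volume_mm3(mesh) < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    if smoothing_iterations > 0:
        before = mesh_volume(mesh)
        mesh = _laplacian_smooth(mesh, smoothing_iterations)
        after = mesh_volume(mesh)
        log.info(
            "Laplacian smoothing (%d iterations) changed enclosed volume by %.3f%%",
            smoothing_iterations,
            100.0 * (after - before) / before,
        )
    return mesh


def _laplacian_smooth(mesh: TriangleMesh, iterations: int, factor: float = 0.5) -> TriangleMesh:
    """Uniform-weight Laplacian smoothing; boundary vertices are kept fixed."""
    e = np.sort(mesh.edges(), axis=1)
    e = np.unique(e, axis=0)
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1.0
    boundary = np.unique(mesh.boundary_edges())
    interior = np.setdiff1d(np.arange(n), boundary)
    v = mesh.vertices.copy()
    for _ in range(iterations):
        mean_nb = adj @ v / degree[:, None]
        v[interior] += factor * (mean_nb[interior] - v[interior])
    return TriangleMesh(v, mesh.faces)


def _signed_volume_mm3(mesh: TriangleMesh) -> float:
    a, b, c = mesh.triangle_corners()
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume of a watertight mesh in cm^3 (divergence theorem).

    The signed volumes of the tetrahedra spanned by each triangle and the
    origin are summed; the absolute value is returned, so the result does
    not depend on global orientation.
    """
    if not mesh.is_watertight():
        n_open = len(mesh.boundary_edges())
        raise ValueError(f"mesh is not watertight ({n_open} open edges); cannot compute volume")
    return abs(_signed_volume_mm3(mesh)) / 1000.0


# ---------------------------------------------------------------------------
# plane cutting
# ---------------------------------------------------------------------------

def edge_plane_point(vertices: np.ndarray, i: int, j: int, d: np.ndarray) -> np.ndarray:
    """Intersection of the edge (i, j) with the plane of signed distances ``d``.

    Evaluated with the endpoints in ascending index order so adjacent
    triangles produce bit-identical points (shared with the ostium
    contour computation).
    """
    if i > j:
        i, j = j, i
    di, dj = d[i], d[j]
    t = di / (di - dj)
    return vertices[i] + t * (vertices[j] - vertices[i])


def crop_mesh(mesh: TriangleMesh, spec: CropSpec) -> TriangleMesh:
    """Cut a mesh by a plane and keep the connected part on the seed side.

    Triangles crossing the plane are split along it, so every boundary edge
    of the result lies on the cutting plane (within ``PLANE_TOL``).  Of the
    retained triangles, only the connected submesh containing the vertex
    nearest ``keep_seed`` is returned (open mesh).
    """
    d_raw = plane_vertex_distances(spec.plane, mesh.vertices)
    side = 1.0 if float(spec.plane.signed_distance(spec.keep_seed)[0]) > 0 else -1.0
    keep_v = d_raw * side > 0.0

    n_keep_per_face = keep_v[mesh.faces].sum(axis=1)
    if not np.any(n_keep_per_face < 3):
        raise ValueError("cutting plane does not intersect the mesh")
    if not np.any(n_keep_per_face > 0):
        raise ValueError("no part of the mesh lies on the keep_seed side of the plane")

    new_vertices: list[np.ndarray] = []
    edge_cache: dict[tuple[int, int], int] = {}
    n0 = mesh.n_vertices

    def cut_point(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        cached = edge_cache.get(key)
        if cached is not None:
            return cached
        t = d_raw[key[0]] / (d_raw[key[0]] - d_raw[key[1]])
        if t <= 0.0:
            idx = key[0]
        elif t >= 1.0:
            idx = key[1]
        else:
            new_vertices.append(edge_plane_point(mesh.vertices, key[0], key[1], d_raw))
            idx = n0 + len(new_vertices) - 1
        edge_cache[key] = idx
        return idx

    out_faces: list[tuple[int, int, int]] = []
    for face, nk in zip(mesh.faces, n_keep_per_face):
        if nk == 3:
            out_faces.append(tuple(face))
            continue
        if nk == 0:
            continue
        # Sutherland-Hodgman clip of the triangle against the keep half-space
        poly: list[int] = []
        for c in range(3):
            i, j = int(face[c]), int(face[(c + 1) % 3])
            if keep_v[i]:
                poly.append(i)
            if keep_v[i] != keep_v[j]:
                poly.append(cut_point(i, j))
        # drop consecutive duplicates (cut point snapped onto an endpoint)
        dedup = [p for k, p in enumerate(poly) if p != poly[k - 1]]
        while len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if len(dedup) < 3:
            continue
        for k in range(1, len(dedup) - 1):
            out_faces.append((dedup[0], dedup[k], dedup[k + 1]))

    if not out_faces:
        raise ValueError("no part of the mesh lies on the keep_seed side of the plane")
    all_vertices = np.vstack([mesh.vertices] + new_vertices) if new_vertices else mesh.vertices
    faces_arr = np.asarray(out_faces, dtype=np.int64)

    # connected component containing the vertex nearest keep_seed
    used = np.unique(faces_arr)
    remap = -np.ones(len(all_vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub_faces = remap[faces_arr]
    sub_vertices = all_vertices[used]
    e = np.concatenate([sub_faces[:, [0, 1]], sub_faces[:, [1, 2]], sub_faces[:, [2, 0]]])
    adj = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(sub_vertices), len(sub_vertices))
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        nearest = int(np.argmin(np.linalg.norm(sub_vertices - spec.keep_seed, axis=1)))
        face_keep = np.all(labels[sub_faces] == labels[nearest], axis=1)
        sub_faces = sub_faces[face_keep]
        used2 = np.unique(sub_faces)
        remap2 = -np.ones(len(sub_vertices), dtype=np.int64)
        remap2[used2] = np.arange(len(used2))
        sub_faces = remap2[sub_faces]
        sub_vertices = sub_vertices[used2]
    return TriangleMesh(sub_vertices, sub_faces)
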