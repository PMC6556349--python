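"""Core containers shared across the pipeline.

Conventions
-----------
All world coordinates are scanner/world **millimetres**.  A voxel index
``(i, j, k)`` maps to world space as ``origin + (i, j, k) * spacing``
(voxel-centre convention, 0-based indices).  Meshes, landmarks and planes
live in the same world frame.  Areas and volumes are carried in mm^2 / mm^3
internally and converted to cm^2 / cm^3 only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "PhaseStack",
    "BinaryMask",
    "TriangleMesh",
    "Plane",
    "LandmarkSet",
    "LANDMARK_ROLES",
]

LANDMARK_ROLES = ("ostium_cut", "laa_seed", "la_seed")


@dataclass
class ImageVolume:
    """A 3D scalar grid (CT intensities) with world geometry.

    Parameters
    ----------
    data : (nx, ny, nz) array
        Intensity values (HU-like, arbitrary units).
    spacing : (3,) array
        Voxel edge lengths in mm, all positive.
    origin : (3,) array
        World position (mm) of the centre of voxel (0, 0, 0).
    phase_label : float, optional
        Cardiac phase as a percentage of the RR interval.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    phase_label: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"volume must be >= 2 voxels per axis, got shape {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_index(self, point_mm) -> np.ndarray:
        """Nearest voxel index of a world point (mm)."""
        idx = np.rint((np.asarray(point_mm, dtype=float) - self.origin) / self.spacing)
        return idx.astype(int)

    def index_to_world(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class PhaseStack:
    """Ordered multi-phase series of image volumes across the cardiac cycle."""

    volumes: list[ImageVolume]
    phase_percents: list[float]

    def __post_init__(self) -> None:
        self.phase_percents = [float(p) for p in self.phase_percents]
        if len(self.volumes) != len(self.phase_percents):
            raise ValueError("volumes and phase_percents must have equal length")
        p = np.asarray(self.phase_percents)
        if len(p) and (np.any(p < 0) or np.any(p >= 100)):
            raise ValueError("phase percentages must lie in [0, 100)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("phase percentages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class BinaryMask:
    """Boolean voxel grid sharing the geometry of its source volume."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing components must be positive")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def world_to_index(self, point_mm) -> np.ndarray:
        idx = np.rint((np.asarray(point_mm, dtype=float) - self.origin) / self.spacing)
        return idx.astype(int)


class TriangleMesh:
    """Triangle surface mesh with vertices in world millimetres.

    Faces with repeated vertex indices (fully collapsed triangles) are
    dropped at construction; exactly collinear-but-distinct triangles from
    discrete isosurfaces are kept so that watertightness is preserved.
    """

    def __init__(self, vertices, faces) -> None:
        vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise ValueError("face index out of range")
        # drop index-degenerate faces (zero area by construction)
        if faces.size:
            ok = (
                (faces[:, 0] != faces[:, 1])
                & (faces[:, 1] != faces[:, 2])
                & (faces[:, 2] != faces[:, 0])
            )
            faces = faces[ok]
        self.vertices = vertices
        self.faces = faces

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def area(self) -> float:
        """Total surface area in mm^2."""
        a, b, c = self.triangle_corners()
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)

    def edges(self) -> np.ndarray:
        """All directed edges as (3 * n_faces, 2) index pairs."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def _edge_counts(self) -> tuple[np.ndarray, np.ndarray]:
        e = np.sort(self.edges(), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges used by exactly one face."""
        uniq, counts = self._edge_counts()
        return uniq[counts == 1]

    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        _, counts = self._edge_counts()
        return bool(np.all(counts == 2))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TriangleMesh):
            return NotImplemented
        return (
            self.vertices.shape == other.vertices.shape
            and self.faces.shape == other.faces.shape
            and np.array_equal(self.vertices, other.vertices)
            and np.array_equal(self.faces, other.faces)
        )


@dataclass
class Plane:
    """Oriented plane: a point on the plane and a unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray
    source_landmarks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError("plane normal must be a nonzero finite vector")
        self.normal = n / norm

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane axes (u, v) with u x v = normal."""
        n = self.normal
        e = np.zeros(3)
        e[np.argmin(np.abs(n))] = 1.0
        u = np.cross(n, e)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def project_2d(self, points) -> np.ndarray:
        """Project world points onto the (u, v) in-plane frame."""
        u, v = self.frame()
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        return np.stack([pts @ u, pts @ v], axis=1)


@dataclass
class LandmarkSet:
    """Named world-space points with roles used to replace interactive picking."""

    names: list[str]
    roles: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not (len(self.names) == len(self.roles) == len(self.points)):
            raise ValueError("names, roles and points must have equal length")
        bad = sorted(set(self.roles) - set(LANDMARK_ROLES))
        if bad:
            raise ValueError(
                f"unknown landmark role(s) {bad}; allowed roles are {list(LANDMARK_ROLES)}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def with_role(self, role: str) -> np.ndarray:
        """All points carrying the given role, as an (n, 3) array."""
        if role not in LANDMARK_ROLES:
            raise ValueError(f"unknown role {role!r}; allowed roles are {list(LANDMARK_ROLES)}")
        sel = [i for i, r in enumerate(self.roles) if r == role]
        return self.points[sel]

    def single(self, role: str) -> np.ndarray:
        pts = self.with_role(role)
        if len(pts) != 1:
            raise ValueError(f"expected exactly one {role!r} landmark, found {len(pts)}")
        return pts[0]
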