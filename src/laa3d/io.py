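"""Readers and writers for the formats the pipeline touches.

Supported: NIfTI volumes (.nii / .nii.gz), axis-aligned DICOM series
directories, STL surface meshes (binary and ASCII) and CSV landmark files.

STL files carry no unit metadata; this library reads and writes them in
millimetres throughout.  The STL writer canonicalises meshes so that
``write -> read -> write`` is a byte-level fixed point: facets are emitted in
face order, vertices are stored as float32, and duplicated facet corners are
merged by exact coordinate match on read (first-occurrence order).
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .core import LANDMARK_ROLES, ImageVolume, LandmarkSet, TriangleMesh

__all__ = [
    "read_volume",
    "write_volume",
    "read_stl",
    "write_stl",
    "read_landmarks",
    "write_landmarks",
]

_AXIS_TOL = 1e-4


# ---------------------------------------------------------------------------
# image volumes
# ---------------------------------------------------------------------------

def read_volume(path, format_hint: str | None = None, phase_label: float | None = None) -> ImageVolume:
    """Read a 3D image volume from a NIfTI file or a DICOM series directory.

    The grid must be axis-aligned in world space (no oblique acquisitions);
    non-axis-aligned geometry is rejected rather than resampled.  Intensities
    are returned unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    fmt = format_hint
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "nifti"
    if fmt == "nifti":
        return _read_nifti(path, phase_label)
    if fmt == "dicom":
        return _read_dicom_series(path, phase_label)
    raise ValueError(f"unknown format hint {fmt!r} (expected 'nifti' or 'dicom')")


def _read_nifti(path: Path, phase_label: float | None) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = img.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > _AXIS_TOL:
        raise ValueError(f"non-axis-aligned NIfTI affine in {path}; oblique grids are not supported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError(f"invalid voxel spacing in {path}: {spacing}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got ndim={data.ndim} in {path}")
    origin = affine[:3, 3].copy()
    # fold axis flips into the origin so spacing stays positive
    for ax in range(3):
        if rot[ax, ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + rot[ax, ax] * (data.shape[ax] - 1)
    return ImageVolume(np.ascontiguousarray(data), spacing, origin, phase_label)


def _read_dicom_series(path: Path, phase_label: float | None) -> ImageVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise IOError(f"no readable DICOM slices in {path}")
    first = slices[0]
    iop = np.asarray(getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float)
    if np.max(np.abs(iop - np.array([1, 0, 0, 0, 1, 0]))) > _AXIS_TOL:
        raise ValueError(
            f"DICOM series in {path} is not axis-aligned (ImageOrientationPatient={iop.tolist()}); "
            "oblique series are not supported"
        )
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) < 2:
        raise ValueError(f"DICOM series in {path} has fewer than 2 slices")
    steps = np.diff(zs)
    if np.any(steps <= 0) or np.max(np.abs(steps - steps[0])) > 1e-3:
        raise ValueError(f"inconsistent slice spacing in DICOM series {path}: steps {steps}")
    ps = np.asarray(first.PixelSpacing, dtype=float)  # (row spacing, col spacing)
    spacing = np.array([ps[1], ps[0], steps[0]])
    arrays = []
    for ds in slices:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(a * slope + intercept)
    if len({a.shape for a in arrays}) != 1:
        raise ValueError(f"inconsistent slice dimensions in DICOM series {path}")
    # pixel_array is (rows, cols); index order here is (i=x/col, j=y/row, k=z)
    data = np.ascontiguousarray(np.stack(arrays, axis=-1).transpose(1, 0, 2))
    origin = np.asarray(first.ImagePositionPatient, dtype=float)
    return ImageVolume(data, spacing, origin, phase_label)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from spacing/origin."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))


# ---------------------------------------------------------------------------
# STL meshes
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path, binary: bool = True) -> None:
    """Write a mesh as STL (binary by default, ASCII on request).

    Refuses empty meshes.  Facet normals are recomputed from the float32
    vertex coordinates so that re-writing a just-read file reproduces it
    byte for byte.
    """
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh to STL")
    v32 = mesh.vertices.astype(np.float32)
    tri = v32[mesh.faces]  # (n, 3, 3)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]).astype(np.float32)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n = (n / norms).astype(np.float32)
    path = Path(path)
    if binary:
        rec = np.zeros(
            len(tri),
            dtype=[("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        )
        rec["normal"] = n
        rec["v"] = tri
        header = b"laa3d binary STL (units: mm)".ljust(80, b" ")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tri)))
            fh.write(rec.tobytes())
    else:
        lines = ["solid laa3d"]
        for fi in range(len(tri)):
            nx, ny, nz = (float(x) for x in n[fi])
            lines.append(f"  facet normal {nx:.9e} {ny:.9e} {nz:.9e}")
            lines.append("    outer loop")
            for c in range(3):
                x, y, z = (float(x) for x in tri[fi, c])
                lines.append(f"      vertex {x:.9e} {y:.9e} {z:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid laa3d")
        path.write_text("\n".join(lines) + "\n")


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a canonical indexed mesh.

    Duplicated facet corners are merged by exact coordinate match, keeping
    first-occurrence order so that the representation is a fixed point of
    write -> read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such STL file: {path}")
    raw = path.read_bytes()
    if len(raw) < 15:
        raise ValueError(f"{path} is not an STL file (too short)")
    if _looks_ascii_stl(raw):
        corners = _parse_ascii_stl(raw, path)
    else:
        corners = _parse_binary_stl(raw, path)
    # merge exactly-equal corners, preserving first occurrence order
    flat = corners.reshape(-1, 3)
    view = flat.view([("x", flat.dtype), ("y", flat.dtype), ("z", flat.dtype)]).ravel()
    _, first_idx, inverse = np.unique(view, return_index=True, return_inverse=True)
    order = np.argsort(first_idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = flat[np.sort(first_idx)]
    faces = rank[inverse].reshape(-1, 3)
    return TriangleMesh(vertices.astype(np.float64), faces)


def _looks_ascii_stl(raw: bytes) -> bool:
    head = raw[:512].lstrip()
    if not head.lower().startswith(b"solid"):
        return False
    return b"facet" in raw[:4096].lower() or raw.strip().lower().endswith(b"endsolid") or (
        b"endsolid" in raw.lower()
    )


def _parse_binary_stl(raw: bytes, path: Path) -> np.ndarray:
    if len(raw) < 84:
        raise ValueError(f"{path} is not a valid binary STL (truncated header)")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) != expected:
        raise ValueError(
            f"{path} is not a valid binary STL: {count} facets imply {expected} bytes, file has {len(raw)}"
        )
    rec = np.frombuffer(raw, dtype=[("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")], offset=84)
    return np.asarray(rec["v"], dtype=np.float32)


def _parse_ascii_stl(raw: bytes, path: Path) -> np.ndarray:
    coords: list[list[float]] = []
    for line in raw.decode("ascii", errors="replace").splitlines():
        parts = line.split()
        if len(parts) == 4 and parts[0].lower() == "vertex":
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ValueError(f"malformed vertex line in ASCII STL {path}: {line!r}") from exc
    if not coords or len(coords) % 3 != 0:
        raise ValueError(f"{path} is not a valid ASCII STL ({len(coords)} vertex lines)")
    return np.asarray(coords, dtype=np.float32).reshape(-1, 3, 3)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read a CSV landmark table with columns name, role, x, y, z (mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    df = pd.read_csv(path)
    required = ["name", "role", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} is missing column(s) {missing}; expected {required}")
    roles = [str(r).strip() for r in df["role"]]
    bad = sorted(set(roles) - set(LANDMARK_ROLES))
    if bad:
        raise ValueError(
            f"unknown landmark role(s) {bad} in {path}; allowed roles are {list(LANDMARK_ROLES)}"
        )
    points = df[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSet([str(n) for n in df["name"]], roles, points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    df = pd.DataFrame(
        {
            "name": landmarks.names,
            "role": landmarks.roles,
            "x": landmarks.points[:, 0],
            "y": landmarks.points[:, 1],
            "z": landmarks.points[:, 2],
        }
    )
    df.to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
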