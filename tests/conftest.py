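"""Shared fixtures: analytic solids, digitized masks and the phantom run."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from laa3d.core import BinaryMask, TriangleMesh
from laa3d.phantom import PhantomSpec, make_dynamic_series
from laa3d.pipeline import run_phases

CT_SPACING = np.array([0.419, 0.419, 1.0])


def digitize_sphere(radius: float, spacing, margin: float = 3.0, center=(0.0, 0.0, 0.0)) -> BinaryMask:
    """Binary mask of a sphere sampled at voxel centres."""
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center, dtype=float)
    n = np.ceil(2 * (radius + margin) / spacing).astype(int)
    origin = center - (n - 1) / 2.0 * spacing
    ax = [origin[k] + np.arange(n[k]) * spacing[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2
    return BinaryMask(inside, spacing, origin)


def icosphere(radius: float, subdivisions: int = 4, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(tm.vertices + np.asarray(center), tm.faces)


def cube_mesh(side: float = 10.0, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    tm = trimesh.creation.box(extents=(side, side, side))
    return TriangleMesh(tm.vertices + np.asarray(center), tm.faces)


@pytest.fixture(scope="session")
def sphere15_mask() -> BinaryMask:
    return digitize_sphere(15.0, CT_SPACING)


@pytest.fixture(scope="session")
def phantom_run():
    """Default 10-phase dynamic phantom and the full pipeline result."""
    spec = PhantomSpec(seed=1)
    stack, truth = make_dynamic_series(spec)
    report = run_phases(stack, truth.landmarks)
    return spec, stack, truth, report
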