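"""Ostium plane fitting, contour extraction, capping, voxelization, Simpson."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from laa3d.core import Plane, TriangleMesh
from laa3d.morphometry import (
    ContourStack,
    OstiumContour,
    close_surface,
    contour_area,
    fit_plane,
    intersect_mesh_plane,
    simpson_volume,
    voxelize_volume,
)
from laa3d.surface import CropSpec, crop_mesh, extract_surface, mesh_volume

from .conftest import CT_SPACING, cube_mesh, digitize_sphere, icosphere

SPHERE_15_CM3 = 4.0 / 3.0 * np.pi * 15.0**3 / 1000.0


# ---------------------------------------------------------------------------
# fit_plane
# ---------------------------------------------------------------------------

def test_fit_plane_three_points_exact():
    plane = fit_plane([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
    assert np.allclose(np.abs(plane.normal), [0, 0, 1])
    assert np.allclose(plane.signed_distance([[0.3, 0.4, 0.0]]), 0.0, atol=1e-12)


def test_fit_plane_four_coplanar_points_zero_residual():
    pts = np.array([[3, 0, 0], [0, 3, 0], [0, 0, 3], [1, 1, 1]], dtype=float)
    plane = fit_plane(pts)
    assert np.allclose(np.abs(plane.normal), np.ones(3) / np.sqrt(3))
    assert np.max(np.abs(plane.signed_distance(pts))) < 1e-12


def test_fit_plane_noisy_points_matches_svd_oracle():
    rng = np.random.default_rng(2)
    n_true = np.array([0.3, -0.5, 0.81])
    n_true /= np.linalg.norm(n_true)
    u = np.cross(n_true, [0, 0, 1.0])
    u /= np.linalg.norm(u)
    v = np.cross(n_true, u)
    ab = rng.uniform(-10, 10, size=(20, 2))
    pts = ab[:, :1] * u + ab[:, 1:] * v + rng.normal(0, 0.1, size=(20, 1)) * n_true
    plane = fit_plane(pts)
    # within 2 degrees of the generating normal
    cosang = abs(plane.normal @ n_true)
    assert np.degrees(np.arccos(min(cosang, 1.0))) < 2.0
    # matches an explicit SVD oracle
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    assert abs(plane.normal @ vt[2]) > 1.0 - 1e-12


def test_fit_plane_collinear_points_rejected():
    with pytest.raises(ValueError, match="collinear"):
        fit_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
    with pytest.raises(ValueError, match="collinear"):
        fit_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]])


def test_fit_plane_normal_points_away_from_far_side():
    mesh = icosphere(5.0, subdivisions=2, center=(0, 0, 20.0))
    plane = fit_plane([[1, 0, 0], [0, 1, 0], [0, 0, 0]], mesh=mesh)
    assert plane.normal[2] == pytest.approx(-1.0)  # mesh sits above; normal away


# ---------------------------------------------------------------------------
# intersect_mesh_plane
# ---------------------------------------------------------------------------

def test_intersection_of_offcentre_sphere_cut_is_circle():
    r, off = 10.0, 6.0
    mesh = icosphere(r, subdivisions=4)
    contour = intersect_mesh_plane(mesh, Plane([0, 0, off], [0, 0, 1]))
    expected_r = np.sqrt(r**2 - off**2)
    radii = np.linalg.norm(contour.points[:, :2], axis=1)
    assert np.max(np.abs(radii - expected_r)) / expected_r < 0.005
    assert contour_area(contour) == pytest.approx(np.pi * expected_r**2 / 100.0, rel=0.01)


def test_intersection_loop_selection_largest_then_anchor():
    big = icosphere(10.0, subdivisions=3, center=(0, 0, 0))
    small = icosphere(4.0, subdivisions=3, center=(30.0, 0, 0))
    both = TriangleMesh(
        np.vstack([big.vertices, small.vertices]),
        np.vstack([big.faces, small.faces + big.n_vertices]),
    )
    plane = Plane([0, 0, 0], [0, 0, 1])
    default = intersect_mesh_plane(both, plane)
    assert np.linalg.norm(default.points.mean(axis=0)) < 1.0  # big sphere's loop
    near_small = intersect_mesh_plane(both, plane, anchor=[30.0, 0, 0])
    assert np.linalg.norm(near_small.points.mean(axis=0) - [30.0, 0, 0]) < 1.0


def test_intersection_counterclockwise_about_normal():
    mesh = icosphere(10.0, subdivisions=3)
    plane = Plane([0, 0, 0], [0, 0, 1])
    contour = intersect_mesh_plane(mesh, plane)
    p2 = plane.project_2d(contour.points)
    x, y = p2[:, 0], p2[:, 1]
    signed = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) / 2.0
    assert signed > 0


def test_intersection_open_chain_rejected():
    hemi = crop_mesh(icosphere(10.0, 3), CropSpec(Plane([0, 0, 0], [0, 0, 1]), [0, 0, 5]))
    with pytest.raises(ValueError, match="not closed across plane"):
        intersect_mesh_plane(hemi, Plane([0, 0, 5.0], [1, 0, 0]))


def test_intersection_plane_missing_mesh_rejected():
    with pytest.raises(ValueError, match="does not intersect"):
        intersect_mesh_plane(icosphere(5.0, 2), Plane([0, 0, 20.0], [0, 0, 1]))


def test_contour_area_is_rigid_motion_invariant():
    mesh = icosphere(10.0, subdivisions=3)
    plane = Plane([0, 0, 4.0], [0, 0, 1])
    a0 = contour_area(intersect_mesh_plane(mesh, plane))
    rot = Rotation.from_euler("xyz", [31.0, -12.0, 57.0], degrees=True)
    shift = np.array([13.0, -7.0, 5.0])
    m2 = TriangleMesh(rot.apply(mesh.vertices) + shift, mesh.faces)
    p2 = Plane(rot.apply(plane.point) + shift, rot.apply(plane.normal))
    a1 = contour_area(intersect_mesh_plane(m2, p2))
    assert abs(a1 - a0) / a0 < 1e-9


# ---------------------------------------------------------------------------
# contour_area closed forms
# ---------------------------------------------------------------------------

def _planar_contour(points_2d, plane=None):
    plane = plane or Plane([0, 0, 0], [0, 0, 1])
    u, v = plane.frame()
    pts = plane.point + points_2d[:, :1] * u + points_2d[:, 1:] * v
    return OstiumContour(pts, plane)


def test_contour_area_square_exact():
    sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
    assert contour_area(_planar_contour(sq)) == pytest.approx(1.000, abs=1e-12)


def test_contour_area_regular_polygon_approaches_circle():
    th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    poly = 10.0 * np.stack([np.cos(th), np.sin(th)], axis=1)
    assert contour_area(_planar_contour(poly)) == pytest.approx(np.pi, rel=1e-4)


def test_contour_area_ellipse():
    a, b = 15.0, 8.0
    th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    poly = np.stack([a * np.cos(th), b * np.sin(th)], axis=1)
    assert contour_area(_planar_contour(poly)) == pytest.approx(np.pi * a * b / 100.0, rel=1e-3)


def test_contour_rejects_self_intersection_and_short_input():
    bow = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
    with pytest.raises(ValueError, match="self-intersecting"):
        _planar_contour(bow)
    with pytest.raises(ValueError, match="at least 3"):
        _planar_contour(np.array([[0, 0], [1, 0]], dtype=float))


# ---------------------------------------------------------------------------
# close_surface
# ---------------------------------------------------------------------------

def test_close_hemisphere_recovers_half_sphere_volume():
    r = 10.0
    mesh = icosphere(r, subdivisions=4)
    plane = Plane([0, 0, 0], [0, 0, 1])
    hemi = crop_mesh(mesh, CropSpec(plane, [0, 0, 5.0]))
    contour = intersect_mesh_plane(mesh, plane)
    model = close_surface(hemi, contour)
    assert model.cap_method == "fan"
    assert mesh_volume(model.mesh) == pytest.approx(0.5 * 4 / 3 * np.pi * r**3 / 1000, rel=0.01)
    # cap area equals the contour area
    cap = model.mesh.faces[model.cap_faces]
    a, b, c = (model.mesh.vertices[cap[:, k]] for k in range(3))
    cap_area = np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0 / 100.0
    assert cap_area == pytest.approx(contour_area(contour), rel=1e-6)


def _horseshoe_mesh():
    """Closed digitized solid with a U-shaped (non-star-shaped) cross-section.

    The area centroid of the U lies in the notch gap, so a fan cap from the
    centroid would self-intersect and ear clipping must be used.
    """
    from laa3d.core import BinaryMask

    h = 0.75
    n = int(np.ceil(34.0 / h))
    ax = np.arange(n) * h - 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    outer = (X >= 0) & (X <= 30) & (Y >= 0) & (Y <= 30) & (Z >= 0) & (Z <= 12)
    notch = (X >= 8) & (X <= 22) & (Y >= 10)
    return extract_surface(BinaryMask(outer & ~notch, (h, h, h), (-2.0, -2.0, -2.0)))


def test_close_nonconvex_contour_uses_ear_clipping():
    mesh = _horseshoe_mesh()
    assert mesh.is_watertight()
    plane = Plane([0, 0, 6.1], [0, 0, 1])
    upper = crop_mesh(mesh, CropSpec(plane, [15.0, 5.0, 10.0]))
    contour = intersect_mesh_plane(mesh, plane)
    model = close_surface(upper, contour)
    assert model.cap_method == "ear_clip"
    assert model.mesh.is_watertight()
    v_vox, _ = voxelize_volume(model, (0.5, 0.5, 0.5))
    assert v_vox == pytest.approx(mesh_volume(model.mesh), rel=0.03)


def test_close_surface_rejects_mismatched_contour():
    mesh = icosphere(10.0, subdivisions=3)
    plane = Plane([0, 0, 0], [0, 0, 1])
    hemi = crop_mesh(mesh, CropSpec(plane, [0, 0, 5.0]))
    other = intersect_mesh_plane(mesh, Plane([0, 0, 1.0], [0, 0, 1]))
    with pytest.raises(ValueError):
        close_surface(hemi, other)


def test_close_surface_rejects_multiple_boundary_loops():
    mesh = icosphere(10.0, subdivisions=3)
    band = crop_mesh(mesh, CropSpec(Plane([0, 0, 5.0], [0, 0, 1]), [0, 0, -5.0]))
    band = crop_mesh(band, CropSpec(Plane([0, 0, -5.0], [0, 0, 1]), [0, 0, 0.0]))
    contour = intersect_mesh_plane(mesh, Plane([0, 0, 5.0], [0, 0, 1]))
    with pytest.raises(ValueError, match="boundary loop"):
        close_surface(band, contour)


# ---------------------------------------------------------------------------
# voxelize_volume
# ---------------------------------------------------------------------------

def test_voxelize_cube_exact_voxel_count():
    cube = cube_mesh(10.0)
    volume, mask = voxelize_volume(cube, (1.0, 1.0, 1.0))
    assert mask.count == 1000
    assert volume == pytest.approx(1.000, abs=1e-12)


def test_voxelize_icosphere_at_ct_resolution(sphere15_mask):
    mesh = icosphere(15.0, subdivisions=4)
    v_vox, _ = voxelize_volume(mesh, CT_SPACING)
    assert v_vox == pytest.approx(SPHERE_15_CM3, rel=0.015)
    assert v_vox == pytest.approx(mesh_volume(mesh), rel=0.02)


def test_voxelize_richardson_convergence_on_sphere():
    mesh = icosphere(12.0, subdivisions=4)
    ref = mesh_volume(mesh)
    err = []
    for s in (2.0, 1.0, 0.5):
        v, _ = voxelize_volume(mesh, (s, s, s))
        err.append(abs(v - ref))
    assert err[2] < err[0]
    assert err[2] / ref < 0.005


def test_voxelize_warns_at_degenerate_resolution():
    mesh = icosphere(5.0, subdivisions=2)
    with pytest.warns(UserWarning, match="interior voxels"):
        v, _ = voxelize_volume(mesh, (10.0, 10.0, 10.0))
    assert v >= 0.0


def test_voxelize_open_mesh_rejected():
    mesh = cube_mesh(10.0)
    broken = TriangleMesh(mesh.vertices, mesh.faces[:-1])
    with pytest.raises(ValueError, match="watertight"):
        voxelize_volume(broken, (1.0, 1.0, 1.0))


def test_voxelize_agrees_with_trimesh_oracle():
    mesh = _horseshoe_mesh()
    v_vox, _ = voxelize_volume(mesh, (0.5, 0.5, 0.5))
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    assert v_vox == pytest.approx(abs(tm.volume) / 1000.0, rel=0.02)


# ---------------------------------------------------------------------------
# Simpson's rule
# ---------------------------------------------------------------------------

def test_simpson_single_slab():
    assert simpson_volume(ContourStack([1.0], 10.0)) == pytest.approx(1.0, abs=1e-12)


def test_simpson_zero_areas():
    assert simpson_volume(ContourStack([0.0, 0.0, 0.0], 1.0)) == 0.0


def test_simpson_negative_area_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        ContourStack([1.0, -0.1], 1.0)


def _sphere_slice_stack(r: float, thickness: float) -> ContourStack:
    z = np.arange(-r + thickness / 2.0, r, thickness)
    areas_cm2 = np.pi * (r**2 - z**2) / 100.0
    return ContourStack(areas_cm2, thickness)


def test_simpson_sphere_within_1pct_and_converges():
    r = 15.0
    true = 4 / 3 * np.pi * r**3 / 1000.0
    assert simpson_volume(_sphere_slice_stack(r, 1.0)) == pytest.approx(true, rel=0.01)
    errs = [abs(simpson_volume(_sphere_slice_stack(r, t)) - true) for t in (2.0, 1.0, 0.5, 0.25)]
    assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))


def test_simpson_approaches_mesh_volume_of_convex_solid():
    mesh = icosphere(9.0, subdivisions=4)
    ref = mesh_volume(mesh)
    vol = simpson_volume(_sphere_slice_stack(9.0, 0.1))
    assert vol == pytest.approx(ref, rel=0.005)
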