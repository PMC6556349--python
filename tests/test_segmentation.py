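"""Threshold selection, masking, component selection and voxel volumetry."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laa3d.core import BinaryMask, ImageVolume
from laa3d.segmentation import (
    apply_threshold,
    auto_threshold,
    mask_voxel_volume,
    select_component,
)

from .conftest import CT_SPACING, digitize_sphere

UNIT = (1.0, 1.0, 1.0)
ZERO = (0.0, 0.0, 0.0)


def brute_force_otsu(data: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over all histogram cut points maximising the
    between-class variance (independent of the library implementation)."""
    hist, edges = np.histogram(data.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_var = centers[0], -1.0
    n = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum() / n
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / hist[:k].sum()
        mu1 = (hist[k:] * centers[k:]).sum() / hist[k:].sum()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[k - 1]
    return float(best_t)


def test_auto_threshold_separates_two_level_phantom():
    data = np.zeros((10, 10, 10))
    data[3:7, 3:7, 3:7] = 300.0
    t = auto_threshold(ImageVolume(data, UNIT, ZERO))
    assert 0.0 < t < 300.0


def test_auto_threshold_matches_brute_force_on_bimodal_volume():
    rng = np.random.default_rng(11)
    data = np.concatenate(
        [rng.normal(50, 20, size=6000), rng.normal(300, 20, size=4000)]
    ).reshape(20, 25, 20)
    vol = ImageVolume(data, UNIT, ZERO)
    t = auto_threshold(vol)
    oracle = brute_force_otsu(data)
    # the between-class variance is nearly flat across the gap between the
    # modes, so implementations may settle on nearby cut points of the plateau
    assert abs(t - oracle) <= 30.0
    # any plateau point separates the two modes (3 sigma from either mean)
    assert 50.0 + 3 * 20.0 < t < 300.0 - 3 * 20.0


def test_auto_threshold_constant_volume_raises():
    with pytest.raises(ValueError, match="no contrast"):
        auto_threshold(ImageVolume(np.full((4, 4, 4), 7.0), UNIT, ZERO))


def test_apply_threshold_extremes_and_override():
    data = np.arange(64, dtype=float).reshape(4, 4, 4)
    vol = ImageVolume(data, UNIT, ZERO)
    assert apply_threshold(vol, data.min()).count == 64  # >= is inclusive
    assert apply_threshold(vol, data.max() + 1).count == 0
    assert apply_threshold(vol, 0.0, override=32.0).count == 32


def test_apply_threshold_recovers_phantom_blood_pool_exactly():
    # noiseless two-level volume: midpoint threshold recovers the indicator
    inside = digitize_sphere(8.0, UNIT).data
    data = np.where(inside, 300.0, 50.0)
    vol = ImageVolume(data, UNIT, ZERO)
    mask = apply_threshold(vol, 175.0)
    assert mask.count == int(inside.sum())


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    t1=st.floats(-1, 1),
    t2=st.floats(-1, 1),
    seed=st.integers(0, 2**16),
)
def test_apply_threshold_is_monotone(t1, t2, seed):
    """Raising the threshold never adds voxels."""
    rng = np.random.default_rng(seed)
    vol = ImageVolume(rng.normal(size=(5, 5, 5)), UNIT, ZERO)
    lo, hi = min(t1, t2), max(t1, t2)
    m_lo = apply_threshold(vol, lo).data
    m_hi = apply_threshold(vol, hi).data
    assert np.all(m_hi <= m_lo)


def _bfs_component(data: np.ndarray, start) -> int:
    """Independent 26-connected flood fill (breadth-first search)."""
    seen = np.zeros_like(data, dtype=bool)
    q = deque([tuple(start)])
    seen[tuple(start)] = True
    count = 0
    shape = data.shape
    while q:
        i, j, k = q.popleft()
        count += 1
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                        if data[ni, nj, nk] and not seen[ni, nj, nk]:
                            seen[ni, nj, nk] = True
                            q.append((ni, nj, nk))
    return count


def test_select_component_keeps_only_seeded_sphere():
    a = digitize_sphere(5.0, UNIT, margin=2.0, center=(0, 0, 0)).data
    b = digitize_sphere(3.0, UNIT, margin=2.0, center=(0, 0, 0)).data
    grid = np.zeros((40, 20, 20), dtype=bool)
    grid[: a.shape[0], : a.shape[1], : a.shape[2]] |= a
    grid[24 : 24 + b.shape[0], : b.shape[1], : b.shape[2]] |= b
    mask = BinaryMask(grid, UNIT, ZERO)
    kept = select_component(mask, (7.0, 7.0, 7.0))  # inside sphere A
    assert kept.count == int(a.sum())
    assert not kept.data[24:, :, :].any()


def test_select_component_matches_bfs_flood_fill():
    rng = np.random.default_rng(5)
    grid = rng.random((12, 12, 12)) > 0.65
    grid[6, 6, 6] = True
    mask = BinaryMask(grid, UNIT, ZERO)
    kept = select_component(mask, (6.0, 6.0, 6.0))
    assert kept.count == _bfs_component(grid, (6, 6, 6))
    assert np.all(kept.data <= grid)  # subset of the input


def test_select_component_background_seed_raises():
    grid = np.zeros((5, 5, 5), dtype=bool)
    grid[0, 0, 0] = True
    with pytest.raises(ValueError, match="seed outside"):
        select_component(BinaryMask(grid, UNIT, ZERO), (2.0, 2.0, 2.0))
    with pytest.raises(ValueError, match="bounds"):
        select_component(BinaryMask(grid, UNIT, ZERO), (50.0, 0.0, 0.0))


def test_mask_voxel_volume_closed_forms():
    full = BinaryMask(np.ones((10, 10, 10), bool), UNIT, ZERO)
    assert mask_voxel_volume(full) == pytest.approx(1.000, abs=1e-12)
    single = np.zeros((2, 2, 2), bool)
    single[0, 0, 0] = True
    one = BinaryMask(single, CT_SPACING, ZERO)
    assert mask_voxel_volume(one) == pytest.approx(0.419 * 0.419 * 1.0 / 1000.0, rel=1e-12)


def test_mask_voxel_volume_digitized_sphere_within_1pct():
    mask = digitize_sphere(15.0, CT_SPACING)
    true = 4.0 / 3.0 * np.pi * 15.0**3 / 1000.0
    assert mask_voxel_volume(mask) == pytest.approx(true, rel=0.01)


def test_mask_voxel_volume_additive_over_disjoint_masks():
    rng = np.random.default_rng(9)
    a = rng.random((8, 8, 8)) > 0.5
    b = (rng.random((8, 8, 8)) > 0.5) & ~a
    va = mask_voxel_volume(BinaryMask(a, CT_SPACING, ZERO))
    vb = mask_voxel_volume(BinaryMask(b, CT_SPACING, ZERO))
    vab = mask_voxel_volume(BinaryMask(a | b, CT_SPACING, ZERO))
    assert vab == pytest.approx(va + vb, rel=1e-12)


def test_mask_voxel_volume_empty_mask_raises():
    with pytest.raises(ValueError, match="empty"):
        mask_voxel_volume(BinaryMask(np.zeros((3, 3, 3), bool), UNIT, ZERO))
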