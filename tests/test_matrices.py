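"""Texture-matrix builders against brute-force oracles and invariants."""

import numpy as np
import pytest

from conftest import make_quantized, random_quantized
from oracles import (
    oracle_glcm,
    oracle_gldm,
    oracle_glrlm,
    oracle_glszm,
    oracle_ngtdm,
)
from petromics.features.matrices import (
    DIRECTIONS_3D,
    glcm,
    gldm,
    glrlm,
    glszm,
    ngtdm,
)

N_RANDOM_CASES = 100


def test_direction_set_is_half_of_26_neighborhood():
    assert len(DIRECTIONS_3D) == 13
    as_set = set(DIRECTIONS_3D)
    for d in as_set:
        assert tuple(-x for x in d) not in as_set


# ---------------------------------------------------------------------------
# hand-worked examples
# ---------------------------------------------------------------------------

def test_glcm_2x2_example_before_symmetrization():
    # levels [[1,1],[1,2]], direction (0,+1): raw pairs (1,1) and (1,2);
    # the builder symmetrizes, so counts double up mirrored
    q = make_quantized(np.array([[1, 1], [1, 2]]), n_levels=2)
    mat = glcm(q, directions=((0, 1, 0),))[0]
    np.testing.assert_array_equal(mat, [[2, 1], [1, 0]])


def test_glcm_constant_roi_single_cell():
    q = make_quantized(np.ones((3, 3), dtype=int), n_levels=2)
    mats = glcm(q)
    total = mats.sum(axis=0)
    assert total[0, 0] > 0
    assert total.sum() == total[0, 0]


def test_glrlm_line_example():
    # 1-D levels [1,1,1,2,2] along the row direction
    q = make_quantized(np.array([[1, 1, 1, 2, 2]]), n_levels=2)
    mat = glrlm(q, directions=((0, 1, 0),))[0]
    assert mat[0, 2] == 1  # one run of level 1, length 3
    assert mat[1, 1] == 1  # one run of level 2, length 2
    assert mat.sum() == 2


def test_glszm_plateau_example():
    # two zones of level 1 (sizes 4 and 2), one zone of level 2 (size 3)
    grid = np.array(
        [
            [1, 1, 2, 0, 1],
            [1, 1, 2, 0, 1],
            [0, 0, 2, 0, 0],
        ]
    )
    q = make_quantized(grid, mask=grid > 0, n_levels=2)
    mat = glszm(q)
    assert mat[0, 3] == 1  # level 1, size 4
    assert mat[0, 1] == 1  # level 1, size 2
    assert mat[1, 2] == 1  # level 2, size 3


def test_gldm_checkerboard_all_mass_at_one():
    grid = np.indices((4, 4)).sum(axis=0) % 2 + 1
    q = make_quantized(grid, n_levels=2)
    hist = gldm(q, directions=((0, 1, 0), (1, 0, 0)))
    assert hist[0] == 0
    assert hist[1] > 0
    assert hist[2:].sum() == 0


def test_ngtdm_flat_roi_zero_deviation():
    q = make_quantized(np.ones((4, 4), dtype=int), n_levels=2)
    s, counts, n = ngtdm(q)
    assert n == 16
    np.testing.assert_allclose(s, 0.0)


def test_ngtdm_single_bright_voxel_hand_computed():
    grid = np.ones((3, 3), dtype=int)
    grid[1, 1] = 2
    q = make_quantized(grid, n_levels=2)
    s, counts, n = ngtdm(q)
    # center: |2 - 1| = 1. corners: neighbors are 2 ones + center 2 -> mean 4/3
    # edges: 4 ones + center 2 -> mean 6/5
    expected_s1 = 4 * abs(1 - 4 / 3) + 4 * abs(1 - 6 / 5)
    assert n == 9
    np.testing.assert_allclose(s[0], expected_s1, atol=1e-12)
    np.testing.assert_allclose(s[1], 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# oracle equality on random ROIs (the core correctness battery)
# ---------------------------------------------------------------------------

def _random_cases(seed: int, n_cases: int):
    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        shape = (
            int(rng.integers(3, 13)),
            int(rng.integers(3, 13)),
            int(rng.integers(1, 7)),
        )
        yield random_quantized(rng, shape=shape, n_levels=int(rng.integers(2, 7)))


def test_glcm_matches_pair_scan_oracle():
    for q in _random_cases(1, N_RANDOM_CASES):
        mats = glcm(q)
        for k, d in enumerate(DIRECTIONS_3D):
            expected = oracle_glcm(q.levels, q.mask, d, q.n_levels)
            np.testing.assert_array_equal(mats[k], expected)


def test_gldm_matches_pair_scan_oracle():
    for q in _random_cases(2, N_RANDOM_CASES):
        hist = gldm(q)
        expected = oracle_gldm(q.levels, q.mask, DIRECTIONS_3D, q.n_levels)
        np.testing.assert_array_equal(hist, expected)


def test_glrlm_matches_run_walk_oracle():
    for q in _random_cases(3, N_RANDOM_CASES):
        mats = glrlm(q)
        for k, d in enumerate(DIRECTIONS_3D):
            expected = oracle_glrlm(q.levels, q.mask, d, q.n_levels)
            np.testing.assert_array_equal(mats[k][:, : expected.shape[1]], expected)


def test_glszm_matches_flood_fill_oracle():
    for q in _random_cases(4, N_RANDOM_CASES):
        mat = glszm(q)
        expected = oracle_glszm(q.levels, q.mask, q.n_levels)
        np.testing.assert_array_equal(mat, expected)


def test_ngtdm_matches_neighbor_average_oracle():
    for q in _random_cases(5, N_RANDOM_CASES):
        s, counts, n = ngtdm(q)
        es, ec, en = oracle_ngtdm(q.levels, q.mask, q.n_levels)
        assert n == en
        np.testing.assert_array_equal(counts, ec)
        np.testing.assert_allclose(s, es, atol=1e-9)


def test_glcm_agrees_with_skimage_in_2d():
    """Independent library cross-check on a single-slice ROI."""
    graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
    rng = np.random.default_rng(6)
    img = rng.integers(1, 5, size=(9, 9))
    q = make_quantized(img, n_levels=4)
    ours = glcm(q, directions=((0, 1, 0),))[0]
    ref = graycomatrix(
        (img - 1).astype(np.uint8), distances=[1], angles=[0], levels=4, symmetric=True
    )[:, :, 0, 0]
    np.testing.assert_array_equal(ours, ref)


# ---------------------------------------------------------------------------
# conservation invariants
# ---------------------------------------------------------------------------

def test_glrlm_runs_partition_voxels():
    """sum_ij j * p(i,j|direction) equals the in-mask voxel count."""
    for q in _random_cases(7, N_RANDOM_CASES):
        mats = glrlm(q)
        j = np.arange(1, mats.shape[2] + 1)
        for k in range(mats.shape[0]):
            assert (mats[k] * j[None, :]).sum() == q.n_voxels


def test_glszm_zones_partition_voxels():
    for q in _random_cases(8, N_RANDOM_CASES):
        mat = glszm(q)
        s = np.arange(1, mat.shape[1] + 1)
        assert (mat * s[None, :]).sum() == q.n_voxels


def test_glcm_symmetry():
    for q in _random_cases(9, 20):
        for mat in glcm(q):
            np.testing.assert_array_equal(mat, mat.T)
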