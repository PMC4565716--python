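"""Scalar texture features: hand-worked cases, transcription oracle, invariants."""

import numpy as np
import pytest

from conftest import make_quantized, random_quantized
from oracles import oracle_glcm_scalar_features
from petromics.features.matrices import TextureMatrixSet, glcm, gldm, glrlm, glszm, ngtdm
from petromics.features.texture import (
    NGTDM_EPSILON,
    glcm_features,
    glcm_features_single,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)


def test_constant_roi_glcm_point_mass():
    q = make_quantized(np.ones((4, 4), dtype=int), n_levels=3)
    f = glcm_features(glcm(q))
    assert f["glcm_energy"] == pytest.approx(1.0)
    assert f["glcm_contrast"] == pytest.approx(0.0)
    assert f["glcm_entropy"] == pytest.approx(0.0)
    assert f["glcm_correlation"] == 0.0  # degenerate marginal -> defined as 0


def test_checkerboard_contrast_is_one():
    grid = np.indices((6, 6)).sum(axis=0) % 2 + 1
    q = make_quantized(grid, n_levels=2)
    f = glcm_features(glcm(q, directions=((0, 1, 0),)))
    assert f["glcm_contrast"] == pytest.approx(1.0)
    assert f["glcm_dissimilarity"] == pytest.approx(1.0)


def test_glcm_features_match_transcription_oracle(rng):
    for _ in range(25):
        q = random_quantized(rng, shape=(7, 6, 2), n_levels=5)
        mats = glcm(q)
        for mat in mats:
            if mat.sum() == 0:
                continue
            p = mat / mat.sum()
            ours = glcm_features_single(p)
            ref = oracle_glcm_scalar_features(p)
            for name, val in ref.items():
                assert ours[name] == pytest.approx(val, abs=1e-9), name


def test_gldm_constant_and_checkerboard():
    q = make_quantized(np.ones((4, 4), dtype=int), n_levels=2)
    f = gldm_features(gldm(q))
    assert f["gldm_mean"] == 0 and f["gldm_variance"] == 0 and f["gldm_entropy"] == 0
    grid = np.indices((6, 6)).sum(axis=0) % 2 + 1
    q2 = make_quantized(grid, n_levels=2)
    f2 = gldm_features(gldm(q2, directions=((0, 1, 0), (1, 0, 0))))
    assert f2["gldm_mean"] == pytest.approx(1.0)
    assert f2["gldm_contrast"] == pytest.approx(1.0)


def test_glrlm_run_percentage_line():
    q = make_quantized(np.array([[1, 1, 1, 2, 2]]), n_levels=2)
    f = glrlm_features(glrlm(q, directions=((0, 1, 0),)), n_voxels=5)
    assert f["glrlm_run_percentage"] == pytest.approx(2 / 5)


def test_long_run_emphasis_maximal_for_single_run():
    """A constant line is one maximal run; any relabelling that splits it
    can only lower long-run emphasis."""
    n = 9
    const = make_quantized(np.ones((1, n), dtype=int), n_levels=2)
    f_const = glrlm_features(glrlm(const, directions=((0, 1, 0),)), n_voxels=n)
    rng = np.random.default_rng(0)
    for _ in range(20):
        grid = rng.integers(1, 3, size=(1, n))
        f = glrlm_features(glrlm(make_quantized(grid, n_levels=2), directions=((0, 1, 0),)), n_voxels=n)
        assert f["glrlm_long_run_emphasis"] <= f_const["glrlm_long_run_emphasis"] + 1e-12


def test_glszm_constant_roi_zone_percentage():
    q = make_quantized(np.ones((3, 4), dtype=int), n_levels=2)
    f = glszm_features(glszm(q), n_voxels=12)
    assert f["glszm_zone_percentage"] == pytest.approx(1 / 12)
    assert f["glszm_large_zone_emphasis"] == pytest.approx(144.0)


def test_ngtdm_flat_roi_coarseness_capped():
    q = make_quantized(np.ones((4, 4), dtype=int), n_levels=2)
    s, counts, n = ngtdm(q)
    f = ngtdm_features(s, counts, n)
    assert f["ngtdm_coarseness"] == pytest.approx(1.0 / NGTDM_EPSILON)
    assert f["ngtdm_contrast"] == 0.0


def test_ngtdm_features_match_literal_formulas(rng):
    """Transcribe the five neighborhood-difference formulas longhand."""
    for _ in range(25):
        q = random_quantized(rng, shape=(6, 6, 2), n_levels=4)
        s, counts, n = ngtdm(q)
        f = ngtdm_features(s, counts, n)
        p = counts / n
        present = [i for i in range(q.n_levels) if p[i] > 0]
        ngp = len(present)
        pis = float(sum(p[i] * s[i] for i in present))
        assert f["ngtdm_coarseness"] == pytest.approx(1.0 / (NGTDM_EPSILON + pis))
        if ngp > 1:
            con = sum(
                p[i] * p[j] * ((i - j) ** 2)
                for i in present
                for j in present
            ) / (ngp * (ngp - 1)) * sum(s[i] for i in present) / n
            assert f["ngtdm_contrast"] == pytest.approx(con, rel=1e-9)
            busy_den = sum(
                abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
            )
            if busy_den > 1e-12:
                assert f["ngtdm_busyness"] == pytest.approx(pis / busy_den, rel=1e-9)


def test_direction_average_excludes_empty_directions():
    # single row: vertical-ish directions have no pairs and must not drag
    # the direction-averaged features toward zero
    q = make_quantized(np.array([[1, 2, 1, 2]]), n_levels=2)
    f = glcm_features(glcm(q))
    assert f["glcm_contrast"] == pytest.approx(1.0)


def test_normalized_matrices_sum_to_one(rng):
    for _ in range(30):
        q = random_quantized(rng, shape=(6, 5, 3), n_levels=4)
        for mat in glcm(q):
            if mat.sum():
                assert (mat / mat.sum()).sum() == pytest.approx(1.0, abs=1e-9)
        hist = gldm(q)
        assert (hist / hist.sum()).sum() == pytest.approx(1.0, abs=1e-9)
        _, counts, n = ngtdm(q)
        assert (counts / n).sum() == pytest.approx(1.0, abs=1e-9)


def test_inplane_rotation_invariance_of_direction_averaged_features(rng):
    """A 90-degree in-plane rotation permutes the 13-direction set (up to
    sign, which symmetrization absorbs), leaving averaged features intact."""
    from petromics.features.texture import texture_matrix_features

    for _ in range(5):
        q = random_quantized(rng, shape=(7, 7, 3), n_levels=4)
        rot_levels = np.rot90(q.levels, axes=(0, 1)).copy()
        rot_mask = np.rot90(q.mask, axes=(0, 1)).copy()
        q_rot = make_quantized(rot_levels, rot_mask, q.n_levels)
        f = texture_matrix_features(TextureMatrixSet.build(q))
        f_rot = texture_matrix_features(TextureMatrixSet.build(q_rot))
        for name in f:
            assert f[name] == pytest.approx(f_rot[name], rel=1e-9, abs=1e-9), name
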