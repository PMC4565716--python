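"""Scalar texture features from the gray-level matrices.

Directional matrices (GLCM, GLRLM) are reduced by computing each feature
per direction and averaging over directions that received at least one
valid pair/run. Degenerate inputs (single-level ROIs) use defined
fallbacks — correlation-type quantities are 0 when a marginal variance
vanishes — so the descriptor is always finite. Logarithms are base 2 with
0·log0 = 0.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrixSet

_EPS = 1e-12


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2(p).sum())


# ---------------------------------------------------------------------------
# GLCM — 20 Haralick-family features
# ---------------------------------------------------------------------------

def glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 20 co-occurrence features of one normalized symmetric GLCM."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, ng + 1)[None, :].astype(float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i[:, 0] * px).sum())
    mu_y = float((j[0, :] * py).sum())
    sd_x = float(np.sqrt(((i[:, 0] - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((j[0, :] - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    kdiff = np.arange(ng)
    p_diff = np.zeros(ng)
    idx_sum = (i + j - 2).astype(int)
    idx_diff = np.abs(i - j).astype(int)
    np.add.at(p_sum, idx_sum.ravel(), p.ravel())
    np.add.at(p_diff, idx_diff.ravel(), p.ravel())

    contrast = float(((i - j) ** 2 * p).sum())
    dissim = float((np.abs(i - j) * p).sum())
    entropy = _entropy(p)
    hx, hy = _entropy(px), _entropy(py)
    pxpy = px[:, None] * py[None, :]
    hxy1 = float(-(p * np.where(pxpy > 0, np.log2(np.maximum(pxpy, _EPS)), 0.0)).sum())
    hxy2 = _entropy(pxpy)
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    if sd_x * sd_y > _EPS:
        correlation = float((((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y))
    else:
        correlation = 0.0

    sum_avg = float((ksum * p_sum).sum())
    diff_avg = float((kdiff * p_diff).sum())
    return {
        "energy": float((p**2).sum()),
        "autocorrelation": float((i * j * p).sum()),
        "cluster_prominence": float(((i + j - mu_x - mu_y) ** 4 * p).sum()),
        "cluster_shade": float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
        "contrast": contrast,
        "correlation": correlation,
        "difference_entropy": _entropy(p_diff),
        "difference_variance": float(((kdiff - diff_avg) ** 2 * p_diff).sum()),
        "dissimilarity": dissim,
        "entropy": entropy,
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "inverse_difference_moment": float((p / (1.0 + (i - j) ** 2)).sum()),
        "imc1": imc1,
        "imc2": imc2,
        "sum_average": sum_avg,
        "sum_entropy": _entropy(p_sum),
        "sum_variance": float(((ksum - sum_avg) ** 2 * p_sum).sum()),
        "idmn": float((p / (1.0 + (i - j) ** 2 / ng**2)).sum()),
        "idn": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "max_probability": float(p.max()),
    }


def glcm_features(glcm_stack: np.ndarray) -> dict[str, float]:
    """Direction-averaged co-occurrence features from raw count matrices."""
    feats: list[dict[str, float]] = []
    for mat in glcm_stack:
        total = mat.sum()
        if total == 0:
            continue  # no valid pairs in this direction: excluded from the average
        feats.append(glcm_features_single(mat / total))
    if not feats:
        raise ValueError("no GLCM direction produced a valid pair")
    return {f"glcm_{k}": float(np.mean([f[k] for f in feats])) for k in feats[0]}


# ---------------------------------------------------------------------------
# GLDM — 4 difference-histogram features
# ---------------------------------------------------------------------------

def gldm_features(hist: np.ndarray) -> dict[str, float]:
    total = hist.sum()
    if total == 0:
        raise ValueError("empty gray-level difference histogram")
    p = hist / total
    d = np.arange(len(p)).astype(float)
    mean = float((d * p).sum())
    return {
        "gldm_mean": mean,
        "gldm_entropy": _entropy(p),
        "gldm_variance": float(((d - mean) ** 2 * p).sum()),
        "gldm_contrast": float((d**2 * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM — 13 run-length features
# ---------------------------------------------------------------------------

def _rlm_features_single(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = mat.sum()
    p = mat.astype(float)
    ng, nl = p.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, nl + 1)[None, :].astype(float)
    pg = p.sum(axis=1)  # per gray level
    pr = p.sum(axis=0)  # per run length
    mu_i = float((np.arange(1, ng + 1) * pg).sum()) / nr
    mu_j = float((np.arange(1, nl + 1) * pr).sum()) / nr
    return {
        "short_run_emphasis": float((p / j**2).sum()) / nr,
        "long_run_emphasis": float((p * j**2).sum()) / nr,
        "low_gray_level_run_emphasis": float((p / i**2).sum()) / nr,
        "high_gray_level_run_emphasis": float((p * i**2).sum()) / nr,
        "short_run_low_gray_level_emphasis": float((p / (i**2 * j**2)).sum()) / nr,
        "short_run_high_gray_level_emphasis": float((p * i**2 / j**2).sum()) / nr,
        "long_run_low_gray_level_emphasis": float((p * j**2 / i**2).sum()) / nr,
        "long_run_high_gray_level_emphasis": float((p * i**2 * j**2).sum()) / nr,
        "gray_level_nonuniformity": float((pg**2).sum()) / nr,
        "run_length_nonuniformity": float((pr**2).sum()) / nr,
        "run_percentage": nr / n_voxels,
        "gray_level_variance": float(((np.arange(1, ng + 1) - mu_i) ** 2 * pg).sum()) / nr,
        "run_length_variance": float(((np.arange(1, nl + 1) - mu_j) ** 2 * pr).sum()) / nr,
    }


def glrlm_features(rlm_stack: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Direction-averaged run-length features."""
    feats = [
        _rlm_features_single(mat, n_voxels) for mat in rlm_stack if mat.sum() > 0
    ]
    if not feats:
        raise ValueError("no GLRLM direction produced a run")
    return {f"glrlm_{k}": float(np.mean([f[k] for f in feats])) for k in feats[0]}


# ---------------------------------------------------------------------------
# GLSZM — 13 size-zone features (direction-free)
# ---------------------------------------------------------------------------

def glszm_features(szm: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = szm.sum()
    if nz == 0:
        raise ValueError("empty size-zone matrix")
    p = szm.astype(float)
    ng, ns = p.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    s = np.arange(1, ns + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    pz = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * pg).sum()) / nz
    mu_s = float((np.arange(1, ns + 1) * pz).sum()) / nz
    return {
        "glszm_small_zone_emphasis": float((p / s**2).sum()) / nz,
        "glszm_large_zone_emphasis": float((p * s**2).sum()) / nz,
        "glszm_low_gray_level_zone_emphasis": float((p / i**2).sum()) / nz,
        "glszm_high_gray_level_zone_emphasis": float((p * i**2).sum()) / nz,
        "glszm_small_zone_low_gray_emphasis": float((p / (i**2 * s**2)).sum()) / nz,
        "glszm_small_zone_high_gray_emphasis": float((p * i**2 / s**2).sum()) / nz,
        "glszm_large_zone_low_gray_emphasis": float((p * s**2 / i**2).sum()) / nz,
        "glszm_large_zone_high_gray_emphasis": float((p * i**2 * s**2).sum()) / nz,
        "glszm_gray_level_nonuniformity": float((pg**2).sum()) / nz,
        "glszm_size_zone_nonuniformity": float((pz**2).sum()) / nz,
        "glszm_zone_percentage": float(nz) / n_voxels,
        "glszm_gray_level_variance": float(
            ((np.arange(1, ng + 1) - mu_i) ** 2 * pg).sum()
        )
        / nz,
        "glszm_zone_size_variance": float(
            ((np.arange(1, ns + 1) - mu_s) ** 2 * pz).sum()
        )
        / nz,
    }


# ---------------------------------------------------------------------------
# NGTDM — the 5 Amadasun–King features
# ---------------------------------------------------------------------------

#: floor inside the coarseness reciprocal; a perfectly flat ROI otherwise
#: divides by zero. Coarseness is capped at 1/epsilon and flagged upstream.
NGTDM_EPSILON = 1e-12


def ngtdm_features(
    s: np.ndarray, counts: np.ndarray, n_valid: int
) -> dict[str, float]:
    if n_valid == 0:
        raise ValueError("no voxel had a valid neighborhood")
    p = counts / n_valid
    present = np.flatnonzero(p > 0)
    ngp = len(present)
    levels = (present + 1).astype(float)
    pi = p[present]
    si = s[present]

    coarseness = 1.0 / (NGTDM_EPSILON + float((pi * si).sum()))
    if ngp > 1:
        diff2 = (levels[:, None] - levels[None, :]) ** 2
        contrast = (
            float((pi[:, None] * pi[None, :] * diff2).sum())
            / (ngp * (ngp - 1))
            * float(si.sum())
            / n_valid
        )
        busy_denom = float(
            np.abs(
                levels[:, None] * pi[:, None] - levels[None, :] * pi[None, :]
            ).sum()
        )
        busyness = float((pi * si).sum()) / busy_denom if busy_denom > _EPS else 0.0
        pisi = pi * si
        complexity = (
            float(
                (
                    np.abs(levels[:, None] - levels[None, :])
                    * (pisi[:, None] + pisi[None, :])
                    / (pi[:, None] + pi[None, :])
                ).sum()
            )
            / n_valid
        )
        strength = float(
            ((pi[:, None] + pi[None, :]) * diff2).sum()
        ) / (NGTDM_EPSILON + float(si.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def texture_matrix_features(mats: TextureMatrixSet) -> dict[str, float]:
    """All 55 matrix-based texture features of one ROI."""
    out: dict[str, float] = {}
    out.update(glcm_features(mats.glcm))
    out.update(glrlm_features(mats.glrlm, mats.n_voxels))
    out.update(glszm_features(mats.glszm, mats.n_voxels))
    out.update(gldm_features(mats.gldm))
    out.update(ngtdm_features(mats.ngtdm_s, mats.ngtdm_counts, mats.ngtdm_n))
    return out
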