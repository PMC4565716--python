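"""Independent brute-force oracles for the texture-matrix builders.

Everything here is written as plain voxel-by-voxel Python loops (or BFS
flood fill), deliberately sharing no code with the package's vectorized
implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def oracle_glcm(levels, mask, direction, n_levels, distance=1):
    """Symmetrized co-occurrence counts by exhaustive pair enumeration."""
    out = np.zeros((n_levels, n_levels), dtype=np.int64)
    dr, dc, dz = (distance * k for k in direction)
    R, C, Z = levels.shape
    for r in range(R):
        for c in range(C):
            for z in range(Z):
                if not mask[r, c, z]:
                    continue
                r2, c2, z2 = r + dr, c + dc, z + dz
                if 0 <= r2 < R and 0 <= c2 < C and 0 <= z2 < Z and mask[r2, c2, z2]:
                    i, j = levels[r, c, z], levels[r2, c2, z2]
                    out[i - 1, j - 1] += 1
                    out[j - 1, i - 1] += 1
    return out


def oracle_gldm(levels, mask, directions, n_levels, distance=1):
    """Pooled absolute-difference histogram by exhaustive pair enumeration."""
    hist = np.zeros(n_levels, dtype=np.int64)
    R, C, Z = levels.shape
    for direction in directions:
        dr, dc, dz = (distance * k for k in direction)
        for r in range(R):
            for c in range(C):
                for z in range(Z):
                    if not mask[r, c, z]:
                        continue
                    r2, c2, z2 = r + dr, c + dc, z + dz
                    if 0 <= r2 < R and 0 <= c2 < C and 0 <= z2 < Z and mask[r2, c2, z2]:
                        hist[abs(int(levels[r, c, z]) - int(levels[r2, c2, z2]))] += 1
    return hist


def oracle_glrlm(levels, mask, direction, n_levels):
    """Run-length counts by walking every maximal run along the direction."""
    R, C, Z = levels.shape
    max_len = max(R, C, Z)
    out = np.zeros((n_levels, max_len), dtype=np.int64)
    dr, dc, dz = direction

    def inside(r, c, z):
        return 0 <= r < R and 0 <= c < C and 0 <= z < Z

    for r in range(R):
        for c in range(C):
            for z in range(Z):
                if not mask[r, c, z]:
                    continue
                pr, pc, pz = r - dr, c - dc, z - dz
                # only start a run if the previous voxel does not continue it
                if (
                    inside(pr, pc, pz)
                    and mask[pr, pc, pz]
                    and levels[pr, pc, pz] == levels[r, c, z]
                ):
                    continue
                length = 1
                nr, nc, nz = r + dr, c + dc, z + dz
                while (
                    inside(nr, nc, nz)
                    and mask[nr, nc, nz]
                    and levels[nr, nc, nz] == levels[r, c, z]
                ):
                    length += 1
                    nr, nc, nz = nr + dr, nc + dc, nz + dz
                out[levels[r, c, z] - 1, length - 1] += 1
    return out


def oracle_glszm(levels, mask, n_levels, connectivity=26):
    """Size-zone counts via BFS flood fill over iso-level components."""
    R, C, Z = levels.shape
    if connectivity == 26:
        neigh = [
            (a, b, c)
            for a in (-1, 0, 1)
            for b in (-1, 0, 1)
            for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(mask, dtype=bool)
    n_vox = int(mask.sum())
    out = np.zeros((n_levels, n_vox), dtype=np.int64)
    for r in range(R):
        for c in range(C):
            for z in range(Z):
                if not mask[r, c, z] or seen[r, c, z]:
                    continue
                lv = levels[r, c, z]
                size = 0
                queue = deque([(r, c, z)])
                seen[r, c, z] = True
                while queue:
                    cr, cc, cz = queue.popleft()
                    size += 1
                    for a, b, d in neigh:
                        nr, nc, nz = cr + a, cc + b, cz + d
                        if (
                            0 <= nr < R
                            and 0 <= nc < C
                            and 0 <= nz < Z
                            and mask[nr, nc, nz]
                            and not seen[nr, nc, nz]
                            and levels[nr, nc, nz] == lv
                        ):
                            seen[nr, nc, nz] = True
                            queue.append((nr, nc, nz))
                out[lv - 1, size - 1] += 1
    return out


def oracle_ngtdm(levels, mask, n_levels):
    """Per-level summed neighbor-average deviations by direct looping."""
    R, C, Z = levels.shape
    s = np.zeros(n_levels)
    counts = np.zeros(n_levels, dtype=np.int64)
    for r in range(R):
        for c in range(C):
            for z in range(Z):
                if not mask[r, c, z]:
                    continue
                neigh_vals = []
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        for d in (-1, 0, 1):
                            if (a, b, d) == (0, 0, 0):
                                continue
                            nr, nc, nz = r + a, c + b, z + d
                            if (
                                0 <= nr < R
                                and 0 <= nc < C
                                and 0 <= nz < Z
                                and mask[nr, nc, nz]
                            ):
                                neigh_vals.append(float(levels[nr, nc, nz]))
                if not neigh_vals:
                    continue
                lv = levels[r, c, z]
                s[lv - 1] += abs(lv - sum(neigh_vals) / len(neigh_vals))
                counts[lv - 1] += 1
    return s, counts, int(counts.sum())


def oracle_glcm_scalar_features(p: np.ndarray) -> dict[str, float]:
    """Literal loop transcription of the co-occurrence feature formulas."""
    ng = p.shape[0]
    idx = range(1, ng + 1)
    px = [sum(p[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1, j - 1] for i in idx) for j in idx]
    mu_x = sum(i * px[i - 1] for i in idx)
    mu_y = sum(j * py[j - 1] for j in idx)
    sd_x = sum((i - mu_x) ** 2 * px[i - 1] for i in idx) ** 0.5
    sd_y = sum((j - mu_y) ** 2 * py[j - 1] for j in idx) ** 0.5

    def log2(v):
        return np.log2(v) if v > 0 else 0.0

    energy = sum(p[i - 1, j - 1] ** 2 for i in idx for j in idx)
    contrast = sum((i - j) ** 2 * p[i - 1, j - 1] for i in idx for j in idx)
    entropy = -sum(
        p[i - 1, j - 1] * log2(p[i - 1, j - 1]) for i in idx for j in idx
    )
    corr = 0.0
    if sd_x > 1e-12 and sd_y > 1e-12:
        corr = (
            sum(
                (i - mu_x) * (j - mu_y) * p[i - 1, j - 1] for i in idx for j in idx
            )
            / (sd_x * sd_y)
        )
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in idx:
        for j in idx:
            p_sum[i + j] += p[i - 1, j - 1]
            p_diff[abs(i - j)] += p[i - 1, j - 1]
    sum_avg = sum(k * v for k, v in p_sum.items())
    diff_avg = sum(k * v for k, v in p_diff.items())
    return {
        "energy": energy,
        "autocorrelation": sum(i * j * p[i - 1, j - 1] for i in idx for j in idx),
        "cluster_prominence": sum(
            (i + j - mu_x - mu_y) ** 4 * p[i - 1, j - 1] for i in idx for j in idx
        ),
        "cluster_shade": sum(
            (i + j - mu_x - mu_y) ** 3 * p[i - 1, j - 1] for i in idx for j in idx
        ),
        "contrast": contrast,
        "correlation": corr,
        "difference_entropy": -sum(v * log2(v) for v in p_diff.values()),
        "difference_variance": sum(
            (k - diff_avg) ** 2 * v for k, v in p_diff.items()
        ),
        "dissimilarity": sum(
            abs(i - j) * p[i - 1, j - 1] for i in idx for j in idx
        ),
        "entropy": entropy,
        "homogeneity": sum(
            p[i - 1, j - 1] / (1 + abs(i - j)) for i in idx for j in idx
        ),
        "inverse_difference_moment": sum(
            p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx
        ),
        "sum_average": sum_avg,
        "sum_entropy": -sum(v * log2(v) for v in p_sum.values()),
        "sum_variance": sum((k - sum_avg) ** 2 * v for k, v in p_sum.items()),
        "idmn": sum(
            p[i - 1, j - 1] / (1 + (i - j) ** 2 / ng**2) for i in idx for j in idx
        ),
        "idn": sum(
            p[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in idx for j in idx
        ),
        "max_probability": float(p.max()),
    }


def oracle_conv2d_valid(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray):
    """Multi-channel 'valid' cross-correlation by explicit quadruple loops.

    x: (C, H, W); kernels: (J, C, kh, kw); returns (J, Ho, Wo).
    """
    c_in, h, w = x.shape
    j_out, _, kh, kw = kernels.shape
    ho, wo = h - kh + 1, w - kw + 1
    out = np.zeros((j_out, ho, wo))
    for j in range(j_out):
        for a in range(ho):
            for b in range(wo):
                acc = 0.0
                for c in range(c_in):
                    for u in range(kh):
                        for v in range(kw):
                            acc += float(x[c, a + u, b + v]) * float(
                                kernels[j, c, u, v]
                            )
                out[j, a, b] = acc + float(bias[j])
    return out


def oracle_maxpool2x2(x: np.ndarray) -> np.ndarray:
    """2x2 non-overlapping max pool of a (C, H, W) array, flooring odd dims."""
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    out = np.zeros((c, h2, w2))
    for ch in range(c):
        for a in range(h2):
            for b in range(w2):
                out[ch, a, b] = max(
                    x[ch, 2 * a, 2 * b],
                    x[ch, 2 * a, 2 * b + 1],
                    x[ch, 2 * a + 1, 2 * b],
                    x[ch, 2 * a + 1, 2 * b + 1],
                )
    return out
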