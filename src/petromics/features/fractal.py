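"""Fractal descriptors of the uptake surface.

Each axial slice is treated as an intensity surface z = I(r, c). A
per-voxel fractal dimension (FD) is estimated by differential box-counting
inside a moving window centred on the voxel: the window is partitioned
into r x r blocks for box sizes r = 2..window, each block contributes
``floor(span / h_r) + 1`` boxes where ``h_r = r * range / window`` is the
box height matched to the box footprint, and FD is the slope of
``log N(r)`` against ``log(1/r)``. A flat window occupies one box per
block at every scale, giving FD = 2 (a smooth surface); fully rough
windows approach 3.

The FD map's mean and standard deviation summarize roughness; the Hurst
exponent comes from rescaled-range (R/S) analysis of the in-mask intensity
sequence; lacunarity from mask-aware gliding-box mass statistics,
``var/mean^2 + 1`` (1 for homogeneous uptake).
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..core import TumorROI


def _box_counts_window(win: np.ndarray, r: int) -> np.ndarray:
    """Differential box count N(r) for every window in a (..., w, w) stack.

    Only blocks fully inside the window are measured; their mean box count
    is scaled to the ideal (w/r)^2 grid so that a flat window yields
    exactly (w/r)^2 boxes at every scale (slope 2, a smooth surface).
    """
    w = win.shape[-1]
    rng_all = win.reshape(*win.shape[:-2], -1)
    span_glob = rng_all.max(axis=-1) - rng_all.min(axis=-1)
    h = r * np.maximum(span_glob, 1e-12) / w  # box height matched to footprint
    edges = list(range(0, w - r + 1, r))
    n = np.zeros(win.shape[:-2])
    for r0 in edges:
        for c0 in edges:
            block = win[..., r0 : r0 + r, c0 : c0 + r]
            flat = block.reshape(*block.shape[:-2], -1)
            span = flat.max(axis=-1) - flat.min(axis=-1)
            n += np.floor(span / h) + 1.0
    return n / len(edges) ** 2 * (w / r) ** 2


def fd_map(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel fractal dimension of a 2-D intensity surface."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    half = window // 2
    padded = np.pad(image.astype(float), half, mode="edge")
    win = sliding_window_view(padded, (window, window))
    # r = window is excluded (a single block carrying no grid information)
    # unless the window is too small to leave two scales otherwise
    hi = window if window < 4 else window - 1
    sizes = np.arange(2, hi + 1)
    logs = np.log(1.0 / sizes)
    counts = np.stack([np.log(_box_counts_window(win, int(r))) for r in sizes], axis=-1)
    # least-squares slope of log N(r) on log(1/r), per pixel
    x = logs - logs.mean()
    denom = float((x**2).sum())
    slope = (counts * x).sum(axis=-1) / denom - counts.mean(axis=-1) * x.sum() / denom
    return slope


def hurst_exponent(series: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst exponent of a 1-D sequence.

    The series is split into non-overlapping chunks at several scales; for
    each chunk, R = range of the cumulative mean-adjusted sum and S = its
    standard deviation; H is the slope of log(R/S) on log(chunk length).
    Degenerate (constant or too short) input returns 0.5, the
    uncorrelated-noise value.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 16 or np.ptp(x) == 0:
        return 0.5
    sizes = np.unique(np.floor(np.logspace(np.log10(8), np.log10(n // 2), 8)).astype(int))
    log_rs, log_n = [], []
    for size in sizes:
        n_chunks = n // size
        chunks = x[: n_chunks * size].reshape(n_chunks, size)
        mean = chunks.mean(axis=1, keepdims=True)
        dev = np.cumsum(chunks - mean, axis=1)
        r = dev.max(axis=1) - dev.min(axis=1)
        s = chunks.std(axis=1)
        ok = s > 1e-12
        if ok.sum() == 0:
            continue
        rs = (r[ok] / s[ok]).mean()
        if rs > 0:
            log_rs.append(np.log(rs))
            log_n.append(np.log(size))
    if len(log_rs) < 2:
        return 0.5
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(slope)


def lacunarity(values: np.ndarray, mask: np.ndarray, box: int = 3) -> float:
    """Mask-aware gliding-box lacunarity, ``var(mass)/mean(mass)^2 + 1``.

    Box mass is the mean uptake over in-mask voxels inside each ``box``-cubed
    gliding window (windows without in-mask voxels are skipped), so a
    constant ROI has zero mass variance and lacunarity exactly 1.
    """
    from scipy import ndimage

    size = (box, box, min(box, values.shape[2]))
    vsum = ndimage.uniform_filter(
        np.where(mask, values, 0.0), size=size, mode="constant"
    )
    csum = ndimage.uniform_filter(mask.astype(float), size=size, mode="constant")
    centers = mask & (csum > 1e-9)
    masses = vsum[centers] / csum[centers]
    mean = masses.mean()
    if mean <= 1e-12:
        return 1.0
    return float(masses.var() / mean**2 + 1.0)


def fractal_features(roi: TumorROI, window: int = 5) -> dict[str, float]:
    """The four fractal descriptors: FD mean/SD, Hurst exponent, lacunarity."""
    values, mask = roi.stack()
    if min(values.shape[0], values.shape[1]) < window:
        warnings.warn(
            "ROI smaller than the fractal window; computed on the zero-padded crop",
            stacklevel=2,
        )
        pr = max(0, window - values.shape[0])
        pc = max(0, window - values.shape[1])
        values = np.pad(values, ((0, pr), (0, pc), (0, 0)))
        mask = np.pad(mask, ((0, pr), (0, pc), (0, 0)))
    fds = []
    for j in range(values.shape[2]):
        m = mask[:, :, j]
        if not m.any():
            continue
        fmap = fd_map(np.where(m, values[:, :, j], 0.0), window=window)
        fds.append(fmap[m])
    fd_all = np.concatenate(fds)
    series = np.concatenate(
        [values[:, :, j][mask[:, :, j]] for j in range(values.shape[2])]
    )
    return {
        "fractal_fd_mean": float(fd_all.mean()),
        "fractal_fd_std": float(fd_all.std()),
        "fractal_hurst": hurst_exponent(series),
        "fractal_lacunarity": lacunarity(values, mask),
    }
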