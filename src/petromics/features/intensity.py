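"""First-order intensity statistics and SUV summaries.

Both families operate on the in-mask SUVs only. The catalog pins 26
first-order statistics and 18 SUV summaries; several SUV summaries
(mean, min, max) intentionally duplicate first-order statistics under
their clinical names — the descriptor mirrors the clinical reporting
convention rather than de-duplicating.

Conventions: population (1/N) variance everywhere; entropy uses a 64-bin
equal-width histogram of the in-mask SUVs, base-2 logs; skewness and
kurtosis (Fisher, i.e. normal = 0) are defined as 0 on zero-variance
input.
"""

from __future__ import annotations

import numpy as np

from ..core import TumorROI

_ENTROPY_BINS = 64


def _hist_entropy(v: np.ndarray, bins: int = _ENTROPY_BINS) -> float:
    if np.ptp(v) == 0:
        return 0.0
    counts, _ = np.histogram(v, bins=bins)
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def first_order_features(roi: TumorROI) -> dict[str, float]:
    """The 26 catalog first-order statistics of the in-mask SUVs."""
    v = roi.masked_values()
    n = v.size
    mean = float(v.mean())
    var = float(v.var())  # population convention
    std = float(np.sqrt(var))
    vmin, vmax = float(v.min()), float(v.max())
    p5, p10, p25, p75, p90, p95 = (
        float(np.percentile(v, q)) for q in (5, 10, 25, 75, 90, 95)
    )
    if std > 1e-12:
        z = (v - mean) / std
        skew = float((z**3).mean())
        kurt = float((z**4).mean() - 3.0)
        cv = std / mean if mean > 1e-12 else 0.0
    else:
        skew = kurt = cv = 0.0
    # mode: densest bin midpoint of a 64-bin histogram (continuous data)
    if vmax > vmin:
        counts, edges = np.histogram(v, bins=_ENTROPY_BINS)
        k = int(np.argmax(counts))
        mode = float(0.5 * (edges[k] + edges[k + 1]))
    else:
        mode = vmin
    sorted_v = np.sort(v)
    trim = int(np.floor(0.1 * n))
    trimmed = sorted_v[trim : n - trim] if n - 2 * trim > 0 else sorted_v
    # uniformity: sum of squared histogram probabilities
    if vmax > vmin:
        hc, _ = np.histogram(v, bins=_ENTROPY_BINS)
        uniformity = float(((hc / n) ** 2).sum())
    else:
        uniformity = 1.0
    return {
        "fo_mean": mean,
        "fo_median": float(np.median(v)),
        "fo_mode": mode,
        "fo_minimum": vmin,
        "fo_maximum": vmax,
        "fo_p5": p5,
        "fo_p10": p10,
        "fo_p25": p25,
        "fo_p75": p75,
        "fo_p90": p90,
        "fo_p95": p95,
        "fo_range": vmax - vmin,
        "fo_iqr": p75 - p25,
        "fo_variance": var,
        "fo_std": std,
        "fo_cv": cv,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": float((v**2).sum()),
        "fo_entropy": _hist_entropy(v),
        "fo_rms": float(np.sqrt((v**2).mean())),
        "fo_mean_abs_deviation": float(np.abs(v - mean).mean()),
        "fo_median_abs_deviation": float(np.median(np.abs(v - np.median(v)))),
        "fo_uniformity": uniformity,
        "fo_trimmed_mean_10": float(trimmed.mean()),
        "fo_midrange": 0.5 * (vmin + vmax),
    }


def _suv_peak(roi: TumorROI) -> float:
    """Mean SUV in a 1 cm^3 sphere centred on the hottest in-mask voxel."""
    values, mask = roi.stack()
    flat = np.where(mask, values, -np.inf)
    idx = np.unravel_index(int(np.argmax(flat)), flat.shape)
    radius_mm = (3.0 / (4.0 * np.pi) * 1000.0) ** (1.0 / 3.0)  # sphere of 1 cm^3
    sr, sc, sz = roi.spacing
    rr, cc, zz = np.meshgrid(
        (np.arange(values.shape[0]) - idx[0]) * sr,
        (np.arange(values.shape[1]) - idx[1]) * sc,
        (np.arange(values.shape[2]) - idx[2]) * sz,
        indexing="ij",
    )
    ball = (rr**2 + cc**2 + zz**2) <= radius_mm**2
    sel = ball & mask
    return float(values[sel].mean())


def suv_features(roi: TumorROI) -> dict[str, float]:
    """The 18 catalog SUV summaries, including MTV and TLG.

    Metabolic tumor volume (MTV) is the ROI volume in cm^3; total lesion
    glycolysis (TLG) = SUVmean x MTV.
    """
    v = roi.masked_values()
    mean = float(v.mean())
    vmin, vmax = float(v.min()), float(v.max())
    p5, p10, p25, p75, p90, p95 = (
        float(np.percentile(v, q)) for q in (5, 10, 25, 75, 90, 95)
    )
    mtv_cc = v.size * roi.voxel_volume_mm3 / 1000.0
    return {
        "suv_max": vmax,
        "suv_min": vmin,
        "suv_mean": mean,
        "suv_median": float(np.median(v)),
        "suv_std": float(v.std()),
        "suv_peak": _suv_peak(roi),
        "suv_p5": p5,
        "suv_p10": p10,
        "suv_p25": p25,
        "suv_p75": p75,
        "suv_p90": p90,
        "suv_p95": p95,
        "suv_range": vmax - vmin,
        "suv_iqr": p75 - p25,
        "suv_total": float(v.sum()),
        "suv_max_mean_ratio": vmax / mean if mean > 1e-12 else 0.0,
        "mtv_cc": mtv_cc,
        "tlg": mean * mtv_cc,
    }
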