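"""Gray-level quantization of a tumor ROI.

Texture matrices operate on discretized intensities. In-mask SUVs are
binned into ``Ng`` equal-width levels between the ROI minimum and maximum
(level of voxel v = ``1 + floor((v - min)/(max - min) * Ng)`` clipped to
``Ng``), so quantized texture is invariant to positive affine rescaling of
the uptake. A constant ROI maps to level 1 everywhere. The bin count is a
catalog choice — the 64-level default is the common radiomics convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import TumorROI


@dataclass(frozen=True)
class QuantizedROI:
    """Discretized ROI: 3-D level array plus in-mask indicator.

    ``levels`` holds integers 1..Ng for in-mask voxels and 0 outside the
    ROI (0 is a sentinel, never a gray level). ``vmin``/``vmax`` record the
    mapping actually used.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    vmin: float
    vmax: float
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def quantize(roi: TumorROI, n_levels: int = 64) -> QuantizedROI:
    """Equal-width quantization of the ROI's in-mask SUVs into ``n_levels`` bins."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values, mask = roi.stack()
    if not mask.any():
        raise ValueError("empty ROI")
    v = values[mask]
    vmin, vmax = float(v.min()), float(v.max())
    levels = np.zeros(values.shape, dtype=np.int64)
    if vmax > vmin:
        scaled = (values[mask] - vmin) / (vmax - vmin) * n_levels
        levels[mask] = np.clip(np.floor(scaled).astype(np.int64) + 1, 1, n_levels)
    else:
        levels[mask] = 1
    return QuantizedROI(
        levels=levels,
        mask=mask,
        n_levels=n_levels,
        vmin=vmin,
        vmax=vmax,
        spacing=roi.spacing,
    )
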