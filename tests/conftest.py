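"""Shared fixtures: small phantoms, delineated ROIs, random quantized grids."""

from __future__ import annotations

import numpy as np
import pytest

import petromics as pm
from petromics.features.quantize import QuantizedROI


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_volume() -> pm.PETVolume:
    spec = pm.PhantomSpec(
        class_label=1, n_slices=6, in_plane_extent=(28, 24), heterogeneity=0.8, seed=11
    )
    return pm.generate_tumor(spec)


@pytest.fixture(scope="session")
def small_roi(small_volume) -> pm.TumorROI:
    return pm.crop_to_mask(pm.delineate(small_volume))


def make_quantized(
    levels: np.ndarray, mask: np.ndarray | None = None, n_levels: int | None = None
) -> QuantizedROI:
    """Wrap an integer level grid (1..Ng; 0 = outside) as a QuantizedROI."""
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[:, :, None]
    ng = int(n_levels if n_levels is not None else max(2, levels.max()))
    return QuantizedROI(
        levels=np.where(mask, levels, 0),
        mask=mask,
        n_levels=ng,
        vmin=1.0,
        vmax=float(ng),
        spacing=(4.7, 4.7, 3.27),
    )


def random_quantized(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (8, 8, 3),
    n_levels: int = 5,
    mask_p: float = 0.85,
) -> QuantizedROI:
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return make_quantized(levels, mask, n_levels)


def make_roi_from_array(
    values: np.ndarray, mask: np.ndarray | None = None, label: int | None = None
) -> pm.TumorROI:
    """Build a TumorROI directly from a 3-D SUV array (last axis axial)."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    elif mask.ndim == 2:
        mask = np.asarray(mask, dtype=bool)[:, :, None]
    return pm.TumorROI(
        slices=[values[:, :, j] for j in range(values.shape[2])],
        masks=[mask[:, :, j] for j in range(values.shape[2])],
        label=label,
    )
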