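"""Tumor ROI delineation by slice-wise relative thresholding.

The delineation rule keeps, within each axial slice, every voxel whose SUV
is at least ``fraction`` (default 40%) of that slice's maximum. The rule is
purely relative, hence invariant to rescaling the whole volume, and is
applied verbatim — no connected-component cleanup unless explicitly
requested.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import PETVolume, TumorROI


def delineate(
    volume: PETVolume,
    fraction: float = 0.40,
    largest_component: bool = False,
) -> TumorROI:
    """Delineate the tumor ROI with a slice-wise relative threshold.

    Per axial slice, the mask is ``value >= fraction * slice_max`` —
    boundary voxels exactly at the threshold are retained (the rule
    *excludes* voxels strictly below it). Slices whose maximum is zero have
    no lesion signal and are dropped with a warning; a fully zero volume is
    an error.

    Parameters
    ----------
    volume
        Lesion-containing SUV crop.
    fraction
        Relative threshold in (0, 1); the study protocol value is 0.40.
    largest_component
        Optional cleanup: keep only the largest in-plane 8-connected
        component of each slice mask. Off by default — the delineation
        protocol specifies none.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if volume.values.size == 0:
        raise ValueError("empty volume")
    if float(volume.values.max()) <= 0.0:
        raise ValueError("volume has no positive voxels; nothing to delineate")

    slices: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    flags: list[str] = []
    for j in range(volume.n_slices):
        sl = volume.axial_slice(j)
        smax = float(sl.max())
        if smax <= 0.0:
            warnings.warn(
                f"slice {j} of {volume.subject_id} is all-zero; dropped from ROI",
                stacklevel=2,
            )
            flags.append(f"dropped_all_zero_slice:{j}")
            continue
        mask = sl >= fraction * smax
        if largest_component:
            labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
            if n > 1:
                sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
                mask = labels == (1 + int(np.argmax(sizes)))
        slices.append(sl.copy())
        masks.append(mask)
    return TumorROI(
        slices=slices,
        masks=masks,
        spacing=volume.spacing,
        subject_id=volume.subject_id,
        label=volume.label,
        flags=flags,
    )


def crop_to_mask(roi: TumorROI) -> TumorROI:
    """Crop each ROI slice to its mask's tight bounding box.

    Values and masks stay aligned; re-cropping an already tight ROI is a
    no-op. Tight crops feed texture analysis; the uncropped slices feed the
    CNN embedding.
    """
    slices: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for s, m in zip(roi.slices, roi.masks):
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        slices.append(s[r0:r1, c0:c1].copy())
        masks.append(m[r0:r1, c0:c1].copy())
    return TumorROI(
        slices=slices,
        masks=masks,
        spacing=roi.spacing,
        subject_id=roi.subject_id,
        label=roi.label,
        flags=list(roi.flags),
    )
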