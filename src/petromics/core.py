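"""Core data containers: PET volumes and delineated tumor ROIs.

Conventions used throughout the package:

* a volume is a 3-D array of SUV (standardized uptake value, dimensionless)
  with shape ``(rows, cols, slices)`` — the **last axis is axial**;
* voxel spacing is an ``(row, col, slice)`` triple in millimetres;
* all indexing is 0-based;
* a ROI stores its axial slices in inferior→superior order together with
  explicit boolean masks — out-of-mask voxels are never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: voxel spacing of the study scanner, mm (in-plane row, in-plane col, axial)
DEFAULT_SPACING: tuple[float, float, float] = (4.7, 4.7, 3.27)


@dataclass(frozen=True)
class PETVolume:
    """A cropped PET scan containing one tumor, in SUV units.

    Parameters
    ----------
    values
        3-D non-negative array, shape ``(rows, cols, n_slices)``.
    spacing
        Voxel spacing in mm, ``(row, col, slice)``.
    subject_id
        Opaque subject token.
    label
        Optional binary response label (1 = responder, 0 = non-responder).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    subject_id: str = "anon"
    label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"PETVolume expects a 3-D array, got ndim={v.ndim}")
        if np.any(v < 0):
            raise ValueError("SUV values must be non-negative")
        if not np.all(np.isfinite(v)):
            raise ValueError("SUV values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axial_slice(self, j: int) -> np.ndarray:
        """Return axial slice ``j`` as a 2-D ``(rows, cols)`` array."""
        return self.values[:, :, j]

    def with_label(self, label: int | None) -> "PETVolume":
        return replace(self, label=label)


@dataclass
class TumorROI:
    """Delineated tumor: ordered axial SUV slices plus binary masks.

    ``slices[j]`` and ``masks[j]`` are aligned 2-D arrays; ``masks[j]`` is
    True inside the ROI. Out-of-mask SUVs are retained but must never enter
    any statistic — consumers go through :meth:`masked_values` or the masks.
    """

    slices: list[np.ndarray]
    masks: list[np.ndarray]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    subject_id: str = "anon"
    label: int | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValueError("TumorROI needs at least one slice")
        if len(self.slices) != len(self.masks):
            raise ValueError("slices and masks must have equal length")
        for j, (s, m) in enumerate(zip(self.slices, self.masks)):
            if s.shape != m.shape:
                raise ValueError(f"slice/mask shape mismatch at index {j}")
            if not m.any():
                raise ValueError(f"empty mask at slice {j}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def masked_values(self) -> np.ndarray:
        """All in-mask SUVs as a flat array (slice order, then raster order)."""
        return np.concatenate(
            [s[m] for s, m in zip(self.slices, self.masks)]
        )

    def masked_slice(self, j: int) -> np.ma.MaskedArray:
        """Slice ``j`` as a masked array (mask=True means *outside* the ROI)."""
        return np.ma.masked_array(self.slices[j], mask=~self.masks[j])

    def stack(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack slices into ``(values, mask)`` 3-D arrays over a common frame.

        Slices must share one in-plane shape (true straight after
        delineation); cropped ROIs are re-embedded into the union bounding
        box before stacking.
        """
        shapes = {s.shape for s in self.slices}
        if len(shapes) == 1:
            vals = np.stack(self.slices, axis=2)
            mask = np.stack(self.masks, axis=2)
            return vals, mask
        rows = max(s.shape[0] for s in self.slices)
        cols = max(s.shape[1] for s in self.slices)
        vals = np.zeros((rows, cols, self.n_slices))
        mask = np.zeros((rows, cols, self.n_slices), dtype=bool)
        for j, (s, m) in enumerate(zip(self.slices, self.masks)):
            r0 = (rows - s.shape[0]) // 2
            c0 = (cols - s.shape[1]) // 2
            vals[r0 : r0 + s.shape[0], c0 : c0 + s.shape[1], j] = s
            mask[r0 : r0 + s.shape[0], c0 : c0 + s.shape[1], j] = m
        return vals, mask

    def suv_max(self) -> float:
        return float(self.masked_values().max())


# ---------------------------------------------------------------------------
# I/O — NIfTI for volumes/masks, NPZ bundles for ROIs
# ---------------------------------------------------------------------------

def save_volume(volume: PETVolume, path: str | Path) -> None:
    """Write a volume to NIfTI with spacing encoded in the affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_volume(
    path: str | Path, subject_id: str | None = None, label: int | None = None
) -> PETVolume:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return PETVolume(values=values, spacing=zooms, subject_id=sid, label=label)


def save_roi(roi: TumorROI, path: str | Path) -> None:
    """Write a ROI bundle (NPZ: per-slice values/masks, spacing, metadata)."""
    payload: dict[str, np.ndarray] = {
        "n_slices": np.array(roi.n_slices),
        "spacing": np.array(roi.spacing),
        "subject_id": np.array(roi.subject_id),
        "label": np.array(-1 if roi.label is None else int(roi.label)),
    }
    for j, (s, m) in enumerate(zip(roi.slices, roi.masks)):
        payload[f"slice_{j:03d}"] = s
        payload[f"mask_{j:03d}"] = m
    np.savez(str(path), **payload)


def load_roi(path: str | Path) -> TumorROI:
    with np.load(str(path), allow_pickle=False) as data:
        n = int(data["n_slices"])
        label = int(data["label"])
        roi = TumorROI(
            slices=[np.asarray(data[f"slice_{j:03d}"], dtype=float) for j in range(n)],
            masks=[np.asarray(data[f"mask_{j:03d}"], dtype=bool) for j in range(n)],
            spacing=tuple(float(x) for x in data["spacing"]),
            subject_id=str(data["subject_id"]),
            label=None if label < 0 else label,
        )
    return roi


def save_mask(roi: TumorROI, path: str | Path) -> None:
    """Write the stacked binary mask as NIfTI (same frame as the volume)."""
    _, mask = roi.stack()
    affine = np.diag(list(roi.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
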