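"""Slice embedding, triplet construction and rotation augmentation.

Tumor ROI slices of arbitrary extent are embedded, centred, into a fixed
100x100 zero background (large enough for every cohort tumor, whose
extents top out at 93x79). The three-slice variant fuses each set of three
axially adjacent embedded slices z_k = (x_k, x_{k+1}, x_{k+2}) into a
3-channel sample — an m-slice tumor yields exactly m-2 triplets — while
the single-slice variant treats each slice as an independent 1-channel
sample. Training sets are augmented with in-plane rotations by k*60
degrees, k = 1..5, applied identically to all channels (bilinear
interpolation, zero fill).

Intensities are normalized per tumor by its global SUVmax before
embedding, mirroring the relative nature of the delineation rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core import TumorROI

EMBED_SIZE = 100
ROTATION_ANGLES = tuple(60.0 * k for k in range(1, 6))


def embed_slice(slice2d: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Embed a 2-D ROI slice, centred, into a 100x100 zero background.

    The slice is placed at offset ``floor((100 - dim) / 2)`` per axis.
    Out-of-mask pixels are zeroed (the background level); slices larger
    than the frame are an error.
    """
    arr = np.asarray(slice2d, dtype=float)
    if arr.ndim != 2:
        raise ValueError("embed_slice expects a 2-D array")
    rows, cols = arr.shape
    if rows > EMBED_SIZE or cols > EMBED_SIZE:
        raise ValueError(f"slice extent {arr.shape} exceeds the {EMBED_SIZE}x{EMBED_SIZE} frame")
    if mask is not None:
        arr = np.where(mask, arr, 0.0)
    out = np.zeros((EMBED_SIZE, EMBED_SIZE))
    r0 = (EMBED_SIZE - rows) // 2
    c0 = (EMBED_SIZE - cols) // 2
    out[r0 : r0 + rows, c0 : c0 + cols] = arr
    return out


def embed_roi(roi: TumorROI, normalize: bool = True) -> np.ndarray:
    """All ROI slices embedded into the standard frame, shape (m, 100, 100)."""
    scale = roi.suv_max() if normalize else 1.0
    if scale <= 0:
        raise ValueError("ROI has no positive uptake")
    return np.stack(
        [
            embed_slice(s / scale, m)
            for s, m in zip(roi.slices, roi.masks)
        ]
    )


def build_triplets(slices: np.ndarray) -> np.ndarray:
    """All sets of three adjacent slices, shape (m-2, 3, 100, 100).

    Requires m >= 3; the caller decides how to handle thinner tumors
    (the cohort minimum of 4 slices always yields at least 2 triplets).
    """
    m = slices.shape[0]
    if m < 3:
        raise ValueError(f"need at least 3 slices to form a triplet, got {m}")
    return np.stack([slices[k : k + 3] for k in range(m - 2)])


def build_singles(slices: np.ndarray) -> np.ndarray:
    """Each slice as an independent 1-channel sample, shape (m, 1, 100, 100)."""
    return slices[:, None, :, :]


def augment_rotations(sample: np.ndarray) -> list[np.ndarray]:
    """The sample plus 5 copies rotated in-plane by 60, 120, ..., 300 degrees.

    The same rotation is applied to every channel (bilinear interpolation
    about the frame centre, zero fill); labels are inherited by the caller.
    """
    if sample.ndim != 3:
        raise ValueError("expected a (channels, rows, cols) sample")
    out = [sample]
    for angle in ROTATION_ANGLES:
        rot = ndimage.rotate(
            sample, angle, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
        )
        out.append(np.clip(rot, 0.0, None))
    return out


@dataclass
class SliceDataset:
    """A flat training/evaluation set of CNN samples.

    ``x`` has shape (N, C, 100, 100); ``y`` binary labels; ``subject``
    maps each sample back to its tumor.
    """

    x: np.ndarray
    y: np.ndarray
    subject: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


def make_dataset(
    rois: list[TumorROI],
    variant: str = "3s",
    augment: bool = False,
    balance: bool = False,
    seed: int = 0,
    normalize: bool = True,
) -> SliceDataset:
    """Build a sample set from labelled ROIs.

    Parameters
    ----------
    variant
        ``"3s"`` for triplets (3 channels) or ``"1s"`` for single slices.
    augment
        Add the five 60-degree rotations of every sample (training only).
    balance
        Equalize class counts by randomly oversampling the minority class
        after augmentation (the training protocol uses balanced sets).
    """
    if variant not in ("3s", "1s"):
        raise ValueError("variant must be '3s' or '1s'")
    xs: list[np.ndarray] = []
    ys: list[int] = []
    subjects: list[str] = []
    for roi in rois:
        if roi.label is None:
            raise ValueError(f"ROI {roi.subject_id} has no label")
        embedded = embed_roi(roi, normalize=normalize)
        if variant == "3s":
            if roi.n_slices < 3:
                import warnings

                warnings.warn(
                    f"{roi.subject_id}: fewer than 3 slices; excluded from the "
                    "triplet pipeline",
                    stacklevel=2,
                )
                continue
            samples = build_triplets(embedded)
        else:
            samples = build_singles(embedded)
        for s in samples:
            pool = augment_rotations(s) if augment else [s]
            for a in pool:
                xs.append(a.astype(np.float32))
                ys.append(int(roi.label))
                subjects.append(roi.subject_id)
    if not xs:
        raise ValueError("no samples could be built")
    x = np.stack(xs)
    y = np.asarray(ys, dtype=np.int64)
    subject = np.asarray(subjects)
    if balance:
        rng = np.random.default_rng(seed)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) == 2 and counts[0] != counts[1]:
            minority = classes[int(np.argmin(counts))]
            idx_min = np.flatnonzero(y == minority)
            extra = rng.choice(idx_min, size=int(counts.max() - counts.min()), replace=True)
            keep = np.concatenate([np.arange(len(y)), extra])
            x, y, subject = x[keep], y[keep], subject[keep]
    return SliceDataset(x=x, y=y, subject=subject)
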