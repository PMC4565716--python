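"""Texture-matrix builders: GLCM, GLDM, GLRLM, GLSZM, NGTDM.

All builders work on a :class:`~petromics.features.quantize.QuantizedROI`
in full 3-D. Pairwise and run-based matrices use the 13 unique 3-D lattice
directions at distance 1 (half of the 26-neighborhood; each direction
represents itself and its negation). Zone finding uses 26-connectivity and
the neighborhood difference matrix a full 3x3x3 surround. Out-of-mask
voxels never contribute: a pair needs both ends in-mask, a mask gap
terminates a run, and neighbor averages are taken over in-mask neighbors
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .quantize import QuantizedROI

#: the 13 unique 3-D directions at distance 1 (row, col, slice offsets):
#: one representative from each {d, -d} pair of the 26-neighborhood.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dr, dc, dz)
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dr, dc, dz) > (0, 0, 0)
)


def _shift_pairs(
    levels: np.ndarray, mask: np.ndarray, d: tuple[int, int, int], distance: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Gray levels of all in-mask voxel pairs separated by ``distance * d``.

    Returns (levels at v, levels at v + d) for every voxel v with both ends
    inside the array and the mask.
    """
    dr, dc, dz = (distance * k for k in d)
    shape = levels.shape

    def _sl(offset: int, size: int) -> tuple[slice, slice]:
        if offset >= 0:
            return slice(0, size - offset), slice(offset, size)
        return slice(-offset, size), slice(0, size + offset)

    (a0, b0), (a1, b1), (a2, b2) = (
        _sl(dr, shape[0]),
        _sl(dc, shape[1]),
        _sl(dz, shape[2]),
    )
    src = (a0, a1, a2)
    dst = (b0, b1, b2)
    valid = mask[src] & mask[dst]
    return levels[src][valid], levels[dst][valid]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm(
    q: QuantizedROI,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Gray-level co-occurrence matrices, one per direction.

    Returns an array of shape ``(n_directions, Ng, Ng)`` of symmetrized raw
    counts (each ordered pair contributes to both (i, j) and (j, i)).
    Directions with zero valid pairs yield an all-zero matrix; feature code
    excludes them from direction averages.
    """
    ng = q.n_levels
    out = np.zeros((len(directions), ng, ng), dtype=np.int64)
    for k, d in enumerate(directions):
        li, lj = _shift_pairs(q.levels, q.mask, d, distance)
        if li.size == 0:
            continue
        flat = np.bincount((li - 1) * ng + (lj - 1), minlength=ng * ng)
        mat = flat.reshape(ng, ng)
        out[k] = mat + mat.T
    return out


# ---------------------------------------------------------------------------
# GLDM — gray-level difference histogram
# ---------------------------------------------------------------------------

def gldm(
    q: QuantizedROI,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Histogram of absolute level differences over in-mask pairs.

    Pairs are pooled over all directions; entry ``d`` counts pairs with
    ``|level(v) - level(v+delta)| = d``, for d = 0..Ng-1.
    """
    ng = q.n_levels
    hist = np.zeros(ng, dtype=np.int64)
    for d in directions:
        li, lj = _shift_pairs(q.levels, q.mask, d, distance)
        if li.size:
            hist += np.bincount(np.abs(li - lj), minlength=ng)
    return hist


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm(
    q: QuantizedROI,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> np.ndarray:
    """Gray-level run-length matrices, one per direction.

    ``out[k, i-1, j-1]`` counts maximal runs of length ``j`` at level ``i``
    along direction ``k``. A run is a maximal set of consecutive in-mask
    voxels sharing one level; out-of-mask voxels break runs. Runs partition
    the in-mask voxels, so ``sum_ij j * out[k,i,j]`` equals the voxel count
    for every direction.
    """
    ng = q.n_levels
    levels, mask = q.levels, q.mask
    max_len = max(levels.shape)
    out = np.zeros((len(directions), ng, max_len), dtype=np.int64)

    for k, d in enumerate(directions):
        # same[v] = True iff v and v+d are both in-mask with equal level
        same = np.zeros(levels.shape, dtype=bool)
        li_idx = _shift_index(levels.shape, d)
        src, dst = li_idx
        same[src] = mask[src] & mask[dst] & (levels[src] == levels[dst])
        # run starts: in-mask voxels not continued from v-d
        cont = np.zeros(levels.shape, dtype=bool)
        cont[dst] = same[src]
        starts = mask & ~cont
        # walk forward from each start voxel, extending while `same` holds
        step = same
        pos = np.argwhere(starts)
        if pos.size == 0:
            continue
        lengths = np.ones(len(pos), dtype=np.int64)
        active = np.ones(len(pos), dtype=bool)
        offset = np.array(d)
        probe = pos.copy()
        while active.any():
            nxt = probe[active]
            ok = step[tuple(nxt.T)]
            lengths[np.flatnonzero(active)[ok]] += 1
            still = np.flatnonzero(active)[ok]
            newactive = np.zeros_like(active)
            newactive[still] = True
            probe[still] += offset
            active = newactive
        lv = levels[tuple(pos.T)]
        np.add.at(out[k], (lv - 1, lengths - 1), 1)
    return out


def _shift_index(shape, d):
    def _sl(offset: int, size: int) -> tuple[slice, slice]:
        if offset >= 0:
            return slice(0, size - offset), slice(offset, size)
        return slice(-offset, size), slice(0, size + offset)

    (a0, b0), (a1, b1), (a2, b2) = (
        _sl(d[0], shape[0]),
        _sl(d[1], shape[1]),
        _sl(d[2], shape[2]),
    )
    return (a0, a1, a2), (b0, b1, b2)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm(q: QuantizedROI, connectivity: int = 26) -> np.ndarray:
    """Gray-level size-zone matrix (direction-free).

    ``out[i-1, s-1]`` counts connected zones of size ``s`` at level ``i``;
    zones are connected components of iso-level in-mask voxels
    (26-connectivity in 3-D by default). Zones partition the in-mask
    voxels: ``sum_is s * out[i,s]`` equals the voxel count.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=int)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    ng = q.n_levels
    n_vox = q.n_voxels
    out = np.zeros((ng, n_vox), dtype=np.int64)
    present = np.unique(q.in_mask_levels())
    for lv in present:
        blob = (q.levels == lv) & q.mask
        labels, n = ndimage.label(blob, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            out[lv - 1, s - 1] += 1
    return out


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighborhood gray-tone difference matrix.

    For each voxel with at least one in-mask neighbor in its 3x3x3 surround
    (center excluded), the deviation ``|level - neighbor mean|`` is
    accumulated per level. Returns ``(s, counts, n_valid)`` where ``s[i-1]``
    is the summed deviation at level ``i``, ``counts[i-1]`` the number of
    contributing voxels, and ``n_valid`` their total.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    vals = np.where(q.mask, q.levels.astype(float), 0.0)
    nb_sum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(q.mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = q.mask & (nb_cnt > 0.5)
    dev = np.zeros(q.levels.shape)
    dev[valid] = np.abs(
        q.levels[valid] - nb_sum[valid] / nb_cnt[valid]
    )
    ng = q.n_levels
    s = np.zeros(ng)
    counts = np.zeros(ng, dtype=np.int64)
    lv = q.levels[valid]
    np.add.at(s, lv - 1, dev[valid])
    np.add.at(counts, lv - 1, 1)
    return s, counts, int(valid.sum())


@dataclass
class TextureMatrixSet:
    """All texture matrices of one quantized ROI, built with one call."""

    glcm: np.ndarray
    gldm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_counts: np.ndarray
    ngtdm_n: int
    n_voxels: int
    n_levels: int

    @classmethod
    def build(cls, q: QuantizedROI, distance: int = 1) -> "TextureMatrixSet":
        s, counts, n_valid = ngtdm(q)
        return cls(
            glcm=glcm(q, distance=distance),
            gldm=gldm(q, distance=distance),
            glrlm=glrlm(q),
            glszm=glszm(q),
            ngtdm_s=s,
            ngtdm_counts=counts,
            ngtdm_n=n_valid,
            n_voxels=q.n_voxels,
            n_levels=q.n_levels,
        )
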