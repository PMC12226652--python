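"""Texture-matrix builders on discretized 3D ROIs.

All builders operate on a dense integer array ``levels`` where 0 marks
voxels outside the ROI and 1..Ng the gray levels inside.  Co-occurrence
and run-length matrices are built per direction over the 13 unique 3D
neighbour directions (4 in-plane directions in 2D mode); zone, dependence
and gray-tone-difference structures use the full 26-neighbourhood
(8-neighbourhood per slice in 2D mode).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "unique_directions",
    "neighbourhood_offsets",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]


def unique_directions(three_d: bool = True) -> list[tuple[int, int, int]]:
    """Unique neighbour directions (one per +/- pair): 13 in 3D, 4 in 2D."""
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if not three_d and dz != 0:
                    continue
                if d > tuple(-c for c in d):
                    continue  # keep one representative per +/- pair
                dirs.append(d)
    return dirs


def neighbourhood_offsets(distance: int = 1,
                          three_d: bool = True) -> list[tuple[int, int, int]]:
    """All offsets with Chebyshev norm <= distance, excluding the origin."""
    r = range(-distance, distance + 1)
    zr = r if three_d else (0,)
    return [(dx, dy, dz) for dx in r for dy in r for dz in zr
            if (dx, dy, dz) != (0, 0, 0)]


def _pair_views(levels: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a, b) with b[v] = levels[v + offset]."""
    src, dst = [], []
    for n, o in zip(levels.shape, offset):
        if abs(o) >= n:
            return (np.empty(0, levels.dtype),) * 2
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return levels[tuple(src)], levels[tuple(dst)]


def _shifted(arr: np.ndarray, offset, fill=0) -> np.ndarray:
    """out[v] = arr[v + offset], padded with ``fill`` outside the grid."""
    out = np.full_like(arr, fill)
    a, b = [], []
    for n, o in zip(arr.shape, offset):
        if abs(o) >= n:
            return out
        if o >= 0:
            a.append(slice(0, n - o))
            b.append(slice(o, n))
        else:
            a.append(slice(-o, n))
            b.append(slice(0, n + o))
    out[tuple(a)] = arr[tuple(b)]
    return out


def glcm_matrix(levels: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts for one direction."""
    a, b = _pair_views(levels, offset)
    valid = (a > 0) & (b > 0)
    ai, bi = a[valid] - 1, b[valid] - 1
    counts = np.bincount(ai * ng + bi, minlength=ng * ng).reshape(ng, ng)
    return (counts + counts.T).astype(np.float64)


def glrlm_matrix(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length counts (level x run length) for one direction.

    A run is a maximal set of consecutive voxels along the direction that
    share a gray level; voxels outside the ROI break runs.
    """
    valid = levels > 0
    nxt = _shifted(levels, direction)
    prv = _shifted(levels, tuple(-c for c in direction))
    same_next = valid & (nxt == levels)
    start = valid & (prv != levels)

    max_run = int(np.ceil(np.linalg.norm(
        [n * abs(o) for n, o in zip(levels.shape, direction)], np.inf))) + 1
    run_len = valid.astype(np.int64)
    cur = same_next.copy()
    k = 1
    while cur.any() and k <= max_run:
        run_len += cur
        koff = tuple(c * k for c in direction)
        cur &= _shifted(same_next, koff, fill=False)
        k += 1

    lv = levels[start] - 1
    rl = run_len[start] - 1
    nr = int(rl.max()) + 1 if rl.size else 1
    counts = np.bincount(lv * nr + rl, minlength=ng * nr)
    return counts.reshape(ng, nr).astype(np.float64)


def glszm_matrix(levels: np.ndarray, ng: int,
                 three_d: bool = True) -> np.ndarray:
    """Zone-size counts (level x zone size); zones are 26-connected
    components of equal gray level (8-connected per slice in 2D mode)."""
    if three_d:
        structure = np.ones((3, 3, 3), dtype=int)
    else:
        structure = np.zeros((3, 3, 3), dtype=int)
        structure[:, :, 1] = 1  # 8-connectivity within each slice
    cols: dict[int, dict[int, int]] = {}
    max_size = 1
    for g in range(1, ng + 1):
        lab, nzones = ndimage.label(levels == g, structure=structure)
        if nzones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        row: dict[int, int] = {}
        for s in sizes:
            row[int(s)] = row.get(int(s), 0) + 1
            max_size = max(max_size, int(s))
        cols[g] = row
    P = np.zeros((ng, max_size), dtype=np.float64)
    for g, row in cols.items():
        for s, c in row.items():
            P[g - 1, s - 1] = c
    return P


def gldm_matrix(levels: np.ndarray, ng: int, alpha: int = 0,
                distance: int = 1, three_d: bool = True) -> np.ndarray:
    """Dependence counts (level x dependence+1).

    The dependence of a voxel is the number of neighbours (Chebyshev
    distance <= ``distance``) whose gray level differs by at most
    ``alpha``; the matrix column index is dependence + 1.
    """
    valid = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in neighbourhood_offsets(distance, three_d=three_d):
        nb = _shifted(levels, off)
        dep += (valid & (nb > 0) & (np.abs(nb - levels) <= alpha))
    lv = levels[valid] - 1
    dp = dep[valid]
    nd = int(dp.max()) + 1
    counts = np.bincount(lv * nd + dp, minlength=ng * nd)
    return counts.reshape(ng, nd).astype(np.float64)


def ngtdm_table(levels: np.ndarray, ng: int, distance: int = 1,
                three_d: bool = True):
    """Neighbourhood gray-tone difference table.

    Returns ``(n_i, s_i)`` arrays of length Ng where ``n_i`` counts the
    ROI voxels of level i (that have at least one valid neighbour) and
    ``s_i`` sums |i - mean level of valid neighbours| over those voxels.
    """
    valid = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for off in neighbourhood_offsets(distance, three_d=three_d):
        nb = _shifted(levels, off)
        inroi = nb > 0
        nb_sum += np.where(inroi, nb, 0)
        nb_cnt += inroi
    use = valid & (nb_cnt > 0)
    diff = np.zeros(levels.shape, dtype=np.float64)
    diff[use] = np.abs(levels[use] - nb_sum[use] / nb_cnt[use])
    n_i = np.zeros(ng, dtype=np.float64)
    s_i = np.zeros(ng, dtype=np.float64)
    np.add.at(n_i, levels[use] - 1, 1.0)
    np.add.at(s_i, levels[use] - 1, diff[use])
    return n_i, s_i
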