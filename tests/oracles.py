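"""Independent brute-force oracles for the texture matrices and the
reliability statistics.

Everything here is deliberately naive (triple loops, BFS, direct formula
evaluation) and shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def inside(shape, v):
    return all(0 <= c < n for c, n in zip(v, shape))


def brute_glcm(levels: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    P = np.zeros((ng, ng))
    shape = levels.shape
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        nb = tuple(i + o for i, o in zip(idx, offset))
        if not inside(shape, nb):
            continue
        b = levels[nb]
        if b == 0:
            continue
        P[a - 1, b - 1] += 1
        P[b - 1, a - 1] += 1
    return P


def brute_glrlm(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length counts by walking every maximal run."""
    shape = levels.shape
    runs = []
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        prev = tuple(i - o for i, o in zip(idx, direction))
        if inside(shape, prev) and levels[prev] == g:
            continue  # not a run start
        length = 1
        cur = idx
        while True:
            nxt = tuple(i + o for i, o in zip(cur, direction))
            if inside(shape, nxt) and levels[nxt] == g:
                length += 1
                cur = nxt
            else:
                break
        runs.append((g, length))
    if not runs:
        return np.zeros((ng, 1))
    max_len = max(length for _, length in runs)
    P = np.zeros((ng, max_len))
    for g, length in runs:
        P[g - 1, length - 1] += 1
    return P


def brute_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Zone-size counts via BFS over 26-connected equal-level components."""
    shape = levels.shape
    seen = np.zeros(shape, bool)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    zones = []
    for idx in np.ndindex(shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        g = levels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(i + o for i, o in zip(cur, off))
                if inside(shape, nb) and not seen[nb] and levels[nb] == g:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def brute_gldm(levels: np.ndarray, ng: int, alpha: int = 0,
               distance: int = 1) -> np.ndarray:
    """Dependence counts by per-voxel neighbour enumeration."""
    shape = levels.shape
    r = range(-distance, distance + 1)
    offsets = [(dx, dy, dz) for dx in r for dy in r for dz in r
               if (dx, dy, dz) != (0, 0, 0)]
    deps = []
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        dep = 0
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if inside(shape, nb) and levels[nb] != 0 \
                    and abs(int(levels[nb]) - int(g)) <= alpha:
                dep += 1
        deps.append((g, dep))
    max_dep = max((d for _, d in deps), default=0)
    P = np.zeros((ng, max_dep + 1))
    for g, d in deps:
        P[g - 1, d] += 1
    return P


def brute_ngtdm(levels: np.ndarray, ng: int, distance: int = 1):
    """(n_i, s_i) by per-voxel neighbourhood-mean enumeration."""
    shape = levels.shape
    r = range(-distance, distance + 1)
    offsets = [(dx, dy, dz) for dx in r for dy in r for dz in r
               if (dx, dy, dz) != (0, 0, 0)]
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        nbs = []
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if inside(shape, nb) and levels[nb] != 0:
                nbs.append(int(levels[nb]))
        if not nbs:
            continue
        n_i[g - 1] += 1
        s_i[g - 1] += abs(float(g) - float(np.mean(nbs)))
    return n_i, s_i


def pad_to(P: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape)
    out[:P.shape[0], :P.shape[1]] = P
    return out


def oracle_icc_a1(x: np.ndarray) -> float:
    """ICC(A,1) by direct two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True)
            - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def oracle_ccc(x, y) -> float:
    """Lin's CCC by direct moment evaluation (denominator n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sxy = ((x - mx) * (y - my)).sum() / n
    sx2 = ((x - mx) ** 2).sum() / n
    sy2 = ((y - my) ** 2).sum() / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def random_roi(rng: np.random.Generator, max_dim: int = 4, max_ng: int = 4):
    """A random discretized ROI: levels 1..Ng inside a random mask."""
    shape = tuple(int(rng.integers(1, max_dim + 1)) for _ in range(3))
    ng = int(rng.integers(1, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.where(mask, levels, 0)
    # renumber so that max level is present (Ng = max assigned level)
    present = np.unique(levels[levels > 0])
    remap = {g: i + 1 for i, g in enumerate(present)}
    out = np.zeros_like(levels)
    for g, new in remap.items():
        out[levels == g] = new
    return out.astype(np.int64), len(present)
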