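"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-voxel / per-pair enumeration with
no shared code with the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBOURS_26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def bf_glcm(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    mat = np.zeros((n_levels, n_levels), dtype=np.int64)
    for v in np.ndindex(levels.shape):
        a = levels[v]
        if a == 0:
            continue
        for sign in (1, -1):
            w = tuple(v[i] + sign * d[i] for i in range(3))
            if _inside(levels.shape, w) and levels[w] > 0:
                mat[a - 1, levels[w] - 1] += 1
    return mat


def bf_glrlm(levels: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Run-length counts by walking every maximal run."""
    runs = []
    for v in np.ndindex(levels.shape):
        a = levels[v]
        if a == 0:
            continue
        prev = tuple(v[i] - d[i] for i in range(3))
        if _inside(levels.shape, prev) and levels[prev] == a:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[i] + d[i] for i in range(3))
            if _inside(levels.shape, nxt) and levels[nxt] == a:
                length += 1
                cur = nxt
            else:
                break
        runs.append((a, length))
    max_run = max(r for _, r in runs)
    mat = np.zeros((n_levels, max_run), dtype=np.int64)
    for a, r in runs:
        mat[a - 1, r - 1] += 1
    return mat


def bf_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone sizes by flood fill over 26-connected equal-level voxels."""
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for v in np.ndindex(levels.shape):
        if levels[v] == 0 or seen[v]:
            continue
        g = levels[v]
        stack, size = [v], 0
        seen[v] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBOURS_26:
                w = tuple(cur[i] + d[i] for i in range(3))
                if _inside(levels.shape, w) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def bf_gldm(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence counts (centre included) by explicit neighbourhood scan."""
    entries = []
    for v in np.ndindex(levels.shape):
        a = levels[v]
        if a == 0:
            continue
        dep = 1  # the centre voxel depends on itself
        for d in NEIGHBOURS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _inside(levels.shape, w) and levels[w] > 0 and abs(levels[w] - a) <= alpha:
                dep += 1
        entries.append((a, dep))
    max_dep = max(j for _, j in entries)
    mat = np.zeros((n_levels, max_dep), dtype=np.int64)
    for a, j in entries:
        mat[a - 1, j - 1] += 1
    return mat


def bf_ngtdm(levels: np.ndarray, n_levels: int):
    """Per-level counts and summed |level - neighbourhood mean|."""
    n = np.zeros(n_levels, dtype=np.int64)
    s = np.zeros(n_levels, dtype=float)
    for v in np.ndindex(levels.shape):
        a = levels[v]
        if a == 0:
            continue
        nbrs = []
        for d in NEIGHBOURS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _inside(levels.shape, w) and levels[w] > 0:
                nbrs.append(levels[w])
        if not nbrs:
            continue
        n[a - 1] += 1
        s[a - 1] += abs(a - float(np.mean(nbrs)))
    return n, s


def bf_ring(intra: np.ndarray, spacing, distance_mm: float) -> np.ndarray:
    """Per-voxel nearest-distance scan for the perinodular ring.

    Voxels exactly on the distance boundary are decided with a 1e-9 mm
    slack: whether sqrt((4*0.8)^2 + (3*0.8)^2) compares <= 4.0 depends on
    float summation order, so an exact tie is not a well-posed oracle.
    """
    spacing = np.asarray(spacing, dtype=float)
    inside = np.argwhere(intra) * spacing
    ring = np.zeros(intra.shape, dtype=bool)
    for v in np.ndindex(intra.shape):
        if intra[v]:
            continue
        p = np.asarray(v) * spacing
        dmin = np.sqrt(((inside - p) ** 2).sum(axis=1)).min()
        ring[v] = dmin <= distance_mm + 1e-9
    return ring


def bf_auc(y, scores) -> float:
    """Normalized Mann-Whitney U with ties counted one half."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bf_glcm_correlation(levels: np.ndarray, d, n_levels: int) -> float:
    """GLCM Correlation of one direction from raw pair enumeration."""
    mat = bf_glcm(levels, d, n_levels).astype(float)
    p = mat / mat.sum()
    i = np.arange(1, n_levels + 1)
    px, py = p.sum(1), p.sum(0)
    mx, my = (i * px).sum(), (i * py).sum()
    sx = np.sqrt(((i - mx) ** 2 * px).sum())
    sy = np.sqrt(((i - my) ** 2 * py).sum())
    if sx == 0 or sy == 0:
        return 1.0
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return float((p * ii * jj).sum() - mx * my) / (sx * sy)
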