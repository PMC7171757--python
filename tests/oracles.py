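"""Independent brute-force references for the texture matrices.

Deliberately naive (explicit Python loops, breadth-first flood fill,
exhaustive neighbourhood enumeration) so they share no code with the
vectorized implementations they check.
"""

from collections import deque

import numpy as np


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def glcm_brute(levels, n_levels, directions):
    """Symmetric co-occurrence counts by looping over every voxel and
    both orientations of every direction."""
    counts = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for d in directions:
        for sign in (1, -1):
            off = tuple(sign * x for x in d)
            for idx in np.ndindex(shape):
                a = levels[idx]
                if a == 0:
                    continue
                jdx = tuple(i + o for i, o in zip(idx, off))
                if not _in_bounds(jdx, shape):
                    continue
                b = levels[jdx]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
    return counts


def glrlm_brute(levels, n_levels, directions):
    """Run-length counts by walking every line voxel by voxel."""
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(3) * max(shape))) + 1
    mat = np.zeros((n_levels, max_len))
    for d in directions:
        for idx in np.ndindex(shape):
            a = levels[idx]
            if a == 0:
                continue
            prev = tuple(i - o for i, o in zip(idx, d))
            if _in_bounds(prev, shape) and levels[prev] == a:
                continue  # not a run start
            length = 1
            cur = tuple(i + o for i, o in zip(idx, d))
            while _in_bounds(cur, shape) and levels[cur] == a:
                length += 1
                cur = tuple(i + o for i, o in zip(cur, d))
            mat[a - 1, length - 1] += 1
    used = np.nonzero(mat.any(axis=0))[0]
    return mat[:, : used[-1] + 1] if used.size else mat[:, :1]


def _neighbors26(idx, shape):
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                j = (idx[0] + dz, idx[1] + dy, idx[2] + dx)
                if _in_bounds(j, shape):
                    yield j


def glzlm_brute(levels, n_levels):
    """Zone counts by breadth-first flood fill over 26-connectivity."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    n_vox = int((levels > 0).sum())
    mat = np.zeros((n_levels, max(n_vox, 1)))
    for start in np.ndindex(shape):
        if levels[start] == 0 or visited[start]:
            continue
        lvl = levels[start]
        size = 0
        queue = deque([start])
        visited[start] = True
        while queue:
            cur = queue.popleft()
            size += 1
            for nb in _neighbors26(cur, shape):
                if not visited[nb] and levels[nb] == lvl:
                    visited[nb] = True
                    queue.append(nb)
        mat[lvl - 1, size - 1] += 1
    used = np.nonzero(mat.any(axis=0))[0]
    return mat[:, : used[-1] + 1] if used.size else mat[:, :1]


def ngldm_brute(levels, n_levels):
    """Per-level counts and absolute-difference sums against the in-ROI
    26-neighbourhood mean, voxel by voxel."""
    shape = levels.shape
    counts = np.zeros(n_levels)
    sums = np.zeros(n_levels)
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        nb = [levels[j] for j in _neighbors26(idx, shape) if levels[j] > 0]
        if not nb:
            continue
        counts[a - 1] += 1
        sums[a - 1] += abs(a - sum(nb) / len(nb))
    return counts, sums
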