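"""Numba kernels for deterministic seeded region growing.

The flood is inherently sequential (each region keeps a running mean that
updates as voxels join), so it is written as jit-compiled breadth-first
searches over a flat int32 label array rather than vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

UNASSIGNED = -1
BARRIER = -2


@njit(cache=True)
def _neighbors(idx, nz, ny, nx, offsets_z, offsets_y, offsets_x, out):
    z = idx // (ny * nx)
    rem = idx % (ny * nx)
    y = rem // nx
    x = rem % nx
    n = 0
    for k in range(offsets_z.shape[0]):
        z2 = z + offsets_z[k]
        y2 = y + offsets_y[k]
        x2 = x + offsets_x[k]
        if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
            out[n] = (z2 * ny + y2) * nx + x2
            n += 1
    return n


def connectivity_offsets(connectivity: int):
    """Neighbour offsets for 6- or 26-connectivity, in lexicographic order."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                offs.append((dz, dy, dx))
    o = np.array(offs, dtype=np.int64)
    return o[:, 0].copy(), o[:, 1].copy(), o[:, 2].copy()


@njit(cache=True)
def grow_regions(values, barrier, nz, ny, nx, tol, oz, oy, ox):
    """Deterministic flood fill with a running-mean similarity criterion.

    Seeds are non-barrier voxels visited in lexicographic (z, y, x) order; a
    voxel joins the current region iff it is connected, non-barrier and
    |value - region running mean| <= tol. Returns (labels, n_regions) with
    labels >= 0 for grown regions, BARRIER for barrier voxels.
    """
    nvox = values.shape[0]
    labels = np.full(nvox, UNASSIGNED, dtype=np.int32)
    for i in range(nvox):
        if barrier[i]:
            labels[i] = BARRIER
    queue = np.empty(nvox, dtype=np.int64)
    nbuf = np.empty(32, dtype=np.int64)
    region = 0
    for start in range(nvox):
        if labels[start] != UNASSIGNED:
            continue
        head = 0
        tail = 0
        queue[tail] = start
        tail += 1
        labels[start] = region
        s = float(values[start])
        cnt = 1.0
        while head < tail:
            cur = queue[head]
            head += 1
            nn = _neighbors(cur, nz, ny, nx, oz, oy, ox, nbuf)
            mean = s / cnt
            for k in range(nn):
                j = nbuf[k]
                if labels[j] != UNASSIGNED:
                    continue
                if abs(values[j] - mean) <= tol:
                    labels[j] = region
                    queue[tail] = j
                    tail += 1
                    s += values[j]
                    cnt += 1.0
                    mean = s / cnt
        region += 1
    return labels, region


@njit(cache=True)
def region_stats(labels, values, n_regions):
    sums = np.zeros(n_regions, dtype=np.float64)
    counts = np.zeros(n_regions, dtype=np.int64)
    for i in range(labels.shape[0]):
        r = labels[i]
        if r >= 0:
            sums[r] += values[i]
            counts[r] += 1
    means = np.zeros(n_regions, dtype=np.float64)
    for r in range(n_regions):
        if counts[r] > 0:
            means[r] = sums[r] / counts[r]
    return means, counts


@njit(cache=True)
def absorb_unassigned(labels, values, means, counts, nz, ny, nx, oz, oy, ox):
    """Merge barrier/unassigned voxels into the adjacent region whose mean
    intensity is nearest, sweeping repeatedly until no voxel changes."""
    nvox = labels.shape[0]
    nbuf = np.empty(32, dtype=np.int64)
    changed = True
    while changed:
        changed = False
        for i in range(nvox):
            if labels[i] >= 0:
                continue
            nn = _neighbors(i, nz, ny, nx, oz, oy, ox, nbuf)
            best = -1
            best_d = 1e300
            for k in range(nn):
                r = labels[nbuf[k]]
                if r >= 0:
                    d = abs(values[i] - means[r])
                    if d < best_d:
                        best_d = d
                        best = r
            if best >= 0:
                labels[i] = best
                means[best] = (means[best] * counts[best] + values[i]) / (counts[best] + 1)
                counts[best] += 1
                changed = True
    return labels


@njit(cache=True)
def merge_small_regions(labels, values, means, counts, min_vox,
                        nz, ny, nx, oz, oy, ox):
    """Relabel every region smaller than min_vox into the adjacent region
    with nearest mean intensity, repeating until stable."""
    nvox = labels.shape[0]
    n_regions = means.shape[0]
    nbuf = np.empty(32, dtype=np.int64)
    remap = np.arange(n_regions, dtype=np.int32)
    for _pass in range(n_regions):
        # resolve remap chains
        for r in range(n_regions):
            t = remap[r]
            while remap[t] != t:
                t = remap[t]
            remap[r] = t
        changed = False
        # find, for each small region, its best adjacent region
        best_d = np.full(n_regions, 1e300)
        best_r = np.full(n_regions, -1, dtype=np.int32)
        for i in range(nvox):
            r = remap[labels[i]]
            if counts[r] >= min_vox:
                continue
            nn = _neighbors(i, nz, ny, nx, oz, oy, ox, nbuf)
            for k in range(nn):
                r2 = remap[labels[nbuf[k]]]
                if r2 != r:
                    d = abs(means[r] - means[r2])
                    if d < best_d[r]:
                        best_d[r] = d
                        best_r[r] = r2
        for r in range(n_regions):
            if remap[r] != r or counts[r] >= min_vox or counts[r] == 0:
                continue
            tgt = best_r[r]
            if tgt < 0:
                continue
            while remap[tgt] != tgt:
                tgt = remap[tgt]
            if tgt == r:
                continue
            tot = counts[r] + counts[tgt]
            means[tgt] = (means[tgt] * counts[tgt] + means[r] * counts[r]) / tot
            counts[tgt] = tot
            counts[r] = 0
            remap[r] = tgt
            changed = True
        if not changed:
            break
    for r in range(n_regions):
        t = remap[r]
        while remap[t] != t:
            t = remap[t]
        remap[r] = t
    for i in range(nvox):
        labels[i] = remap[labels[i]]
    return labels
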