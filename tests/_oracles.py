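"""Independent brute-force oracles used only by the test suite.

Everything here is written deliberately naively (explicit sorting, BFS
flood fill, textbook sum formulas, exhaustive enumeration) and shares no
code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_segment(data, clip_percentile=96.5, threshold_fraction=0.9):
    """Sort-based re-implementation of clip-and-threshold segmentation.

    Returns a dict with clip_value, threshold, mask (after keeping the
    largest 26-connected component, ties broken by unweighted component
    centroid proximity to the crop centre), n_voxels and the local
    intensity-weighted centroid as (x, y, z).
    """
    arr = np.asarray(data, dtype=float)
    flat = sorted(arr.ravel().tolist())
    n = len(flat)
    rank = int(math.ceil(clip_percentile / 100.0 * n))
    clip_value = flat[max(1, min(rank, n)) - 1]
    clipped = np.where(arr > clip_value, clip_value, arr)
    threshold = threshold_fraction * clipped.max()
    mask = clipped >= threshold

    # BFS flood fill, 26-connectivity, components in C-scan discovery order
    visited = np.zeros_like(mask, dtype=bool)
    components = []
    nz, ny, nx = mask.shape
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[z0, y0, x0] or visited[z0, y0, x0]:
                    continue
                comp = []
                stack = [(z0, y0, x0)]
                visited[z0, y0, x0] = True
                while stack:
                    z, y, x = stack.pop()
                    comp.append((z, y, x))
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                if dz == dy == dx == 0:
                                    continue
                                zz, yy, xx = z + dz, y + dy, x + dx
                                if (
                                    0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                                    and mask[zz, yy, xx] and not visited[zz, yy, xx]
                                ):
                                    visited[zz, yy, xx] = True
                                    stack.append((zz, yy, xx))
                components.append(comp)

    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    best = None
    for comp in components:
        size = len(comp)
        cz = sum(p[0] for p in comp) / size
        cy = sum(p[1] for p in comp) / size
        cx = sum(p[2] for p in comp) / size
        dist = math.dist((cz, cy, cx), center)
        key = (-size, dist)
        if best is None or key < best[0]:
            best = (key, comp)
    chosen = best[1]

    final = np.zeros_like(mask)
    for z, y, x in chosen:
        final[z, y, x] = True
    wsum = sum(clipped[p] for p in chosen)
    cx = sum(clipped[p] * p[2] for p in chosen) / wsum
    cy = sum(clipped[p] * p[1] for p in chosen) / wsum
    cz = sum(clipped[p] * p[0] for p in chosen) / wsum
    return {
        "clip_value": clip_value,
        "threshold": threshold,
        "mask": final,
        "n_voxels": len(chosen),
        "centroid_local_xyz": (cx, cy, cz),
    }


def kruskal_H_by_ranks(groups):
    """Tie-corrected Kruskal-Wallis H from explicitly computed mid-ranks."""
    pooled = []
    for gi, g in enumerate(groups):
        pooled.extend((v, gi) for v in g)
    pooled.sort(key=lambda t: t[0])
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        mid = (i + 1 + j) / 2.0  # average of ranks i+1 .. j
        for k in range(i, j):
            ranks[k] = mid
        i = j
    rank_sums = [0.0] * len(groups)
    for (v, gi), r in zip(pooled, ranks):
        rank_sums[gi] += r
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[gi] ** 2 / len(g) for gi, g in enumerate(groups)
    ) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    denom = 1.0 - ties / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def exact_permutation_pvalue(groups):
    """Exact permutation p-value for the Kruskal-Wallis H over every way of
    partitioning the pooled observations into groups of the given sizes."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = kruskal_H_by_ranks(groups)
    idx = list(range(len(pooled)))

    count = 0
    total = 0
    for first in itertools.combinations(idx, sizes[0]):
        rest1 = [i for i in idx if i not in set(first)]
        for second in itertools.combinations(rest1, sizes[1]):
            third = [i for i in rest1 if i not in set(second)]
            parts = [
                [pooled[i] for i in first],
                [pooled[i] for i in second],
                [pooled[i] for i in third],
            ]
            h = kruskal_H_by_ranks(parts)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
    return count / total


def pearson_sum_formula(a, b):
    """Textbook sum-formula Pearson coefficient."""
    a = [float(v) for v in np.ravel(a)]
    b = [float(v) for v in np.ravel(b)]
    n = len(a)
    sx = sum(a)
    sy = sum(b)
    sxy = sum(x * y for x, y in zip(a, b))
    sxx = sum(x * x for x in a)
    syy = sum(y * y for y in b)
    return (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))


def exhaustive_bead_matching(ref, mov, gate):
    """Best one-to-one matching between two small point sets (<= 6 each):
    maximise the number of within-gate pairs, then minimise total distance,
    by exhaustive enumeration.  Returns sorted (ref_index, mov_index) pairs."""
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    best = (-1, math.inf, [])
    for k in range(min(len(ref), len(mov)), 0, -1):
        for ref_subset in itertools.combinations(range(len(ref)), k):
            for mov_perm in itertools.permutations(range(len(mov)), k):
                pairs = list(zip(ref_subset, mov_perm))
                if any(np.linalg.norm(ref[i] - mov[j]) > gate for i, j in pairs):
                    continue
                cost = sum(np.linalg.norm(ref[i] - mov[j]) for i, j in pairs)
                if (k, -cost) > (best[0], -best[1]):
                    best = (k, cost, pairs)
        if best[0] == k:
            break
    return sorted(best[2])
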