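"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the production
code: patch-level Euler deltas by direct cell counting, neighborhood
connectivity by flood fill over explicit voxel sets, voxel classification
by all-pairs distances, and flow matching by direct subset enumeration
over bit masks.
"""

from __future__ import annotations

import itertools

import numpy as np

from hepatree.euler import euler_characteristic


def patch_euler_delta(patch: np.ndarray) -> int:
    """Change in chi of a 3x3x3 patch when its center is deleted,
    computed with the octant-free cubical-complex chi."""
    p = np.asarray(patch, bool)
    assert p.shape == (3, 3, 3) and p[1, 1, 1]
    q = p.copy()
    q[1, 1, 1] = False
    return euler_characteristic(p) - euler_characteristic(q)


def neighbors_components(patch: np.ndarray) -> int:
    """Number of 26-connected components among the 26 neighbors of the
    center (center excluded), by explicit flood fill."""
    p = np.asarray(patch, bool)
    vox = [tuple(v) for v in np.argwhere(p) if tuple(v) != (1, 1, 1)]
    vox_set = set(vox)
    seen = set()
    comps = 0
    for start in vox:
        if start in seen:
            continue
        comps += 1
        stack = [start]
        seen.add(start)
        while stack:
            z, y, x = stack.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        n = (z + dz, y + dy, x + dx)
                        if n in vox_set and n not in seen:
                            seen.add(n)
                            stack.append(n)
    return comps


def brute_force_classify(liver: np.ndarray, groups: dict[int, np.ndarray],
                         spacing) -> np.ndarray:
    """All-pairs minimum-distance labeling: for every liver voxel the
    label of the group with the smallest squared Euclidean distance
    ``sum_axis ((v - p) * s)^2`` to any of its voxels, ties to the lowest
    label."""
    lv = np.asarray(liver, bool)
    sp = np.asarray(spacing, float)
    liver_idx = np.argwhere(lv).astype(float)
    labels_sorted = sorted(groups)
    dmin = np.full((len(labels_sorted), len(liver_idx)), np.inf)
    for i, lab in enumerate(labels_sorted):
        pts = np.asarray(groups[lab], float)
        for start in range(0, len(liver_idx), 8192):
            chunk = liver_idx[start:start + 8192]
            d2 = (((chunk[:, None, :] - pts[None, :, :]) * sp) ** 2
                  ).sum(axis=2)
            dmin[i, start:start + len(chunk)] = d2.min(axis=1)
    arg = np.argmin(dmin, axis=0)
    out = np.zeros(lv.shape, np.int32)
    out[lv] = np.asarray(labels_sorted, np.int32)[arg]
    return out


def best_flow_subset(r_in: float, noncyclic: list[float],
                     cyclic: list[float]) -> set[int]:
    """Exhaustive minimum-|Diff| subset of cyclic outflow candidates,
    enumerated over bit masks (independent of itertools.combinations
    ordering); ties resolved like the implementation: smaller |Diff|,
    then fewer members, then lexicographically earlier index tuple."""
    target = r_in ** 2 - sum(r ** 2 for r in noncyclic)
    best, best_key = None, None
    for mask in range(1 << len(cyclic)):
        idx = tuple(i for i in range(len(cyclic)) if mask >> i & 1)
        diff = abs(target - sum(cyclic[i] ** 2 for i in idx))
        key = (diff, len(idx), idx)
        if best_key is None or key < best_key:
            best, best_key = set(idx), key
    return best


def exhaustive_wcss_pairing(points: np.ndarray, k: int) -> float:
    """Best within-cluster sum of squares over all assignments of
    ``points`` into ``k`` clusters — only feasible for tiny n."""
    n = len(points)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        wcss = 0.0
        for c in range(k):
            members = points[[i for i in range(n) if assign[i] == c]]
            wcss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return best
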