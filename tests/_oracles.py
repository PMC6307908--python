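"""Independent brute-force reference implementations used only by tests.

Deliberately naive pure-Python code (flood fill, exhaustive scans,
enumeration of matchings) kept free of any import from the package's
algorithmic internals, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int):
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return [
        off
        for off in itertools.product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0) and sum(abs(o) for o in off) <= rank
    ]


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Partition of True voxels into connected components (BFS flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    offsets = neighbour_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps


def label_partition(labels: np.ndarray) -> set[frozenset]:
    """Component partition implied by a label grid (ignoring label values)."""
    out: dict[int, list] = {}
    for v in zip(*np.nonzero(labels)):
        out.setdefault(int(labels[v]), []).append(v)
    return {frozenset(vs) for vs in out.values()}


def regional_partition_bruteforce(graft_mask, ccv_point, ccv_axis, voxel_size):
    """Sort graft voxels by CCV-axis projection and slice into near-equal thirds.

    Pure-Python reimplementation used as the oracle for the equal-volume
    partition: returns a dict voxel -> region (1 proximal, 2 middle, 3 distal).
    """
    voxels = [tuple(v) for v in np.argwhere(np.asarray(graft_mask, dtype=bool))]
    keyed = []
    for v in voxels:
        pos = [(v[i] + 0.5) * voxel_size[i] for i in range(3)]
        s = sum((pos[i] - ccv_point[i]) * ccv_axis[i] for i in range(3))
        keyed.append((s, v[0], v[1], v[2], v))
    keyed.sort()
    n = len(keyed)
    base, r = divmod(n, 3)
    sizes = [base + (1 if r >= 1 else 0), base + (1 if r >= 2 else 0), base]
    region = {}
    start = 0
    for region_id, size in enumerate(sizes, start=1):
        for _, _, _, _, v in keyed[start : start + size]:
            region[v] = region_id
        start += size
    return region


def disc_pixels_bruteforce(shape_yx, voxel_size_yx, centre_yx, radius):
    """Set of (y, x) pixel indices whose centre is within the disc."""
    out = set()
    for y in range(shape_yx[0]):
        for x in range(shape_yx[1]):
            cy = (y + 0.5) * voxel_size_yx[0]
            cx = (x + 0.5) * voxel_size_yx[1]
            if math.hypot(cy - centre_yx[0], cx - centre_yx[1]) <= radius + 1e-9:
                out.add((y, x))
    return out


def best_matching_bruteforce(points_a, points_b, max_step):
    """Minimal-total-distance injective matching between two point sets.

    Exhaustive enumeration over all partial injective mappings (feasible for
    a handful of points); returns a set of (i, j) index pairs.
    """
    points_a = [np.asarray(p, dtype=float) for p in points_a]
    points_b = [np.asarray(p, dtype=float) for p in points_b]
    n_a, n_b = len(points_a), len(points_b)
    best_cost, best_pairs = math.inf, set()
    indices_b = list(range(n_b))
    for k in range(min(n_a, n_b), -1, -1):
        for subset_a in itertools.combinations(range(n_a), k):
            for perm_b in itertools.permutations(indices_b, k):
                cost = 0.0
                ok = True
                for i, j in zip(subset_a, perm_b):
                    d = float(np.linalg.norm(points_a[i] - points_b[j]))
                    if d > max_step:
                        ok = False
                        break
                    cost += d
                # prefer maximal cardinality, then minimal cost (mirrors the
                # assignment solver: unmatched pairs carry a huge penalty)
                if ok:
                    total = cost + (min(n_a, n_b) - k) * 1e12
                    if total < best_cost - 1e-12:
                        best_cost = total
                        best_pairs = set(zip(subset_a, perm_b))
    return best_pairs
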