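"""Independent brute-force oracles used to cross-check the implementations.

These deliberately re-derive results from first principles with simple O(n²)
or exhaustive algorithms, sharing no code with the package internals.
"""

import numpy as np
from scipy import stats


def decline_phases_oracle(area, start_frame=0):
    """O(n²) scan re-deriving decline phases from the definition.

    A decline starts at the smallest frame s past the previous phase end
    whose area lies strictly below 95% of the maximum observed since that
    end; it ends at the first later frame at which the area rises (or at the
    last frame).
    """
    area = np.asarray(area, dtype=float)
    n = len(area)
    phases = []
    prev_end = start_frame
    while True:
        found = None
        for s in range(prev_end + 1, n):
            ref = max(area[prev_end : s + 1])  # fresh scan each time: O(n²)
            if area[s] < 0.95 * ref:
                found = s
                break
        if found is None:
            return phases
        end = n - 1
        for j in range(found + 1, n):
            if area[j] > area[j - 1]:
                end = j
                break
        phases.append((found, end))
        if end >= n - 1:
            return phases
        prev_end = end


def expansion_phases_oracle(times, area, decline_bounds, start_frame=0):
    """Accepted expansion intervals re-derived directly from the criteria."""
    n = len(area)
    prev_end = start_frame
    candidates = []
    for s, e in decline_bounds:
        candidates.append((prev_end, s - 1))
        prev_end = e
    candidates.append((prev_end, n - 1))
    accepted = []
    for s, e in candidates:
        if e - s + 1 < 5:
            continue
        seg_t, seg_a = times[s : e + 1], area[s : e + 1]
        if np.ptp(seg_a) == 0 or np.ptp(seg_t) == 0:
            continue
        r = stats.pearsonr(seg_t, seg_a)[0]
        if r > 0.9:
            accepted.append((s, e))
    return accepted


def optimal_matching_oracle(gt_pts, seg_pts, radius):
    """Exhaustive maximum one-to-one matching size within the radius.

    Backtracking over all injective partial assignments; feasible only for
    tiny instances (≤ ~7 points per side).
    """
    gt_pts = np.asarray(gt_pts, dtype=float)
    seg_pts = np.asarray(seg_pts, dtype=float)
    n_gt = len(gt_pts)
    adjacency = [
        [
            s
            for s in range(len(seg_pts))
            if np.linalg.norm(gt_pts[g] - seg_pts[s]) <= radius
        ]
        for g in range(n_gt)
    ]
    best = 0

    def recurse(g, used, count):
        nonlocal best
        best = max(best, count)
        if g == n_gt:
            return
        recurse(g + 1, used, count)  # leave this ground-truth point unmatched
        for s in adjacency[g]:
            if s not in used:
                recurse(g + 1, used | {s}, count + 1)

    recurse(0, frozenset(), 0)
    return best


def delaunay_adjacency_oracle(simplices, n_points):
    """Pairwise adjacency re-derived by looping over every tetrahedron."""
    neighbours = [set() for _ in range(n_points)]
    for simplex in simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    neighbours[a].add(b)
    return [len(s) for s in neighbours]
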