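"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths (scipy.ndimage /
skimage.measure / DP segmentation) so that agreement is informative.
"""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_components(
    image: np.ndarray, background: float, factor: float = 2.0, eight: bool = True
) -> list[dict]:
    """Connected components of the strict-threshold mask by BFS flood fill.

    Returns one dict per component with the pixel set, pixel area,
    background-subtracted peak/integrated intensity and intensity-weighted
    centroid (row, col in pixel units, pixel centres at index + 0.5).
    """
    h, w = image.shape
    mask = image > factor * background
    seen = np.zeros_like(mask, dtype=bool)
    if eight:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            pixels = []
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr, dc in neigh:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            weights = np.array([image[p] - background for p in pixels])
            wr = sum(wt * (p[0] + 0.5) for wt, p in zip(weights, pixels)) / weights.sum()
            wc = sum(wt * (p[1] + 0.5) for wt, p in zip(weights, pixels)) / weights.sum()
            comps.append(
                {
                    "pixels": frozenset(pixels),
                    "area_px": len(pixels),
                    "peak": float(weights.max()),
                    "integrated": float(weights.sum()),
                    "centroid_rc": (wr, wc),
                }
            )
    return comps


def kruskal_h_direct(groups: list[np.ndarray]) -> float:
    """KW H by direct evaluation of the rank formula (midranks, tie-corrected)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def exhaustive_change_points(y: np.ndarray, n_segments: int) -> float:
    """Minimum SSE over ALL change-point placements, by full enumeration."""
    n = y.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), n_segments - 1):
        b = (0, *cuts, n)
        sse = 0.0
        for k in range(n_segments):
            seg = y[b[k] : b[k + 1]]
            sse += float(np.sum((seg - seg.mean()) ** 2))
        best = min(best, sse)
    return best
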