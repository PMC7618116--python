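"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (loops, enumeration, closed forms) that
share no code with the package internals they check.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 8-connected components of a binary mask by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    n = 0
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                n += 1
                q = deque([(sy, sx)])
                seen[sy, sx] = True
                while q:
                    y, x = q.popleft()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                q.append((yy, xx))
    return n


def regional_maxima_deeper_than(height: np.ndarray, h: float) -> int:
    """Count regional maxima of ``height`` deeper than ``h``.

    Brute-force greyscale reconstruction by iterative dilation of
    ``height − h`` under ``height``; maxima survive where the
    reconstruction stays below the original.  Returns the number of
    8-connected components of the surviving maxima set.
    """
    height = np.asarray(height, dtype=float)
    marker = height - h
    while True:
        dilated = marker.copy()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                shifted = np.roll(np.roll(marker, dy, axis=0), dx, axis=1)
                if dy > 0:
                    shifted[:dy, :] = -np.inf
                elif dy < 0:
                    shifted[dy:, :] = -np.inf
                if dx > 0:
                    shifted[:, :dx] = -np.inf
                elif dx < 0:
                    shifted[:, dx:] = -np.inf
                dilated = np.maximum(dilated, shifted)
        dilated = np.minimum(dilated, height)
        if np.array_equal(dilated, marker):
            break
        marker = dilated
    maxima = (height - marker) > 1e-9
    return flood_fill_components(maxima)


def pixel_overlap_area(
    labels_a: np.ndarray, id_a: int, labels_b: np.ndarray, id_b: int, pixel_area: float
) -> float:
    """Exact intersection area of two label masks by pixel counting."""
    return float(np.count_nonzero((labels_a == id_a) & (labels_b == id_b))) * pixel_area


def all_pairs_best_match(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    pixel_area: float,
    min_overlap: float,
) -> list[tuple[int, int, float]]:
    """Exhaustive all-pairs pairing followed by best-match per ``a`` label."""
    out = []
    for ia in range(1, int(labels_a.max()) + 1):
        best = None
        for ib in range(1, int(labels_b.max()) + 1):
            area = pixel_overlap_area(labels_a, ia, labels_b, ib, pixel_area)
            if area >= min_overlap and (best is None or area > best[1]):
                best = (ib, area)
        if best is not None:
            out.append((ia, best[0], best[1]))
    return out


def fisher_two_sided(k: int, q: int, r: int, universe: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Table: ``[[k, q−k], [r−k, U−q−r+k]]`` — drawing ``q`` genes from a
    universe containing ``r`` reference genes; two-sided rule sums the
    probabilities of all overlap counts no more likely than the observed.
    """

    def pmf(x: int) -> float:
        if x < max(0, q + r - universe) or x > min(q, r):
            return 0.0
        return (
            math.comb(r, x)
            * math.comb(universe - r, q - x)
            / math.comb(universe, q)
        )

    p_obs = pmf(k)
    return sum(pmf(x) for x in range(0, min(q, r) + 1) if pmf(x) <= p_obs * (1 + 1e-12))


def percentile_by_sorting(values: np.ndarray, pct: float) -> float:
    """Linear-interpolation percentile computed directly from the sorted
    sample (the classic definition, no library call)."""
    v = np.sort(np.asarray(values, dtype=float))
    rank = pct / 100 * (len(v) - 1)
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)
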