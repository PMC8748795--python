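"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by literal enumeration or a closed
form, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_local_maxima(y) -> list[int]:
    """Literal local-maximum scan: an interior sample (or flat run) that is
    strictly higher than its distinct neighbours on both sides; a flat run
    reports its middle index (rounded down)."""
    y = list(float(v) for v in y)
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def oracle_detect_indices(y, min_intensity: float, min_separation_px: int) -> list[int]:
    """Literal application of the detection rules: local maxima, apex
    filter, then greedy left-to-right merging keeping the higher apex
    (leftmost on ties)."""
    candidates = [i for i in oracle_local_maxima(y) if y[i] >= min_intensity]
    kept: list[int] = []
    for i in candidates:
        if kept and i - kept[-1] < min_separation_px:
            if y[i] > y[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return kept


def oracle_gaussian_fwhm(sigma: float) -> float:
    """Width of A*exp(-x^2/2sigma^2) at half height via numeric root finding."""
    from scipy.optimize import brentq

    def g(x):
        return math.exp(-0.5 * (x / sigma) ** 2) - 0.5

    right = brentq(g, 0.0, 10.0 * sigma)
    return 2.0 * right


def oracle_multiotsu_background(values: np.ndarray, n_classes: int = 3):
    """Exhaustive search over threshold pairs drawn from the distinct values,
    maximizing between-class variance; returns (background mask, background
    mean) for the lowest class."""
    flat = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(flat)
    total_mean = flat.mean()

    def between_var(class_masks):
        return sum(
            m.sum() * (flat[m].mean() - total_mean) ** 2
            for m in class_masks
            if m.any()
        )

    best = None
    if n_classes == 3 and uniq.size >= 3:
        candidates = uniq[:-1]
        for a_i in range(candidates.size):
            for b_i in range(a_i + 1, candidates.size):
                t1, t2 = candidates[a_i], candidates[b_i]
                masks = [flat <= t1, (flat > t1) & (flat <= t2), flat > t2]
                v = between_var(masks)
                if best is None or v > best[0]:
                    best = (v, t1)
    else:
        for t1 in uniq[:-1]:
            masks = [flat <= t1, flat > t1]
            v = between_var(masks)
            if best is None or v > best[0]:
                best = (v, t1)
    t1 = best[1]
    mask = np.asarray(values, dtype=float) <= t1
    return mask, float(flat[flat <= t1].mean())


def oracle_bin_particles(volumes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per-particle loop placing each volume into [edge_i, edge_{i+1});
    the top edge is inclusive, matching histogram convention."""
    counts = np.zeros(edges.size - 1, dtype=int)
    for v in volumes:
        if v < edges[0] or v > edges[-1]:
            continue
        if v == edges[-1]:
            counts[-1] += 1
            continue
        lo, hi = 0, edges.size - 2
        while lo < hi:
            mid = (lo + hi) // 2
            if v < edges[mid + 1]:
                hi = mid
            else:
                lo = mid + 1
        counts[lo] += 1
    return counts
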