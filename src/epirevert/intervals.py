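"""Sorted, merged genomic interval arithmetic on (N, 2) integer arrays.

All coordinates are 0-based half-open.  An interval set for one chromosome is
a numpy array of shape (N, 2) with non-overlapping rows sorted by start; the
empty set is a (0, 2) array.  These primitives back the bp-resolution context
partition and the Monte-Carlo enrichment sampler, both of which need
vectorised membership queries rather than a tree structure.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_intervals",
    "merge",
    "expand",
    "subtract",
    "complement",
    "total_length",
    "overlap_bp",
    "overlaps_point_set",
    "overlaps_any",
]


def as_intervals(pairs) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (N, 2) int64 array."""
    arr = np.asarray(list(pairs), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (start, end) pairs")
    if np.any(arr[:, 1] <= arr[:, 0]):
        bad = arr[arr[:, 1] <= arr[:, 0]][0]
        raise ValueError(f"interval end <= start: {tuple(bad)}")
    return arr


def merge(iv: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or touching intervals."""
    iv = as_intervals(iv)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def expand(iv: np.ndarray, flank: int, chrom_length: int) -> np.ndarray:
    """Widen each interval by `flank` bp on both sides, clipped to the chromosome."""
    iv = as_intervals(iv)
    if len(iv) == 0:
        return iv
    widened = np.stack(
        [np.maximum(iv[:, 0] - flank, 0), np.minimum(iv[:, 1] + flank, chrom_length)],
        axis=1,
    )
    return merge(widened)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b; both inputs must be merged/sorted."""
    a = as_intervals(a)
    b = as_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append([cur, bs])
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append([cur, e])
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(out, dtype=np.int64)


def complement(iv: np.ndarray, chrom_length: int) -> np.ndarray:
    """Gaps of a merged interval set within [0, chrom_length)."""
    return subtract(np.array([[0, chrom_length]], dtype=np.int64), merge(iv))


def total_length(iv: np.ndarray) -> int:
    iv = as_intervals(iv)
    if len(iv) == 0:
        return 0
    return int(np.sum(iv[:, 1] - iv[:, 0]))


def overlap_bp(start: int, end: int, iv: np.ndarray) -> int:
    """Total bp of [start, end) covered by the merged set `iv`."""
    iv = as_intervals(iv)
    if len(iv) == 0 or end <= start:
        return 0
    lo = np.maximum(iv[:, 0], start)
    hi = np.minimum(iv[:, 1], end)
    return int(np.sum(np.maximum(hi - lo, 0)))


def overlaps_point_set(positions: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Boolean mask: which single-bp positions fall inside the merged set."""
    iv = as_intervals(iv)
    positions = np.asarray(positions)
    if len(iv) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(positions), dtype=bool)
    res[ok] = positions[ok] < iv[idx[ok], 1]
    return res


def overlaps_any(starts, ends, iv: np.ndarray) -> np.ndarray:
    """Half-open overlap test of many query regions against a merged set.

    A shared endpoint does not count as an overlap.  Vectorised: for merged,
    sorted intervals the only candidate overlapping a query [s, e) is the
    interval with the greatest start < e.
    """
    iv = as_intervals(iv)
    starts = np.atleast_1d(np.asarray(starts, dtype=np.int64))
    ends = np.atleast_1d(np.asarray(ends, dtype=np.int64))
    if len(iv) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(iv[:, 0], ends, side="left") - 1
    ok = idx >= 0
    res = np.zeros(len(starts), dtype=bool)
    res[ok] = iv[idx[ok], 1] > starts[ok]
    return res
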