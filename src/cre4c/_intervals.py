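"""Sorted-interval primitives shared by the overlap-based stages.

All coordinates are 0-based half-open integers, as in BED. The query
structure answers "does this interval overlap anything in the set by at
least ``min_overlap`` bp" in O(log n) per query via a searchsorted over
reference starts plus a running maximum over reference ends, which keeps
the 10,000-permutation null of the enrichment stage vectorizable.
"""

from __future__ import annotations

import numpy as np


def as_interval_array(regions) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs / a DataFrame to an (n, 2) int array."""
    if hasattr(regions, "columns"):  # DataFrame-like
        arr = np.asarray(regions[["start", "end"]], dtype=np.int64)
    else:
        arr = np.asarray([(int(r[0]), int(r[1])) for r in regions], dtype=np.int64)
        arr = arr.reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("intervals must satisfy start < end")
    return arr


def merge_overlapping(intervals) -> np.ndarray:
    """Merge strictly intersecting intervals (abutting intervals stay separate)."""
    iv = as_interval_array(intervals)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


class IntervalIndex:
    """Static overlap index over a set of reference intervals."""

    def __init__(self, intervals):
        iv = as_interval_array(intervals)
        order = np.argsort(iv[:, 0], kind="stable") if len(iv) else np.array([], int)
        self.starts = iv[order, 0] if len(iv) else np.array([], np.int64)
        self.ends = iv[order, 1] if len(iv) else np.array([], np.int64)
        # running max of ends over the start-sorted references
        self.cummax_ends = (
            np.maximum.accumulate(self.ends) if len(iv) else np.array([], np.int64)
        )

    def __len__(self) -> int:
        return len(self.starts)

    def overlaps_any(self, starts, ends, min_overlap: int = 1) -> np.ndarray:
        """Boolean array: query i intersects some reference by >= min_overlap bp.

        Works on arbitrarily shaped (broadcast-compatible) start/end arrays,
        which is what lets permutation nulls run as one vectorized call.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1 bp")
        if len(self) == 0:
            return np.zeros(np.broadcast(starts, ends).shape, dtype=bool)
        if min_overlap == 1:
            # exact for 1 bp: [rs, re) meets [s, e)  <=>  rs < e and re > s
            idx = np.searchsorted(self.starts, ends - 1, side="right")
            hit = idx > 0
            safe = np.maximum(idx - 1, 0)
            hit &= self.cummax_ends[safe] >= starts + 1
            return hit
        return self._overlaps_any_exact(starts, ends, min_overlap)

    def _overlaps_any_exact(self, starts, ends, min_overlap: int) -> np.ndarray:
        shape = np.broadcast(starts, ends).shape
        s_flat = np.broadcast_to(starts, shape).ravel()
        e_flat = np.broadcast_to(ends, shape).ravel()
        out = np.zeros(s_flat.shape, dtype=bool)
        for i, (s, e) in enumerate(zip(s_flat, e_flat)):
            hi = np.searchsorted(self.starts, e, side="left")
            if hi == 0:
                continue
            inter = np.minimum(self.ends[:hi], e) - np.maximum(self.starts[:hi], s)
            out[i] = bool(np.any(inter >= min_overlap))
        return out.reshape(shape)
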