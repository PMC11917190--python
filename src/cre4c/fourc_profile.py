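"""Viewpoint-profile processing: counts per fragment end, normalization,
running-window smoothing, 5 kb binning and replicate QC.

A profile holds one value per *valid* fragment end in genomic order.  A
valid fragment has exactly one NlaIII-derived end (its flanking enzymes
differ), so profile arrays are one value per valid fragment, anchored at
the NlaIII-side boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import read_bed, read_bedgraph, write_bedgraph
from .restriction_map import FragmentMap


@dataclass
class ViewpointProfile:
    """Per-fragment-end 4C counts for one replicate, plus derived tracks."""

    fmap: FragmentMap
    replicate: str
    raw: np.ndarray
    normalized: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    dropped_records: int = 0

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.fmap.valid_indices()):
            raise ValueError("raw counts must align to the map's valid fragment ends")
        if np.any(self.raw < 0):
            raise ValueError("counts must be non-negative")

    @property
    def distances(self) -> np.ndarray:
        """Signed bp from the viewpoint, per valid fragment end (anchor-based)."""
        if self.fmap.viewpoint is None:
            raise ValueError("fragment map has no viewpoint set")
        return self.fmap.anchors() - self.fmap.viewpoint

    def to_bedgraph(self, path, track: str = "raw") -> None:
        values = getattr(self, track)
        if values is None:
            raise ValueError(f"track {track!r} not computed yet")
        iv = self.fmap.valid_intervals()
        write_bedgraph(
            pd.DataFrame(
                {"chrom": self.fmap.chrom, "start": iv[:, 0], "end": iv[:, 1], "value": values}
            ),
            path,
        )


@dataclass
class BinnedCounts:
    """Fixed-width bins tiling a symmetric window around the viewpoint."""

    edges: np.ndarray  # length n_bins + 1
    values: np.ndarray
    viewpoint: int
    bin_size: int

    def to_frame(self, chrom: str = "chr1") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": self.edges[:-1],
                "end": self.edges[1:],
                "value": self.values,
            }
        )


class CorrelationResult(NamedTuple):
    r: float
    n: int


def window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-index half-widths of a centered running window of ``window`` points.

    An even window is centered as floor(w/2) left + (w - floor(w/2) - 1)
    right + self.  Near the array edges the window shrinks symmetrically
    (truncated equally on both sides) so every index keeps a defined value.
    """
    left = window // 2
    right = window - left - 1
    idx = np.arange(n)
    shrink = np.maximum(0, np.maximum(left - idx, right - (n - 1 - idx)))
    return np.maximum(0, left - shrink), np.maximum(0, right - shrink)


def load_counts(path, fmap: FragmentMap, replicate: str = "rep", fmt: str | None = None) -> ViewpointProfile:
    """Assign bedGraph values (or BED read positions) to valid fragment ends.

    bedGraph records are assigned by their midpoint, BED records by their
    start position.  Records landing in invalid fragments or outside the
    map are dropped and counted in ``dropped_records``.
    """
    path = str(path)
    if fmt is None:
        fmt = "bed" if path.endswith(".bed") else "bedgraph"
    if fmt == "bedgraph":
        df = read_bedgraph(path)
        positions = ((df["start"] + df["end"]) // 2).to_numpy()
        weights = df["value"].to_numpy(dtype=float)
    elif fmt == "bed":
        df = read_bed(path)
        positions = df["start"].to_numpy()
        weights = np.ones(len(df))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    chrom_ok = (df["chrom"] == fmap.chrom).to_numpy()

    starts = np.asarray([f.start for f in fmap.fragments])
    ends = np.asarray([f.end for f in fmap.fragments])
    full_to_valid = np.full(len(fmap), -1, dtype=int)
    full_to_valid[fmap.valid_indices()] = np.arange(len(fmap.valid_indices()))

    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = np.clip(idx, 0, len(fmap) - 1)
    inside = chrom_ok & (positions >= starts[idx]) & (positions < ends[idx])
    vpos = np.where(inside, full_to_valid[idx], -1)

    raw = np.zeros(len(fmap.valid_indices()))
    keep = vpos >= 0
    np.add.at(raw, vpos[keep], weights[keep])
    dropped = int(np.sum(~keep))
    if dropped:
        logging.getLogger("cre4c").warning(
            "%s: %d records dropped (invalid fragments or outside the map)", path, dropped
        )
    return ViewpointProfile(fmap=fmap, replicate=replicate, raw=raw, dropped_records=dropped)


def normalize(profile: ViewpointProfile, target_total: float = 1e6) -> ViewpointProfile:
    """Library-size scaling: normalized_i = raw_i * target_total / sum(raw)."""
    total = float(profile.raw.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return replace(profile, normalized=profile.raw * (target_total / total))


def smooth(profile: ViewpointProfile, window: int = 30) -> ViewpointProfile:
    """Mean running window over ``window`` fragment ends (centered)."""
    if profile.normalized is None:
        raise ValueError("normalize the profile before smoothing")
    n = len(profile.normalized)
    if n < window:
        raise ValueError(f"profile has {n} fragment ends, fewer than window={window}")
    left, right = window_bounds(n, window)
    csum = np.concatenate([[0.0], np.cumsum(profile.normalized)])
    idx = np.arange(n)
    sums = csum[idx + right + 1] - csum[idx - left]
    return replace(profile, smoothed=sums / (left + right + 1))


def bin_counts(
    profile: ViewpointProfile,
    bin_size: int = 5000,
    span: int = 1_000_000,
    track: str = "normalized",
) -> BinnedCounts:
    """Sum counts into fixed-width bins over viewpoint +/- span.

    Each valid fragment end contributes to the bin containing the midpoint
    of its fragment interval; ends outside the window are ignored.
    """
    if span % bin_size != 0:
        raise ValueError("span must be a multiple of the bin size")
    values = getattr(profile, track)
    if values is None:
        raise ValueError(f"track {track!r} not computed yet")
    vp = profile.fmap.viewpoint
    if vp is None:
        raise ValueError("fragment map has no viewpoint set")
    n_bins = 2 * span // bin_size
    edges = vp - span + bin_size * np.arange(n_bins + 1)
    iv = profile.fmap.valid_intervals()
    mids = (iv[:, 0] + iv[:, 1]) // 2
    in_window = (mids >= edges[0]) & (mids < edges[-1])
    binned = np.zeros(n_bins)
    which = (mids[in_window] - edges[0]) // bin_size
    np.add.at(binned, which.astype(int), values[in_window])
    return BinnedCounts(edges=edges, values=binned, viewpoint=vp, bin_size=bin_size)


def replicate_correlation(a: BinnedCounts, b: BinnedCounts) -> CorrelationResult:
    """Pearson correlation between two identically binned replicates.

    Returns NaN (rather than raising) when either vector has zero
    variance, flagging the correlation as undefined.
    """
    if len(a.values) != len(b.values) or not np.array_equal(a.edges, b.edges):
        raise ValueError("binned vectors must share the same binning")
    n = len(a.values)
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        return CorrelationResult(float("nan"), n)
    r, _ = stats.pearsonr(a.values, b.values)
    return CorrelationResult(float(r), n)
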