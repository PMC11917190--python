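"""Fixed-width rebinning of scored region sets and pairwise Pearson correlation.

Each sample's region scores are converted to standardized percentiles
(average-tie rank / n, in (0, 1]); every 100 bp bin a region overlaps
receives the region's percentile (maximum on collision).  Bins covered by
no sample are dropped, and Pearson's r is computed between each pair of
samples over the retained bins, with an average-linkage clustering order
for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


def n_bins(chrom_length: int, width: int = 100) -> int:
    """Number of fixed-width bins tiling a chromosome (ceiling convention)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    return math.ceil(chrom_length / width)


@dataclass
class BinMatrix:
    """samples x bins matrix of standardized percentiles in [0, 1]."""

    values: sparse.csr_matrix
    samples: list[str]
    width: int
    chrom_length: int
    bin_ids: np.ndarray  # original bin indices of the retained columns

    @property
    def sparsity(self) -> float:
        """Fraction of zero entries."""
        total = self.values.shape[0] * self.values.shape[1]
        return 1.0 - self.values.nnz / total if total else 1.0


def rebin(samples: dict[str, pd.DataFrame], chrom_length: int, width: int = 100) -> BinMatrix:
    """Fill per-sample bins with the percentile rank of each region's score.

    ``samples`` maps a sample name to a DataFrame with start/end/score
    columns; regions must lie within [0, chrom_length) and carry
    non-negative scores.
    """
    total_bins = n_bins(chrom_length, width)
    names = list(samples)
    rows = []
    for name in names:
        df = samples[name]
        dense = np.zeros(total_bins)
        if len(df):
            starts = df["start"].to_numpy(dtype=np.int64)
            ends = df["end"].to_numpy(dtype=np.int64)
            scores = df["score"].to_numpy(dtype=float)
            if np.any(scores < 0):
                raise ValueError(f"sample {name!r} has negative scores")
            if np.any(starts < 0) or np.any(ends > chrom_length):
                raise ValueError(f"sample {name!r} has regions outside [0, chrom_length)")
            pct = rankdata(scores, method="average") / len(scores)
            for s, e, p in zip(starts, ends, pct):
                b0, b1 = s // width, (e - 1) // width
                seg = dense[b0 : b1 + 1]
                np.maximum(seg, p, out=seg)
        rows.append(sparse.csr_matrix(dense))
    values = sparse.vstack(rows).tocsr() if rows else sparse.csr_matrix((0, total_bins))
    return BinMatrix(
        values=values,
        samples=names,
        width=width,
        chrom_length=chrom_length,
        bin_ids=np.arange(total_bins),
    )


def drop_empty(matrix: BinMatrix) -> BinMatrix:
    """Remove bins no sample overlaps; error if nothing remains."""
    col_nnz = matrix.values.getnnz(axis=0)
    keep = np.flatnonzero(col_nnz > 0)
    if keep.size == 0:
        raise ValueError("all bins are empty: no sample overlaps any bin")
    return BinMatrix(
        values=matrix.values[:, keep].tocsr(),
        samples=matrix.samples,
        width=matrix.width,
        chrom_length=matrix.chrom_length,
        bin_ids=matrix.bin_ids[keep],
    )


def pearson_matrix(matrix: BinMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson r over retained bins, plus a display clustering order.

    Zero-variance samples yield NaN correlations (reported as missing);
    the hierarchical clustering (average linkage on 1 - r) is computed on
    the remaining samples and NaN samples are appended at the end of the
    order.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    dense = np.asarray(matrix.values.todense(), dtype=float)
    if dense.shape[1] < 2:
        raise ValueError("need at least two retained bins")
    sd = dense.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dense)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    df = pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)

    ok = np.flatnonzero(sd > 0)
    order: list[str]
    if len(ok) >= 2:
        sub = np.clip(corr[np.ix_(ok, ok)], -1.0, 1.0)
        dist = squareform(1.0 - sub, checks=False)
        link = hierarchy.linkage(dist, method="average")
        leaves = hierarchy.leaves_list(link)
        order = [matrix.samples[ok[i]] for i in leaves]
    else:
        order = [matrix.samples[i] for i in ok]
    order += [matrix.samples[i] for i in range(len(matrix.samples)) if i not in set(ok)]
    return df, order
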