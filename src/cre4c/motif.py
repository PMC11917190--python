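"""De novo k-mer over-representation analysis of pCRE sequences.

Classical oligo-analysis: overlapping k-mer occurrences (k = 6 and 7 by
default) are counted on both strands and collapsed to a canonical form
(the lexicographic minimum of the k-mer and its reverse complement); each
canonical k-mer's observed count is compared with its expectation under an
order-0 background by an upper-tail binomial test, and p-values are
corrected to E-values by the number of possible canonical k-mers tested.
Significant oligos are greedily assembled into consensus count matrices by
longest exact overlap.

Dependencies between overlapping occurrences are ignored, as in classical
oligo-analysis; the binomial tail is therefore an approximation for
self-overlapping oligos (e.g. homopolymers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def n_canonical_kmers(k: int) -> int:
    """Number of distinct canonical k-mers (palindromes counted once)."""
    total = 4**k
    palindromes = 4 ** (k // 2) if k % 2 == 0 else 0
    return (total + palindromes) // 2


@dataclass
class OligoEnrichment:
    oligo: str  # canonical form
    observed: int
    expected: float
    p_value: float
    e_value: float


@dataclass
class ConsensusMatrix:
    """Position x {A,C,G,T} counts assembled from overlapping oligos."""

    counts: np.ndarray  # (width, 4)
    members: list[str]

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def to_transfac(self, name: str = "motif") -> str:
        lines = [f"ID {name}", "BF synthetic", "P0\tA\tC\tG\tT"]
        for i, row in enumerate(self.counts, start=1):
            lines.append(f"{i:02d}\t" + "\t".join(str(int(c)) for c in row))
        lines.append("XX")
        lines.append("//")
        return "\n".join(lines)

    def to_meme(self, name: str = "motif") -> str:
        total = self.counts.sum(axis=1, keepdims=True)
        freq = np.divide(self.counts, total, out=np.full_like(self.counts, 0.25, dtype=float),
                         where=total > 0)
        lines = [
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width}",
        ]
        for row in freq:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines)


def count_oligos(sequences: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    """Canonical k-mer counts over both strands of the input sequences.

    Overlapping occurrences are all counted; windows containing N are
    skipped.  Returns (counts, number of scanned windows over both
    strands), the latter being the number of binomial trials downstream.
    """
    counts: dict[str, int] = {}
    n_positions = 0
    for seq in sequences:
        seq = seq.upper()
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if "N" in kmer:
                    continue
                n_positions += 1
                c = canonical(kmer)
                counts[c] = counts.get(c, 0) + 1
    return counts, n_positions


def background_from_sequences(sequences: Iterable[str]) -> dict[str, float]:
    """Order-0 background: single-base frequencies pooled over both strands.

    Pooling with the reverse complement makes the background strand
    symmetric (freq(A) = freq(T), freq(C) = freq(G)).
    """
    tallies = {b: 0 for b in BASES}
    for seq in sequences:
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            for b in BASES:
                tallies[b] += s.count(b)
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("no A/C/G/T content in the input sequences")
    return {b: tallies[b] / total for b in BASES}


UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}


def _kmer_prob(kmer: str, background: dict[str, float]) -> float:
    p = 1.0
    for b in kmer:
        p *= background[b]
    return p


def oligo_enrichment(
    counts: dict[str, int],
    n_positions: int,
    background: dict[str, float] | None = None,
    k: int | None = None,
) -> list[OligoEnrichment]:
    """Upper-tail binomial over-representation test per canonical k-mer.

    For canonical class c = {w, revcomp(w)} the per-window emission
    probability is P(w) + P(revcomp(w)) (just P(w) for palindromes) and the
    expectation is reported on the both-strand counting scale,
    expected = n_positions * prob.  The tail test is computed on the
    *genomic occurrence* scale: scanning both strands counts every
    occurrence twice, so treating the doubled count as binomial would
    double the variance and wreck calibration.  With W = n_positions / 2
    distinct windows and G = observed / 2 occurrences,
    p = P(X >= G) for X ~ Binomial(W, prob); E-value = p x number of
    possible canonical k-mers.  Results are sorted by E-value.
    """
    if not counts:
        return []
    if background is None:
        background = UNIFORM_BACKGROUND
    if abs(sum(background.values()) - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    if k is None:
        k = len(next(iter(counts)))
    n_tested = n_canonical_kmers(k)
    out = []
    for oligo, obs in counts.items():
        rc = revcomp(oligo)
        prob = _kmer_prob(oligo, background)
        if rc != oligo:
            prob += _kmer_prob(rc, background)
        if prob <= 0:
            raise ValueError(
                f"degenerate background: observed oligo {oligo!r} has zero expectation"
            )
        expected = n_positions * prob
        n_windows = max(1, n_positions // 2)
        g = (obs + 1) // 2
        p = float(binom.sf(g - 1, n_windows, prob))
        out.append(
            OligoEnrichment(
                oligo=oligo,
                observed=obs,
                expected=float(expected),
                p_value=p,
                e_value=float(min(p * n_tested, np.inf)),
            )
        )
    out.sort(key=lambda r: (r.e_value, r.oligo))
    return out


def enrichment_to_frame(results: Sequence[OligoEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oligo": [r.oligo for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "p_value": [r.p_value for r in results],
            "e_value": [r.e_value for r in results],
        }
    )


def _oligo_matrix(oligo: str, weight: int) -> np.ndarray:
    m = np.zeros((len(oligo), 4))
    for i, b in enumerate(oligo):
        m[i, BASES.index(b)] = weight
    return m


def _matrix_revcomp(m: np.ndarray) -> np.ndarray:
    return m[::-1, ::-1].copy()  # reverse positions, swap A<->T and C<->G


def _best_overlap(a: str, b: str, min_overlap: int) -> tuple[int, int, bool] | None:
    """Longest exact suffix-prefix overlap between consensus strings.

    Returns (overlap length, offset of b relative to a, b reverse-complemented?)
    or None.  Both orientations of b are considered; ties prefer forward.
    """
    best = None
    for flipped, bb in ((False, b), (True, revcomp(b))):
        max_o = min(len(a), len(bb))
        for o in range(max_o, min_overlap - 1, -1):
            if a[len(a) - o :] == bb[:o]:  # b extends a to the right
                cand = (o, len(a) - o, flipped)
                if best is None or cand[0] > best[0]:
                    best = cand
                break
        for o in range(max_o, min_overlap - 1, -1):
            if bb[len(bb) - o :] == a[:o]:  # b extends a to the left
                cand = (o, o - len(bb), flipped)
                if best is None or cand[0] > best[0]:
                    best = cand
                break
    return best


def assemble_matrices(
    oligos: dict[str, int] | Sequence[str],
    min_overlap: int | None = None,
) -> list[ConsensusMatrix]:
    """Greedy agglomeration of significant oligos into consensus matrices.

    Repeatedly merges the pair of current matrices with the longest exact
    consensus overlap >= ``min_overlap`` (default: shortest oligo length
    minus 2), weighting columns by observed counts and considering both
    orientations; unmergeable oligos end up as singleton matrices.
    """
    if not isinstance(oligos, dict):
        oligos = {o: 1 for o in oligos}
    if not oligos:
        return []
    if min_overlap is None:
        min_overlap = max(1, min(len(o) for o in oligos) - 2)
    items = [
        ConsensusMatrix(counts=_oligo_matrix(o, w), members=[o])
        for o, w in sorted(oligos.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    while len(items) > 1:
        best = None  # (overlap, i, j, offset, flipped)
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                hit = _best_overlap(items[i].consensus, items[j].consensus, min_overlap)
                if hit and (best is None or hit[0] > best[0]):
                    best = (hit[0], i, j, hit[1], hit[2])
        if best is None:
            break
        _, i, j, offset, flipped = best
        a, b = items[i], items[j]
        b_counts = _matrix_revcomp(b.counts) if flipped else b.counts
        start = min(0, offset)
        width = max(a.width, offset + b_counts.shape[0]) - start
        merged = np.zeros((width, 4))
        merged[-start : -start + a.width] += a.counts
        merged[offset - start : offset - start + b_counts.shape[0]] += b_counts
        items[i] = ConsensusMatrix(counts=merged, members=a.members + b.members)
        del items[j]
    return items
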