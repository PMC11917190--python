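"""In-silico NlaIII/DpnII double digestion and fragment-map filtering.

4C-seq signal is anchored on the restriction fragments of the primary
(NlaIII) / secondary (DpnII) digest.  This module scans a genome for the
two recognition motifs, converts them to cut positions, tiles the
chromosome into fragments labelled by their flanking enzymes, and flags
which fragments are usable for viewpoint analysis: a fragment is *blind*
(uninformative) when both flanks carry the same enzyme, too short below a
minimum length, or too close to the viewpoint where self-ligation
artefacts dominate.

Coordinates are 0-based half-open throughout; fragment maps round-trip
through BED6+3 (extra columns: left enzyme, right enzyme, valid flag).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

CHROM_EDGE = "chrom_edge"

#: recognition motif and cut offset in bp from the motif start.  NlaIII
#: cuts after its CATG (leaving a 3' CATG overhang), DpnII cuts in front
#: of its GATC (5' GATC overhang), so fragment ends carry the motif as in
#: real 4C libraries.
ENZYMES: dict[str, tuple[str, int]] = {
    "NlaIII": ("CATG", 4),
    "DpnII": ("GATC", 0),
}


@dataclass(frozen=True)
class RestrictionSite:
    """One occurrence of a recognition motif on the forward strand."""

    chrom: str
    pos: int  # 0-based start of the motif occurrence
    enzyme: str


@dataclass
class Fragment:
    chrom: str
    start: int
    end: int
    left_enzyme: str
    right_enzyme: str
    valid: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def is_blind(self) -> bool:
        """Same enzyme on both flanks, or a chromosome edge: uninformative in 4C."""
        return (
            self.left_enzyme == self.right_enzyme
            or CHROM_EDGE in (self.left_enzyme, self.right_enzyme)
        )


@dataclass
class FragmentMap:
    """Ordered, gap-free tiling of a chromosome by restriction fragments."""

    chrom: str
    fragments: list[Fragment]
    viewpoint: int | None = None
    enzymes: tuple[str, str] = ("NlaIII", "DpnII")
    genome_id: str | None = None

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    @property
    def span(self) -> tuple[int, int]:
        return self.fragments[0].start, self.fragments[-1].end

    def valid_indices(self) -> np.ndarray:
        return np.asarray([i for i, f in enumerate(self.fragments) if f.valid], int)

    def valid_fragments(self) -> list[Fragment]:
        return [f for f in self.fragments if f.valid]

    def valid_intervals(self) -> np.ndarray:
        """(n, 2) start/end array over valid fragments, genomic order."""
        return np.asarray([(f.start, f.end) for f in self.fragments if f.valid], int).reshape(-1, 2)

    def anchors(self) -> np.ndarray:
        """NlaIII-side boundary of each valid fragment.

        A valid fragment has different enzymes on its two flanks, hence
        exactly one end derived from the primary enzyme; 4C reads are
        accounted per such fragment end and distances to the viewpoint are
        measured from this anchor.
        """
        primary = self.enzymes[0]
        out = []
        for f in self.fragments:
            if not f.valid:
                continue
            out.append(f.start if f.left_enzyme == primary else f.end)
        return np.asarray(out, dtype=np.int64)

    def fragment_index_at(self, pos: int) -> int:
        """Index of the fragment containing ``pos`` or -1 if outside the span."""
        starts = np.asarray([f.start for f in self.fragments])
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self.fragments[i].end:
            return -1
        return i

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": [f.start for f in self.fragments],
                "end": [f.end for f in self.fragments],
                "name": [f"frag{i}" for i in range(len(self.fragments))],
                "score": 0,
                "strand": ".",
                "left_enzyme": [f.left_enzyme for f in self.fragments],
                "right_enzyme": [f.right_enzyme for f in self.fragments],
                "valid": [int(f.valid) for f in self.fragments],
            }
        )

    def to_bed(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, viewpoint: int | None = None) -> "FragmentMap":
        cols = [
            "chrom", "start", "end", "name", "score", "strand",
            "left_enzyme", "right_enzyme", "valid",
        ]
        df = pd.read_csv(path, sep="\t", header=None, names=cols)
        frags = [
            Fragment(r.chrom, int(r.start), int(r.end), r.left_enzyme,
                     r.right_enzyme, bool(int(r.valid)))
            for r in df.itertuples()
        ]
        return cls(chrom=str(df["chrom"].iloc[0]), fragments=frags, viewpoint=viewpoint)


def find_sites(seq: str, enzyme: str, chrom: str = "chr1") -> list[RestrictionSite]:
    """All forward-strand occurrences of the enzyme's recognition motif.

    CATG and GATC are palindromic, so one strand suffices.  Overlapping
    occurrences are all reported; N never matches.
    """
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}")
    motif = ENZYMES[enzyme][0]
    s = seq.upper()
    return [
        RestrictionSite(chrom, m.start(), enzyme)
        for m in re.finditer(f"(?={motif})", s)
    ]


def digest(
    seq: str,
    chrom: str = "chr1",
    primary: str = "NlaIII",
    secondary: str = "DpnII",
    genome_id: str | None = None,
) -> FragmentMap:
    """Double-digest a chromosome into an ordered fragment map.

    Cut positions are the union of both enzymes' cut points plus the two
    chromosome edges; fragments are the intervals between consecutive cut
    positions and carry the enzyme label of each bounding cut.  When an
    NlaIII cut (motif end) coincides with a DpnII cut (motif start), the
    left-hand fragment is flanked by NlaIII and the right-hand one by DpnII.
    """
    length = len(seq)
    if length == 0:
        raise ValueError("cannot digest an empty genome")
    # cut position -> [label of left flank, label of right flank]
    cuts: dict[int, list[str]] = {0: [CHROM_EDGE, CHROM_EDGE], length: [CHROM_EDGE, CHROM_EDGE]}
    for enz in (primary, secondary):
        _, offset = ENZYMES[enz]
        for site in find_sites(seq, enz, chrom):
            c = site.pos + offset
            if not 0 <= c <= length:
                continue
            entry = cuts.get(c)
            if entry is None:
                cuts[c] = [enz, enz]
            elif offset > 0:  # motif lies left of the cut: owns the left flank
                entry[0] = enz
            else:
                entry[1] = enz
    bounds = sorted(cuts)
    fragments = [
        Fragment(chrom, b0, b1, cuts[b0][1], cuts[b1][0])
        for b0, b1 in zip(bounds[:-1], bounds[1:])
    ]
    return FragmentMap(
        chrom=chrom, fragments=fragments, enzymes=(primary, secondary), genome_id=genome_id
    )


def filter_fragments(
    fmap: FragmentMap,
    viewpoint: int,
    min_len: int = 40,
    exclusion: int = 5000,
    exclusion_mode: str = "any_overlap",
) -> FragmentMap:
    """Set validity flags; nothing is deleted so the audit trail is complete.

    A fragment is valid iff it is non-blind (different, non-edge flanking
    enzymes), at least ``min_len`` bp long ("smaller than 40 bp" removes
    only < 40), and clear of the viewpoint exclusion zone.  With the
    default ``any_overlap`` mode a fragment is excluded when any part of
    it intersects [viewpoint - exclusion, viewpoint + exclusion); the
    ``midpoint`` mode excludes on the fragment midpoint only.
    """
    if min_len < 0 or exclusion < 0:
        raise ValueError("min_len and exclusion must be non-negative")
    if exclusion_mode not in ("any_overlap", "midpoint"):
        raise ValueError(f"unknown exclusion_mode {exclusion_mode!r}")
    lo, hi = viewpoint - exclusion, viewpoint + exclusion
    out = []
    for f in fmap.fragments:
        if exclusion_mode == "any_overlap":
            near_vp = f.start < hi and f.end > lo
        else:
            near_vp = lo <= f.midpoint < hi
        valid = (not f.is_blind) and f.length >= min_len and not near_vp
        out.append(Fragment(f.chrom, f.start, f.end, f.left_enzyme, f.right_enzyme, valid))
    return FragmentMap(
        chrom=fmap.chrom,
        fragments=out,
        viewpoint=viewpoint,
        enzymes=fmap.enzymes,
        genome_id=fmap.genome_id,
    )
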