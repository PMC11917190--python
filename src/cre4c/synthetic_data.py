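"""Synthetic genomes, 4C count profiles and ChIP peak sets with ground truth.

The generator emulates the data-generating situation of a one-viewpoint
4C experiment: a random genome carrying NlaIII/DpnII sites at controlled
densities, a contact profile that decays monotonically with distance from
the viewpoint with negative-binomial replicate noise, planted interaction
peaks at known coordinates, and ChIP peak sets with a controlled fraction
of peaks overlapping a designated query set.  Every downstream stage of
the pipeline is testable against the emitted ground truth (``SimTruth``)
without any external data.

Restriction-site counts are controlled exactly: the background sequence is
scrubbed of natural CATG/GATC occurrences and a binomially sampled number
of motifs is planted by substitution at sampled positions, so the observed
site count per enzyme is the planted one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fourc_profile import ViewpointProfile
from .io import write_fasta
from .restriction_map import ENZYMES, FragmentMap, filter_fragments

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MOTIFS = {name: np.frombuffer(m.encode(), dtype=np.uint8) for name, (m, _) in ENZYMES.items()}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults give ~2,000 valid fragments in a centered 1.2 Mb genome with
    an amplitude-100 contact decay and overdispersed (NB, k=5) counts in
    two replicates.
    """

    genome_length: int = 1_200_000
    site_rate_primary: float = 2.0  # expected NlaIII sites per kb
    site_rate_secondary: float = 2.0  # expected DpnII sites per kb
    viewpoint_pos: int = 600_000
    decay_amplitude: float = 100.0  # expected counts at distance 0
    decay_exponent: float = 1.0
    decay_scale: float = 50_000.0  # bp
    planted_interactions: tuple = ()  # (center bp, half-width in fragments, fold)
    nb_dispersion: float = 5.0  # variance = mu + mu^2/k; k -> inf is Poisson
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.decay_amplitude <= 0 or self.decay_scale <= 0 or self.decay_exponent <= 0:
            raise ValueError("decay parameters must be positive")
        if not (self.nb_dispersion > 0):
            raise ValueError("nb_dispersion must be positive (use math.inf for Poisson)")
        if self.n_replicates < 2:
            raise ValueError("interaction calling requires at least two replicates")
        for center, half_width, fold in self.planted_interactions:
            if fold < 1:
                raise ValueError("fold-enhancement must be >= 1")
            if not 0 <= center < self.genome_length:
                raise ValueError("planted interaction center outside the genome")
            if half_width < 0:
                raise ValueError("half-width must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for parameter-recovery tests."""

    planted_regions: list  # genomic intervals, 0-based half-open
    enrichment_design: dict = field(default_factory=dict)
    seed: int = 0
    expected_means: np.ndarray | None = None  # per valid fragment end

    def to_json(self, path) -> None:
        payload = {
            "planted_regions": [[int(s), int(e)] for s, e in self.planted_regions],
            "enrichment_design": self.enrichment_design,
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _find_occurrences(arr: np.ndarray, motif: np.ndarray) -> np.ndarray:
    """Start positions of every (possibly overlapping) motif occurrence."""
    if len(arr) < len(motif):
        return np.array([], dtype=int)
    hit = arr[: len(arr) - len(motif) + 1] == motif[0]
    for j in range(1, len(motif)):
        hit &= arr[j : len(arr) - len(motif) + 1 + j] == motif[j]
    return np.flatnonzero(hit)


def _scrub_motifs(arr: np.ndarray, protected: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate bases until no unplanted CATG/GATC occurrence remains.

    Each offending occurrence has at least one unprotected base (planted
    motifs never combine into a new protected occurrence); that base is
    substituted, preferring a substitution that creates no motif in the
    local window.
    """
    motifs = list(_MOTIFS.values())
    for _ in range(200):
        dirty = False
        for motif in motifs:
            for i in _find_occurrences(arr, motif):
                if protected[i : i + 4].all():
                    continue  # a planted site
                dirty = True
                free = [j for j in range(i, i + 4) if not protected[j]]
                j = free[len(free) // 2]
                current = arr[j]
                for cand in rng.permutation(_BASES):
                    if cand == current:
                        continue
                    arr[j] = cand
                    lo, hi = max(0, i - 3), min(len(arr), i + 7)
                    window = arr[lo:hi]
                    if all(len(_find_occurrences(window, m)) == 0 or
                           _covered_by(protected, lo, _find_occurrences(window, m))
                           for m in motifs):
                        break
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")  # pragma: no cover


def _covered_by(protected: np.ndarray, offset: int, occ: np.ndarray) -> bool:
    return all(protected[offset + i : offset + i + 4].all() for i in occ)


def _plant_positions(rng: np.random.Generator, length: int, n: int, occupied: np.ndarray) -> np.ndarray:
    """Sample n motif start positions at least 4 bp apart (collisions re-sampled)."""
    out = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise ValueError("genome too short for the requested site density")
        p = int(rng.integers(0, length - 3))
        if occupied[max(0, p - 3) : p + 4].any():
            continue
        occupied[p : p + 4] = True
        out.append(p)
    return np.asarray(sorted(out), dtype=int)


def simulate_genome(config: SimConfig, fasta_path=None, chrom: str = "chr1") -> str:
    """Random A/C/G/T genome with controlled NlaIII/DpnII site densities.

    Returns the sequence; writes a FASTA when ``fasta_path`` is given.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    rng = np.random.default_rng([config.seed, 11])
    length = config.genome_length
    arr = rng.choice(_BASES, size=length)

    occupied = np.zeros(length, dtype=bool)
    protected = np.zeros(length, dtype=bool)
    for enzyme, rate in (
        ("NlaIII", config.site_rate_primary),
        ("DpnII", config.site_rate_secondary),
    ):
        n_sites = int(rng.binomial(length, min(1.0, rate / 1000.0)))
        for p in _plant_positions(rng, length, n_sites, occupied):
            arr[p : p + 4] = _MOTIFS[enzyme]
            protected[p : p + 4] = True
    _scrub_motifs(arr, protected, rng)
    seq = arr.tobytes().decode("ascii")
    if fasta_path is not None:
        write_fasta({chrom: seq}, fasta_path)
    return seq


def expected_decay(abs_distance, config: SimConfig) -> np.ndarray:
    """Background contact mean: amplitude * (1 + |d|/scale)^(-exponent)."""
    d = np.abs(np.asarray(abs_distance, dtype=float))
    return config.decay_amplitude * (1.0 + d / config.decay_scale) ** (-config.decay_exponent)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    if math.isinf(k):
        return rng.poisson(mu).astype(float)
    p = k / (k + mu)
    return rng.negative_binomial(k, p).astype(float)


def simulate_4c_counts(
    fmap: FragmentMap,
    config: SimConfig,
    outdir=None,
    cell_line: str = "sim",
) -> tuple[list[ViewpointProfile], SimTruth]:
    """Draw per-fragment-end counts for each replicate.

    The expected count of the fragment end at signed distance d from the
    viewpoint is ``decay_amplitude * (1 + |d|/decay_scale)^(-decay_exponent)``,
    multiplied by the fold-enhancement for fragments inside a planted
    interaction; replicate counts are independent negative-binomial draws.
    """
    if len(fmap) == 0:
        raise ValueError("empty fragment map")
    lo, hi = fmap.span
    if not lo <= config.viewpoint_pos < hi:
        raise ValueError("viewpoint outside the genome span")
    if fmap.viewpoint is None:
        fmap = filter_fragments(fmap, config.viewpoint_pos)
    elif fmap.viewpoint != config.viewpoint_pos:
        raise ValueError("fragment map was filtered for a different viewpoint")

    anchors = fmap.anchors()
    iv = fmap.valid_intervals()
    mu = expected_decay(anchors - config.viewpoint_pos, config)

    fold = np.ones(len(mu))
    planted_regions: list[tuple[int, int]] = []
    if len(iv):
        for center, half_width, f in config.planted_interactions:
            j = int(np.argmin(np.abs((iv[:, 0] + iv[:, 1]) // 2 - center)))
            a, b = max(0, j - half_width), min(len(mu) - 1, j + half_width)
            fold[a : b + 1] = np.maximum(fold[a : b + 1], f)
            planted_regions.append((int(iv[a, 0]), int(iv[b, 1])))
    mu_full = mu * fold

    profiles = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, 101, r])
        counts = _nb_counts(rng, mu_full, config.nb_dispersion)
        prof = ViewpointProfile(fmap=fmap, replicate=f"rep{r + 1}", raw=counts)
        profiles.append(prof)
    truth = SimTruth(
        planted_regions=planted_regions, seed=config.seed, expected_means=mu_full
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for prof in profiles:
            prof.to_bedgraph(outdir / f"{cell_line}_{prof.replicate}.bedgraph", "raw")
        truth.to_json(outdir / f"{cell_line}_truth.json")
    return profiles, truth


def pad_regions_by_fragments(regions, fmap: FragmentMap, pad_fragments: int) -> list[tuple[int, int]]:
    """Expand genomic intervals by a number of valid fragments on each side.

    Used when scoring interval recovery: a caller operating on a
    ``w``-fragment smoothed profile cannot resolve boundaries more finely
    than about w/2 fragments, so recovery is judged with that slack.
    """
    iv = fmap.valid_intervals()
    n = len(iv)
    out = []
    for s, e in regions:
        i0 = int(np.searchsorted(iv[:, 1], s, side="right"))
        i1 = int(np.searchsorted(iv[:, 0], e, side="left")) - 1
        a = max(0, min(i0, n - 1) - pad_fragments)
        b = min(n - 1, max(i1, 0) + pad_fragments)
        out.append((int(iv[a, 0]), int(iv[b, 1])))
    return out


def interval_recovery(
    pcres,
    planted_regions,
    fmap: FragmentMap,
    pad_fragments: int = 15,
) -> dict:
    """Interval-level sensitivity and precision of called pCREs vs ground truth.

    A planted interval is recovered when some pCRE overlaps it; a pCRE is
    a true call when it overlaps a planted interval padded by
    ``pad_fragments`` valid fragments (half the smoothing window by
    default, the caller's resolution limit).
    """
    from ._intervals import IntervalIndex

    called = [(p.start, p.end) for p in pcres]
    planted = [(int(s), int(e)) for s, e in planted_regions]
    if not planted:
        return {
            "sensitivity": float("nan"),
            "precision": float("nan") if not called else 0.0,
            "n_called": len(called),
            "n_planted": 0,
        }
    padded = pad_regions_by_fragments(planted, fmap, pad_fragments)
    called_idx = IntervalIndex(called) if called else None
    recovered = (
        int(
            called_idx.overlaps_any(
                np.asarray([s for s, _ in planted]), np.asarray([e for _, e in planted])
            ).sum()
        )
        if called_idx
        else 0
    )
    pad_idx = IntervalIndex(padded)
    true_calls = (
        int(
            pad_idx.overlaps_any(
                np.asarray([s for s, _ in called]), np.asarray([e for _, e in called])
            ).sum()
        )
        if called
        else 0
    )
    return {
        "sensitivity": recovered / len(planted),
        "precision": true_calls / len(called) if called else float("nan"),
        "n_called": len(called),
        "n_planted": len(planted),
    }


def simulate_chip_peaks(
    query,
    universe: tuple[int, int],
    n_peaks: int,
    overlap_fraction: float,
    width_dist: tuple[float, float] = (500.0, 150.0),
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, dict]:
    """ChIP peak set with a controlled fraction of peaks overlapping ``query``.

    ``round(n_peaks * overlap_fraction)`` peaks are placed to overlap
    distinct query regions (cycling through the query set if it is smaller);
    the remainder are placed uniformly in the universe.  Peaks carry a
    positive score in BED column 5.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    query = list(query) if query is not None else []
    if overlap_fraction > 0 and n_peaks > 0 and len(query) == 0:
        raise ValueError("cannot plant overlaps against an empty query set")
    u0, u1 = int(universe[0]), int(universe[1])
    if u1 <= u0:
        raise ValueError("empty universe")
    rng = np.random.default_rng([seed, 7])
    n_overlap = int(round(n_peaks * overlap_fraction))

    widths = np.maximum(20, rng.normal(width_dist[0], width_dist[1], size=n_peaks)).astype(int)
    widths = np.minimum(widths, u1 - u0)
    rows = []
    if n_overlap:
        order = rng.permutation(len(query))
        targets = [query[order[i % len(query)]] for i in range(n_overlap)]
    else:
        targets = []
    for i in range(n_peaks):
        w = int(widths[i])
        if i < n_overlap:
            qs, qe = int(targets[i][0]), int(targets[i][1])
            lo = max(u0, qs - w + 1)
            hi = min(u1 - w, qe - 1)
            if hi < lo:  # query pinned at a universe edge; clamp
                start = int(np.clip(qs, u0, u1 - w))
            else:
                start = int(rng.integers(lo, hi + 1))
        else:
            start = int(rng.integers(u0, u1 - w + 1))
        score = float(np.round(1.0 + rng.gamma(2.0, 10.0), 3))
        rows.append((chrom, start, start + w, f"peak{i}", score, "."))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    peaks = peaks.sort_values("start", kind="stable").reset_index(drop=True)
    truth = {
        "n_peaks": int(n_peaks),
        "overlap_fraction": float(overlap_fraction),
        "n_planted_overlapping": n_overlap,
        "seed": int(seed),
    }
    return peaks, truth
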