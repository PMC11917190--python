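"""Permutation-based overlap enrichment of pCRE classes in ChIP peak sets.

The observed statistic is the number of query regions (pCREs of one class)
overlapping at least one reference peak by >= 1 bp.  The null re-places
every query region uniformly at random within the analysis universe,
preserving lengths and allowing the placed regions to overlap each other;
the default is 10,000 permutations per comparison.  Empirical p-values use
the add-one estimator p = (1 + #{null >= obs}) / (1 + n); depletion is the
mirror-image tail.  Families of tests are corrected with Benjamini-
Hochberg FDR, and replicate results for one mark x cell x class are
aggregated as arithmetic means of z and FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._intervals import IntervalIndex, as_interval_array


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    p_enrichment: float
    p_depletion: float
    proportional_overlap: float  # fraction of query regions hit
    n_query: int
    n_permutations: int
    seed: int | None = None
    fdr: float | None = None
    labels: dict = field(default_factory=dict)


def overlap_count(query, reference) -> int:
    """Number of query regions overlapping >= 1 reference peak by >= 1 bp."""
    q = as_interval_array(query)
    if len(q) == 0:
        return 0
    index = IntervalIndex(as_interval_array(reference))
    return int(index.overlaps_any(q[:, 0], q[:, 1]).sum())


def permute_regions(query, universe: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Re-place each query region uniformly at random within the universe.

    Lengths are preserved and placed regions may overlap each other (the
    simplest exactly-specifiable null).
    """
    q = as_interval_array(query)
    u0, u1 = int(universe[0]), int(universe[1])
    lengths = q[:, 1] - q[:, 0]
    if np.any(lengths > u1 - u0):
        raise ValueError("a query region is longer than the universe")
    starts = rng.integers(u0, u1 - lengths + 1)
    return np.stack([starts, starts + lengths], axis=1)


def permutation_enrichment(
    query,
    reference,
    universe: tuple[int, int],
    n: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labels: dict | None = None,
) -> EnrichmentResult:
    """Permuted overlap enrichment test (both one-sided tails reported)."""
    q = as_interval_array(query)
    ref = as_interval_array(reference)
    if len(q) == 0 or len(ref) == 0:
        raise ValueError("query and reference must be nonempty")
    if rng is None:
        rng = np.random.default_rng(seed)
    index = IntervalIndex(ref)
    observed = int(index.overlaps_any(q[:, 0], q[:, 1]).sum())

    u0, u1 = int(universe[0]), int(universe[1])
    lengths = q[:, 1] - q[:, 0]
    if np.any(lengths > u1 - u0):
        raise ValueError("a query region is longer than the universe")
    # vectorized null: one (n x n_query) matrix of placements
    starts = rng.integers(u0, (u1 - lengths + 1)[None, :], size=(n, len(q)))
    hits = index.overlaps_any(starts, starts + lengths[None, :])
    null = hits.sum(axis=1)

    mean, sd = float(null.mean()), float(null.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    p_enr = (1.0 + int(np.sum(null >= observed))) / (1.0 + n)
    p_dep = (1.0 + int(np.sum(null <= observed))) / (1.0 + n)
    return EnrichmentResult(
        observed=observed,
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_enrichment=p_enr,
        p_depletion=p_dep,
        proportional_overlap=observed / len(q),
        n_query=len(q),
        n_permutations=n,
        seed=seed,
        labels=labels or {},
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH-correct the enrichment p-values of one invocation's test family."""
    fdrs = bh_fdr([r.p_enrichment for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return list(results)


def aggregate_replicates(results: Sequence[EnrichmentResult]) -> dict:
    """Mean z and mean FDR across the replicates of one mark x cell x class."""
    if len(results) == 0:
        raise ValueError("no replicate results to aggregate")
    zs = [r.z for r in results]
    fdrs = [r.fdr for r in results]
    if any(f is None for f in fdrs):
        raise ValueError("adjust the family (FDR) before aggregating replicates")
    return {
        "mean_z": float(np.mean(zs)),
        "mean_fdr": float(np.mean(fdrs)),
        "mean_proportional_overlap": float(np.mean([r.proportional_overlap for r in results])),
        "n_replicates": len(results),
    }


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(r.labels)
        row.update(
            observed=r.observed,
            null_mean=r.null_mean,
            null_sd=r.null_sd,
            z=r.z,
            p_enrichment=r.p_enrichment,
            p_depletion=r.p_depletion,
            fdr=r.fdr,
            proportional_overlap=r.proportional_overlap,
            n_query=r.n_query,
            n_permutations=r.n_permutations,
        )
        rows.append(row)
    return pd.DataFrame(rows)
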