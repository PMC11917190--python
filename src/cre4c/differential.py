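"""Differential classification of pCREs relative to the expressing cell line.

A pCRE called in the expressing line is *shared* when it overlaps a pCRE
of at least one baseline line and *gained* when it overlaps none; baseline
pCREs overlapping no expressing pCRE are *lost* (mutually overlapping
baseline regions are merged first so each lost region is counted once).
Classes therefore partition the distinct regions across cell lines:
|shared| + |gained| + |lost| equals the number of expressing pCREs plus
the merged baseline-only regions.

Distance classes follow the near-/medium-/far-cis convention: < 0.2 Mb,
0.2-0.5 Mb (both boundaries inclusive), > 0.5 Mb from the viewpoint,
measured at the pCRE midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._intervals import IntervalIndex, as_interval_array, merge_overlapping

NEAR_MAX = 200_000
FAR_MIN = 500_000


@dataclass
class ClassifiedPCREs:
    """Per-region class labels plus class counts."""

    table: pd.DataFrame  # chrom, start, end, pcre_class, source
    counts: dict

    def regions(self, pcre_class: str) -> pd.DataFrame:
        return self.table[self.table["pcre_class"] == pcre_class].reset_index(drop=True)


def _frame(regions, chrom: str | None) -> pd.DataFrame:
    if hasattr(regions, "columns"):
        df = regions.copy()
    else:
        iv = as_interval_array(regions)
        df = pd.DataFrame({"chrom": chrom or "chr1", "start": iv[:, 0], "end": iv[:, 1]})
    if "chrom" not in df.columns:
        df["chrom"] = chrom or "chr1"
    return df[["chrom", "start", "end"]]


def classify(
    expressing,
    baselines: Sequence,
    min_overlap: int = 1,
    expressing_name: str = "expressing",
    baseline_names: Sequence[str] | None = None,
    chrom: str | None = None,
) -> ClassifiedPCREs:
    """Shared/gained/lost partition of pCREs anchored on the expressing line."""
    exp_df = _frame(expressing, chrom)
    base_dfs = [_frame(b, chrom) for b in baselines]
    if len(exp_df) == 0 and all(len(b) == 0 for b in base_dfs):
        raise ValueError("no pCREs in any input set")
    baseline_names = list(baseline_names or [f"baseline{i + 1}" for i in range(len(base_dfs))])

    base_union = (
        np.vstack([as_interval_array(b) for b in base_dfs if len(b)])
        if any(len(b) for b in base_dfs)
        else np.empty((0, 2), int)
    )
    base_index = IntervalIndex(base_union)
    exp_iv = as_interval_array(exp_df)
    shared_mask = (
        base_index.overlaps_any(exp_iv[:, 0], exp_iv[:, 1], min_overlap)
        if len(exp_iv)
        else np.array([], bool)
    )

    merged_base = merge_overlapping(base_union)
    exp_index = IntervalIndex(exp_iv)
    lost_mask = (
        ~exp_index.overlaps_any(merged_base[:, 0], merged_base[:, 1], min_overlap)
        if len(merged_base)
        else np.array([], bool)
    )

    rows = []
    for i, (s, e) in enumerate(exp_iv):
        rows.append(
            (
                exp_df["chrom"].iloc[i],
                int(s),
                int(e),
                "shared" if shared_mask[i] else "gained",
                expressing_name,
            )
        )
    base_chrom = base_dfs[0]["chrom"].iloc[0] if any(len(b) for b in base_dfs) else (chrom or "chr1")
    for j, (s, e) in enumerate(merged_base):
        if lost_mask[j]:
            rows.append((base_chrom, int(s), int(e), "lost", "+".join(baseline_names)))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "pcre_class", "source"])
    counts = {
        "shared": int(shared_mask.sum()),
        "gained": int(len(exp_iv) - shared_mask.sum()),
        "lost": int(lost_mask.sum()) if len(merged_base) else 0,
    }
    return ClassifiedPCREs(table=table, counts=counts)


def distance_class(region, viewpoint: int, chrom: str | None = None) -> str:
    """near (< 0.2 Mb), medium (0.2-0.5 Mb inclusive) or far (> 0.5 Mb)."""
    region_chrom = getattr(region, "chrom", None)
    if region_chrom is not None and chrom is not None and region_chrom != chrom:
        raise ValueError("trans pCRE: the pipeline is cis-only")
    if hasattr(region, "midpoint"):
        mid = region.midpoint
    else:
        mid = (region[0] + region[1]) / 2.0
    d = abs(mid - viewpoint)
    if d < NEAR_MAX:
        return "near"
    if d <= FAR_MIN:
        return "medium"
    return "far"


def add_distances(classified: ClassifiedPCREs, viewpoint: int) -> ClassifiedPCREs:
    """Annotate the classified table with viewpoint distance and distance class."""
    table = classified.table.copy()
    mids = (table["start"] + table["end"]) / 2.0
    table["distance"] = (mids - viewpoint).abs().astype(int)
    table["distance_class"] = [
        distance_class((s, e), viewpoint) for s, e in zip(table["start"], table["end"])
    ]
    return ClassifiedPCREs(table=table, counts=classified.counts)


def distance_density(
    classified: ClassifiedPCREs | pd.DataFrame,
    viewpoint: int,
    bandwidth: float = 50_000.0,
    grid: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Gaussian kernel density of |distance| per class, each integrating to 1.

    density(x) = mean_i N(x; d_i, bandwidth^2) over the class's pCRE
    midpoint distances.  Classes with fewer than two pCREs are omitted
    with a warning.
    """
    table = classified.table if isinstance(classified, ClassifiedPCREs) else classified
    mids = (table["start"] + table["end"]) / 2.0
    dist = (mids - viewpoint).abs().to_numpy(dtype=float)
    out = {}
    for cls in ("shared", "gained", "lost"):
        d = dist[(table["pcre_class"] == cls).to_numpy()]
        if len(d) < 2:
            if len(d) or (table["pcre_class"] == cls).any():
                warnings.warn(f"class {cls!r} has < 2 pCREs; density omitted")
            continue
        g = (
            grid
            if grid is not None
            else np.linspace(d.min() - 5 * bandwidth, d.max() + 5 * bandwidth, 512)
        )
        dens = norm.pdf(g[:, None], loc=d[None, :], scale=bandwidth).mean(axis=1)
        out[cls] = (g, dens)
    return out


def annotate_promoter(
    pcres,
    gene_models: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 100,
) -> list[str]:
    """Label each pCRE promoter / exonic / non-coding against simple gene models.

    Gene models are BED6-like records (chrom, start, end, name, score,
    strand); each record's span is treated as its exonic region.  The
    promoter is the strand-adjusted window [TSS - upstream, TSS + downstream).
    Precedence: promoter > exonic > non-coding.
    """
    if "strand" not in gene_models.columns or gene_models["strand"].isna().any():
        raise ValueError("gene models must carry a strand column")
    if not set(gene_models["strand"]).issubset({"+", "-"}):
        raise ValueError("gene strands must be '+' or '-'")
    promoters = []
    for g in gene_models.itertuples():
        if g.strand == "+":
            promoters.append((g.start - upstream, g.start + downstream))
        else:
            promoters.append((g.end - downstream, g.end + upstream))
    prom_index = IntervalIndex([(max(0, s), e) for s, e in promoters if e > s])
    exon_index = IntervalIndex(as_interval_array(gene_models[["start", "end"]]))

    iv = as_interval_array(_frame(pcres, None))
    labels = []
    for s, e in iv:
        if len(prom_index) and bool(prom_index.overlaps_any(s, e)):
            labels.append("promoter")
        elif len(exon_index) and bool(exon_index.overlaps_any(s, e)):
            labels.append("exonic")
        else:
            labels.append("non-coding")
    return labels
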