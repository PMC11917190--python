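"""Viewpoint-interaction calling by monotonic-regression background modelling.

The smoothed mean-of-replicates profile is fit, separately on each side
(arm) of the viewpoint, with a non-increasing isotonic regression on
absolute distance — the background contact decay.  A fragment end is then
called as interacting when it satisfies all four criteria:

1. its smoothed signal exceeds the fitted background in *every* replicate;
2. its smoothed mean exceeds a fixed fraction (default 2.5%) of the fitted
   background at the viewpoint-adjacent fragment;
3. its residual over background clears a signal-to-noise threshold
   (residual z-score >= ``snr_k``, default 2.5, with the residual sd
   estimated per arm);
4. its local coverage score — the fraction of covered fragment ends in a
   centered 30-fragment window of the pooled raw counts — reaches the
   upper quartile of the scores over all fragments in the analysis window.

Only fragments within ``flank`` (default 1 Mb) of the viewpoint are
considered.  Called fragments no more than ``merge_gap`` (default 40) bp
apart are merged into pCREs (potential cis-regulatory elements).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .fourc_profile import ViewpointProfile, normalize, smooth, window_bounds


@dataclass
class CallerConfig:
    viewpoint_fraction: float = 0.025
    snr_k: float = 2.5
    coverage_window: int = 30
    coverage_quantile: float = 0.75
    merge_gap: int = 40
    flank: int = 1_000_000
    smoothing_window: int = 30
    target_total: float = 1e6

    def __post_init__(self):
        if self.viewpoint_fraction <= 0 or self.snr_k <= 0 or self.merge_gap < 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.coverage_quantile < 1:
            raise ValueError("coverage_quantile must lie in (0, 1)")


@dataclass
class BackgroundFit:
    """Per-arm isotonic background for a smoothed viewpoint profile."""

    fitted: np.ndarray  # aligned to the profile; NaN outside the flank window
    sigma: np.ndarray  # residual sd of the fragment's arm, aligned likewise
    b_vp: float  # fitted background at the fragment end nearest the viewpoint
    in_flank: np.ndarray  # bool mask of fragments within the flank window
    arm: np.ndarray  # -1 upstream, +1 downstream, 0 outside flank


@dataclass
class PCRE:
    """A merged run of significantly interacting fragments."""

    chrom: str
    start: int
    end: int
    fragments: list[int]  # indices into the valid-fragment arrays
    peak_signal: float
    cell_line: str = "sample"

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class CallResult:
    indices: np.ndarray
    audit: pd.DataFrame
    fit: BackgroundFit
    config: CallerConfig


def fit_monotonic_background(
    values: np.ndarray,
    distances: np.ndarray,
    flank: int = 1_000_000,
    min_points: int = 10,
) -> BackgroundFit:
    """Non-increasing isotonic regression of signal on |distance|, per arm.

    The fit is the pool-adjacent-violators least-squares solution under the
    non-increasing constraint, computed independently for the upstream
    (d < 0) and downstream (d >= 0) arms; the residual sd per arm provides
    the noise scale for the signal-to-noise criterion.
    """
    values = np.asarray(values, dtype=float)
    distances = np.asarray(distances)
    fitted = np.full(len(values), np.nan)
    sigma = np.full(len(values), np.nan)
    in_flank = np.abs(distances) <= flank
    arm = np.zeros(len(values), dtype=int)
    arm[in_flank & (distances < 0)] = -1
    arm[in_flank & (distances >= 0)] = 1
    for side in (-1, 1):
        mask = arm == side
        if int(mask.sum()) < min_points:
            raise ValueError(
                f"{'upstream' if side < 0 else 'downstream'} arm has "
                f"{int(mask.sum())} fragment ends; need at least {min_points}"
            )
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        fit = iso.fit_transform(np.abs(distances[mask]), values[mask])
        fitted[mask] = np.maximum(fit, 0.0)
        resid = values[mask] - fitted[mask]
        sigma[mask] = float(np.std(resid, ddof=1)) if mask.sum() > 1 else 0.0
    nearest = int(np.argmin(np.abs(np.where(in_flank, distances, np.iinfo(np.int64).max))))
    b_vp = float(fitted[nearest])
    return BackgroundFit(fitted=fitted, sigma=sigma, b_vp=b_vp, in_flank=in_flank, arm=arm)


def coverage_scores(raw_counts: np.ndarray, window: int = 30) -> np.ndarray:
    """Fraction of covered (nonzero) fragment ends in a centered window, per index."""
    nonzero = (np.asarray(raw_counts) > 0).astype(float)
    n = len(nonzero)
    left, right = window_bounds(n, min(window, n))
    csum = np.concatenate([[0.0], np.cumsum(nonzero)])
    idx = np.arange(n)
    return (csum[idx + right + 1] - csum[idx - left]) / (left + right + 1)


def local_coverage_score(raw_counts: np.ndarray, index: int, window: int = 30) -> float:
    """Coverage score of one fragment end (see :func:`coverage_scores`)."""
    return float(coverage_scores(raw_counts, window)[index])


def prepare_profiles(
    profiles: Sequence[ViewpointProfile], cfg: CallerConfig | None = None
) -> list[ViewpointProfile]:
    """Normalize and smooth raw replicate profiles where not already done."""
    cfg = cfg or CallerConfig()
    out = []
    for p in profiles:
        if p.normalized is None:
            p = normalize(p, cfg.target_total)
        if p.smoothed is None:
            p = smooth(p, cfg.smoothing_window)
        out.append(p)
    return out


def call_fragments(
    profiles: Sequence[ViewpointProfile],
    cfg: CallerConfig | None = None,
    fit: BackgroundFit | None = None,
) -> CallResult:
    """Apply the four interaction criteria to >= 2 replicate profiles."""
    cfg = cfg or CallerConfig()
    if len(profiles) < 2:
        raise ValueError("interaction calling requires at least two replicates")
    lengths = {len(p.raw) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("replicate profiles must share a fragment map")
    profiles = prepare_profiles(profiles, cfg)
    distances = profiles[0].distances
    smoothed = np.vstack([p.smoothed for p in profiles])
    mean_sm = smoothed.mean(axis=0)
    if fit is None:
        fit = fit_monotonic_background(mean_sm, distances, flank=cfg.flank)

    with np.errstate(invalid="ignore"):
        crit1 = np.all(smoothed > fit.fitted, axis=0)
        crit2 = mean_sm > cfg.viewpoint_fraction * fit.b_vp
        resid = mean_sm - fit.fitted
        z = np.where(fit.sigma > 0, resid / np.where(fit.sigma > 0, fit.sigma, 1.0),
                     np.where(resid > 0, np.inf, -np.inf))
        crit3 = z >= cfg.snr_k

    pooled = np.sum([p.raw for p in profiles], axis=0)
    coverage = coverage_scores(pooled, cfg.coverage_window)
    threshold = float(np.quantile(coverage[fit.in_flank], cfg.coverage_quantile))
    crit4 = coverage >= threshold

    significant = fit.in_flank & crit1 & crit2 & crit3 & crit4
    audit = pd.DataFrame(
        {
            "distance": distances,
            "mean_smoothed": mean_sm,
            "background": fit.fitted,
            "z": z,
            "coverage": coverage,
            "in_flank": fit.in_flank,
            "crit1_all_replicates": crit1,
            "crit2_viewpoint_fraction": crit2,
            "crit3_snr": crit3,
            "crit4_coverage": crit4,
            "significant": significant,
        }
    )
    return CallResult(indices=np.flatnonzero(significant), audit=audit, fit=fit, config=cfg)


def merge_to_pcres(
    fmap,
    indices: np.ndarray,
    signal: np.ndarray | None = None,
    merge_gap: int = 40,
    cell_line: str = "sample",
) -> list[PCRE]:
    """Merge called fragments no more than ``merge_gap`` bp apart into pCREs."""
    indices = np.asarray(sorted(int(i) for i in np.asarray(indices).ravel()))
    if len(indices) == 0:
        return []
    iv = fmap.valid_intervals()[indices]
    if signal is None:
        signal = np.zeros(int(np.max(indices)) + 1)
    groups: list[list[int]] = [[0]]
    for j in range(1, len(indices)):
        # gap relative to the current merged run's right edge
        gap = iv[j, 0] - max(iv[k, 1] for k in groups[-1])
        if gap <= merge_gap:
            groups[-1].append(j)
        else:
            groups.append([j])
    pcres = []
    for grp in groups:
        members = [int(indices[j]) for j in grp]
        start = int(min(iv[j, 0] for j in grp))
        end = int(max(iv[j, 1] for j in grp))
        peak = float(np.max([signal[m] for m in members]))
        pcres.append(PCRE(fmap.chrom, start, end, members, peak, cell_line))
    return pcres


def pcres_to_frame(pcres: Sequence[PCRE]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in pcres],
            "start": [p.start for p in pcres],
            "end": [p.end for p in pcres],
            "name": [p.cell_line for p in pcres],
            "score": [p.peak_signal for p in pcres],
            "strand": ".",
        }
    )


def write_pcre_bed(pcres: Sequence[PCRE], path) -> None:
    pcres_to_frame(pcres).to_csv(path, sep="\t", header=False, index=False)
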