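"""End-to-end orchestration of the simulator-driven analysis.

``run_pipeline`` executes every stage against a single seeded config and
writes each stage's artifacts into a run directory with a JSON manifest
(config hash, seed, package version, stage timings).  A rerun with the
same config and seed is bit-identical: all randomness flows from the
config seed through named substreams per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .correlation import drop_empty, pearson_matrix, rebin
from .differential import add_distances, classify, distance_density
from .enrichment import (
    adjust_family,
    aggregate_replicates,
    permutation_enrichment,
    results_to_frame,
)
from .fourc_profile import bin_counts, load_counts, replicate_correlation
from .interaction_caller import (
    CallerConfig,
    call_fragments,
    merge_to_pcres,
    pcres_to_frame,
    prepare_profiles,
    write_pcre_bed,
)
from .io import write_bed
from .motif import assemble_matrices, count_oligos, enrichment_to_frame, oligo_enrichment
from .restriction_map import digest, filter_fragments
from .synthetic_data import SimConfig, simulate_4c_counts, simulate_chip_peaks, simulate_genome

logger = logging.getLogger("cre4c")


def _substream(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 derived from the config seed."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    sim = config.sim
    if sim.n_replicates < 2:
        raise ValueError(
            "each condition needs two replicates: interacting fragments must "
            "appear in both replicates"
        )
    if len(sim.cell_lines) < 2:
        raise ValueError("need an expressing cell line and at least one baseline")

    # --- genome and fragment map -------------------------------------------
    t0 = time.perf_counter()
    base_cfg = SimConfig(
        genome_length=sim.genome_length,
        site_rate_primary=sim.site_rate_primary,
        site_rate_secondary=sim.site_rate_secondary,
        viewpoint_pos=sim.viewpoint_pos,
        decay_amplitude=sim.decay_amplitude,
        decay_exponent=sim.decay_exponent,
        decay_scale=sim.decay_scale,
        nb_dispersion=sim.nb_dispersion,
        n_replicates=sim.n_replicates,
        seed=_substream(config.seed, 0),
    )
    genome_dir = outdir / "genome"
    genome_dir.mkdir(exist_ok=True)
    genome = simulate_genome(base_cfg, genome_dir / "genome.fa")
    fmap = digest(genome)
    fmap = filter_fragments(
        fmap,
        sim.viewpoint_pos,
        min_len=config.profile.min_fragment_len,
        exclusion=config.profile.viewpoint_exclusion,
    )
    (outdir / "fragment_map").mkdir(exist_ok=True)
    fmap.to_bed(outdir / "fragment_map" / "fragments.bed")
    timings["genome_and_map"] = time.perf_counter() - t0
    logger.info("fragment map: %d fragments, %d valid", len(fmap), len(fmap.valid_indices()))

    # --- per-cell-line profiles and interaction calling --------------------
    t0 = time.perf_counter()
    caller_cfg = CallerConfig(
        viewpoint_fraction=config.caller.viewpoint_fraction,
        snr_k=config.caller.snr_k,
        coverage_window=config.caller.coverage_window,
        coverage_quantile=config.caller.coverage_quantile,
        merge_gap=config.caller.merge_gap,
        flank=config.caller.flank,
        smoothing_window=config.profile.smoothing_window,
        target_total=config.profile.target_total,
    )
    prof_dir = outdir / "profiles"
    pcre_dir = outdir / "pcres"
    prof_dir.mkdir(exist_ok=True)
    pcre_dir.mkdir(exist_ok=True)
    pcres_by_cell: dict[str, pd.DataFrame] = {}
    truths = {}
    qc_rows = []
    for ci, cell in enumerate(sim.cell_lines):
        cell_cfg = SimConfig(
            **{
                **base_cfg.__dict__,
                "planted_interactions": tuple(
                    (p.center, p.half_width, p.fold) for p in cell.planted_interactions
                ),
                "seed": _substream(config.seed, 1, ci),
            }
        )
        profiles, truth = simulate_4c_counts(fmap, cell_cfg, outdir=prof_dir, cell_line=cell.name)
        truths[cell.name] = truth
        profiles = prepare_profiles(profiles, caller_cfg)
        for p in profiles:
            p.to_bedgraph(prof_dir / f"{cell.name}_{p.replicate}.normalized.bedgraph", "normalized")
            p.to_bedgraph(prof_dir / f"{cell.name}_{p.replicate}.smoothed.bedgraph", "smoothed")
        binned = [
            bin_counts(p, config.profile.bin_size, config.profile.span) for p in profiles
        ]
        for i in range(len(binned)):
            for j in range(i + 1, len(binned)):
                r, nb = replicate_correlation(binned[i], binned[j])
                qc_rows.append((cell.name, f"rep{i+1}", f"rep{j+1}", r, nb))
        call = call_fragments(profiles, caller_cfg)
        call.audit.to_csv(pcre_dir / f"{cell.name}_audit.tsv", sep="\t", index=False)
        pcres = merge_to_pcres(
            fmap,
            call.indices,
            signal=call.audit["mean_smoothed"].to_numpy(),
            merge_gap=caller_cfg.merge_gap,
            cell_line=cell.name,
        )
        write_pcre_bed(pcres, pcre_dir / f"{cell.name}.bed")
        pcres_by_cell[cell.name] = pcres_to_frame(pcres)
        logger.info("%s: %d significant fragments -> %d pCREs", cell.name, len(call.indices), len(pcres))
    pd.DataFrame(
        qc_rows, columns=["cell", "rep_a", "rep_b", "pearson_r", "n_bins"]
    ).to_csv(prof_dir / "replicate_correlation.tsv", sep="\t", index=False)
    timings["profiles_and_calling"] = time.perf_counter() - t0

    # --- differential classification ---------------------------------------
    t0 = time.perf_counter()
    class_dir = outdir / "classes"
    class_dir.mkdir(exist_ok=True)
    expressing = sim.cell_lines[0].name
    baselines = [c.name for c in sim.cell_lines[1:]]
    classified = classify(
        pcres_by_cell[expressing],
        [pcres_by_cell[b] for b in baselines],
        expressing_name=expressing,
        baseline_names=baselines,
    )
    classified = add_distances(classified, sim.viewpoint_pos)
    table = classified.table.copy()
    table["name"] = table["pcre_class"]
    table["score"] = 0
    table["strand"] = "."
    write_bed(table, class_dir / "classified.bed")
    table.to_csv(class_dir / "classified.tsv", sep="\t", index=False)
    summary = (
        table.groupby(["pcre_class", "distance_class"]).size().rename("count").reset_index()
    )
    summary.to_csv(class_dir / "class_by_distance.tsv", sep="\t", index=False)
    results["class_counts"] = classified.counts
    try:
        densities = distance_density(classified, sim.viewpoint_pos)
        if densities:
            from .plots import density_plot

            density_plot(densities, class_dir / "distance_density.png")
    except Exception:  # pragma: no cover - plotting is best-effort
        logger.exception("density plot failed")
    timings["classification"] = time.perf_counter() - t0

    # --- permuted overlap enrichment ---------------------------------------
    t0 = time.perf_counter()
    enr_dir = outdir / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    vp = sim.viewpoint_pos
    flank = config.caller.flank
    universe = (max(0, vp - flank), min(sim.genome_length, vp + flank))
    class_regions = {
        cls: classified.regions(cls)[["start", "end"]].to_records(index=False).tolist()
        for cls in ("gained", "lost")
    }
    all_results = []
    peak_samples: dict[str, pd.DataFrame] = {}
    for di, design in enumerate(config.enrichment.peak_designs):
        planted_query = class_regions.get(design.overlap_with or "", [])
        for cell_i, cell in enumerate((expressing, *baselines)):
            for rep in range(design.n_replicates):
                peaks, _ = simulate_chip_peaks(
                    planted_query if planted_query else None,
                    universe,
                    design.n_peaks,
                    design.overlap_fraction if planted_query else 0.0,
                    width_dist=(design.width_mean, design.width_sd),
                    seed=_substream(config.seed, 2, di, cell_i, rep),
                )
                peak_samples[f"{design.mark}_{cell}_rep{rep+1}"] = peaks
                for cls, regions in class_regions.items():
                    if not regions:
                        logger.warning("no %s pCREs; skipping enrichment", cls)
                        continue
                    res = permutation_enrichment(
                        regions,
                        peaks[["start", "end"]],
                        universe,
                        n=config.enrichment.n_permutations,
                        seed=_substream(config.seed, 3, di, cell_i, rep),
                        labels={
                            "pcre_class": cls,
                            "mark": design.mark,
                            "cell": cell,
                            "replicate": f"rep{rep+1}",
                        },
                    )
                    all_results.append(res)
    if all_results:
        adjust_family(all_results)
        frame = results_to_frame(all_results)
        frame.to_csv(enr_dir / "results.tsv", sep="\t", index=False)
        agg_rows = []
        for (cls, mark, cell), grp in _group_results(all_results):
            agg = aggregate_replicates(grp)
            agg_rows.append({"pcre_class": cls, "mark": mark, "cell": cell, **agg})
        agg_frame = pd.DataFrame(agg_rows)
        agg_frame.to_csv(enr_dir / "aggregated.tsv", sep="\t", index=False)
        from .plots import enrichment_barplot

        enrichment_barplot(agg_frame, enr_dir / "proportional_overlap.png")
        results["enrichment"] = agg_frame
    timings["enrichment"] = time.perf_counter() - t0

    # --- rebinning correlation ----------------------------------------------
    t0 = time.perf_counter()
    corr_dir = outdir / "correlation"
    corr_dir.mkdir(exist_ok=True)
    samples = {}
    for cell, df in pcres_by_cell.items():
        if len(df):
            samples[f"pCRE_{cell}"] = df[["start", "end", "score"]]
    for name, peaks in peak_samples.items():
        samples[name] = peaks[["start", "end", "score"]]
    if len(samples) >= 2:
        bm = rebin(samples, sim.genome_length, config.correlation.width)
        bm = drop_empty(bm)
        corr, order = pearson_matrix(bm)
        corr.to_csv(corr_dir / "pearson.tsv", sep="\t")
        from .plots import correlation_heatmap

        correlation_heatmap(corr, order, corr_dir / "heatmap.png")
        results["correlation_samples"] = order
        results["correlation_bins_retained"] = len(bm.bin_ids)
    timings["correlation"] = time.perf_counter() - t0

    # --- motif discovery on gained pCREs ------------------------------------
    t0 = time.perf_counter()
    motif_dir = outdir / "motifs"
    motif_dir.mkdir(exist_ok=True)
    gained = classified.regions("gained")
    seqs = [genome[int(r.start) : int(r.end)] for r in gained.itertuples()]
    motif_frames = []
    for k in config.motif.k:
        counts, n_pos = count_oligos(seqs, k)
        if not counts:
            continue
        enr = oligo_enrichment(counts, n_pos, k=k)
        frame = enrichment_to_frame(enr)
        frame["k"] = k
        motif_frames.append(frame)
        sig = {
            r.oligo: r.observed
            for r in enr
            if r.e_value < config.motif.e_value_threshold
        }
        matrices = assemble_matrices(sig) if sig else []
        with open(motif_dir / f"matrices_k{k}.transfac", "w") as fh:
            for mi, m in enumerate(matrices):
                fh.write(m.to_transfac(f"motif_k{k}_{mi+1}") + "\n")
    if motif_frames:
        pd.concat(motif_frames).to_csv(motif_dir / "oligo_enrichment.tsv", sep="\t", index=False)
    timings["motifs"] = time.perf_counter() - t0

    # --- manifest -----------------------------------------------------------
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "class_counts": results.get("class_counts", {}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    results["pcres_by_cell"] = pcres_by_cell
    results["classified"] = classified
    return results


def _group_results(results):
    keys = []
    groups = {}
    for r in results:
        key = (r.labels["pcre_class"], r.labels["mark"], r.labels["cell"])
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(r)
    return [(k, groups[k]) for k in keys]
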