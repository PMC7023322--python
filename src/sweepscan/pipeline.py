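"""End-to-end orchestration: QC -> windows -> statistics -> candidates.

``run_full_scan`` executes the whole scan from one configuration object,
writing every table as TSV plus a plain-text ``run.log`` of key=value
lines that records every threshold, removal count and set size, so the
run is auditable from the log alone.  All stage outputs are pure
functions of (inputs, configuration, seed); rerunning with the same
inputs produces byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import data_io, ld_decay, popstruct, roh, selection_scan, site_filters, window_stats
from .data_io import write_tsv

@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    outdir: str
    annotation: str | None = None
    annotation_format: str = "bed"
    gene_sets: str | None = None
    focal_group: str = "sport"
    window_size_bp: int = 100_000
    step_bp: int = 50_000
    top_fraction: float = 0.01
    absolute_z: bool = False
    percentile_method: str = "quantile"
    qc: site_filters.QCConfig = field(default_factory=site_filters.QCConfig)
    roh_params: roh.ROHParams = field(default_factory=roh.ROHParams)
    ld_max_dist_bp: int = 300_000
    ld_bin_bp: int = 10_000
    ld_max_pairs_per_chrom: int = 1_000_000
    run_ld: bool = False
    run_tree: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc_raw = raw.pop("qc", {})
        roh_raw = raw.pop("roh_params", {})
        return cls(
            qc=site_filters.QCConfig(**qc_raw),
            roh_params=roh.ROHParams(**roh_raw),
            **raw,
        )


class RunLog:
    """Ordered key=value log written as plain text (no timestamps)."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def add(self, **kv: Any) -> None:
        for key, val in kv.items():
            self.lines.append(f"{key}={val}")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def _window_key_frame(keys: set, label: str) -> pd.DataFrame:
    rows = sorted(keys, key=lambda w: (data_io.natural_chrom_key(w[0]), w[1]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(set=label)


def run_full_scan(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the complete selection scan and write the report bundle.

    Stages: site QC -> sample QC -> window grid -> windowed diversity for
    both groups, windowed Weir–Cockerham F_st, focal-group Tajima's D ->
    Z-transform and log2 diversity ratio -> top-percentile intersection
    with Tajima validation -> gene annotation (if provided) -> ROH
    detection and overlap with candidates -> optional LD decay, NJ tree
    and gene-set enrichment.  Returns the in-memory results keyed by
    stage; every table is also written under ``cfg.outdir``.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    log = RunLog()
    log.add(**{
        "params.window_size_bp": cfg.window_size_bp,
        "params.step_bp": cfg.step_bp,
        "params.top_fraction": cfg.top_fraction,
        "params.tajima_filter": "D<=0",
        "params.focal_group": cfg.focal_group,
        "params.seed": cfg.seed,
    })
    for key, val in asdict(cfg.qc).items():
        if key == "annotation_thresholds":
            for name, thr in (val or {}).items():
                log.add(**{f"params.qc.annotation.{name}": thr})
        else:
            log.add(**{f"params.qc.{key}": val})
    for key, val in asdict(cfg.roh_params).items():
        log.add(**{f"params.roh.{key}": val})

    results: dict[str, Any] = {}

    # ------------------------------------------------------------------ QC
    gm = data_io.read_vcf(cfg.vcf)
    pops = data_io.read_population_map(cfg.popmap)
    log.add(**{"input.n_samples": gm.n_samples, "input.n_sites": gm.n_sites})

    gm, removed_sites = site_filters.apply_site_qc(gm, cfg.qc)
    for name, count in removed_sites.items():
        log.add(**{f"qc.site_removed.{name}": count})
    log.add(**{"qc.sites_retained": gm.n_sites})
    if gm.n_sites == 0:
        raise RuntimeError("stage site_qc: no sites survived QC")

    gm, removed_samples = site_filters.apply_sample_qc(gm, cfg.qc)
    log.add(**{
        "qc.samples_removed": len(removed_samples),
        "qc.samples_retained": gm.n_samples,
    })
    pops = data_io.PopulationMap({
        s: g for s, g in pops.assignments.items() if s in gm.sample_ids
    })
    write_tsv(
        pd.DataFrame(
            list(removed_sites.items()), columns=["filter", "n_removed"]
        ),
        os.path.join(cfg.outdir, "qc_site_removals.tsv"),
    )

    # -------------------------------------------------------------- windows
    grid = window_stats.make_windows(
        gm.chrom_extents(), cfg.window_size_bp, cfg.step_bp
    )
    log.add(**{"windows.n_total": grid.n_windows})

    stats = window_stats.compute_window_stats(gm, pops, grid, cfg.focal_group)
    n_defined = int(np.isfinite(stats["fst"]).sum())
    log.add(**{"windows.n_with_defined_fst": n_defined})
    write_tsv(stats, os.path.join(cfg.outdir, "window_stats.tsv"))
    results["window_stats"] = stats

    # ----------------------------------------------------------- candidates
    cand = selection_scan.candidate_windows(
        stats, cfg.top_fraction, absolute_z=cfg.absolute_z,
        method=cfg.percentile_method,
    )
    log.add(**{
        "thresholds.z_fst_cut": f"{cand.thresholds['z_fst_cut']:.6g}",
        "thresholds.ratio_cut": f"{cand.thresholds['ratio_cut']:.6g}",
        "sets.top_fst": len(cand.top_fst),
        "sets.top_ratio": len(cand.top_ratio),
        "sets.shared": len(cand.shared),
        "sets.final": len(cand.final),
    })
    results["candidates"] = cand
    with open(os.path.join(cfg.outdir, "thresholds.json"), "w") as fh:
        json.dump(cand.thresholds, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # ------------------------------------------------------ gene annotation
    gene_lists: dict = {}
    n_distinct = 0
    if cfg.annotation:
        ann = data_io.read_gene_annotation(cfg.annotation, cfg.annotation_format)
        gene_lists, n_distinct = selection_scan.annotate_genes(cand.final, ann)
        cand.genes = gene_lists
        log.add(**{"genes.distinct_in_final": n_distinct})
    results["n_distinct_genes"] = n_distinct

    key_index = {
        (r.chrom, int(r.start), int(r.end)): i for i, r in enumerate(stats.itertuples())
    }
    cand_rows = []
    for w in sorted(cand.top_fst | cand.top_ratio,
                    key=lambda w: (data_io.natural_chrom_key(w[0]), w[1])):
        row = stats.iloc[key_index[w]]
        cand_rows.append({
            "chrom": w[0], "start": w[1], "end": w[2],
            "z_fst": row["z_fst"], "log2_ratio": row["log2_ratio"],
            "tajima_d_focal": row["tajima_d_focal"],
            "in_top_fst": int(w in cand.top_fst),
            "in_top_ratio": int(w in cand.top_ratio),
            "in_shared": int(w in cand.shared),
            "in_final": int(w in cand.final),
            "genes": ",".join(gene_lists.get(w, [])) or ".",
        })
    write_tsv(pd.DataFrame(cand_rows), os.path.join(cfg.outdir, "candidates.tsv"))

    # ------------------------------------------------------------------ ROH
    segments = roh.detect_roh(gm, cfg.roh_params)
    summaries = roh.summarize_roh(segments, pops)
    log.add(**{"roh.n_segments": len(segments)})
    write_tsv(segments, os.path.join(cfg.outdir, "roh_segments.tsv"))
    for name, table in summaries.items():
        write_tsv(table, os.path.join(cfg.outdir, f"roh_summary_{name}.tsv"))
    results["roh_segments"] = segments

    roh_intervals = [
        (r.chrom, int(r.start_bp), int(r.end_bp)) for r in segments.itertuples()
    ]
    overlaps = selection_scan.overlap_regions(cand.final, roh_intervals)
    log.add(**{"roh.overlap_with_final": len(overlaps)})
    write_tsv(
        pd.DataFrame(overlaps, columns=["chrom", "start", "end"]),
        os.path.join(cfg.outdir, "roh_candidate_overlap.tsv"),
    )
    results["roh_overlap"] = overlaps

    # ----------------------------------------------------------- LD / tree
    if cfg.run_ld:
        for group, samples in pops.groups.items():
            curve = ld_decay.ld_decay_curve(
                gm, samples, cfg.ld_max_dist_bp, cfg.ld_bin_bp,
                cfg.ld_max_pairs_per_chrom, seed=cfg.seed,
            )
            write_tsv(curve, os.path.join(cfg.outdir, f"ld_decay_{group}.tsv"))
            results[f"ld_{group}"] = curve
            if len(curve):
                log.add(**{f"ld.{group}.last_bin_mean_r2":
                           f"{curve['mean_r2'].iloc[-1]:.4f}"})
    if cfg.run_tree:
        dm = popstruct.ibs_distance(gm)
        tree = popstruct.neighbor_joining(dm)
        data_io.write_newick(tree, os.path.join(cfg.outdir, "nj_tree.nwk"))
        write_tsv(
            dm.to_frame().reset_index().rename(columns={"index": "sample"}),
            os.path.join(cfg.outdir, "distance_matrix.tsv"),
        )
        results["tree"] = tree

    # ------------------------------------------------------------ enrichment
    if cfg.gene_sets and cfg.annotation and cand.final:
        gene_sets = data_io.read_gmt(cfg.gene_sets)
        ann = data_io.read_gene_annotation(cfg.annotation, cfg.annotation_format)
        background = set(ann.records["gene_name"])
        candidate_genes = {g for genes in gene_lists.values() for g in genes}
        if candidate_genes:
            enr = selection_scan.enrichment_test(
                candidate_genes, background, gene_sets
            )
            write_tsv(enr, os.path.join(cfg.outdir, "enrichment.tsv"))
            log.add(**{"enrichment.n_terms": len(enr)})
            results["enrichment"] = enr

    log.write(os.path.join(cfg.outdir, "run.log"))
    results["log"] = log
    results["genotypes"] = gm
    results["grid"] = grid
    return results
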