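"""Runs of homozygosity via the SNP-window scanning algorithm.

Follows the widely used sliding-window heuristic: windows of a fixed SNP
count are classified as homozygous when they contain at most a small
number of heterozygous and missing calls; each SNP's "hit rate" is the
fraction of overlapping windows that are homozygous; SNPs clearing the
hit-rate threshold seed candidate runs, which are then split at large
physical gaps and filtered on SNP count, physical length and SNP density.
Defaults match the parameter set used for mammalian whole-genome data
(50-SNP windows, 1 het / 5 missing allowed, 1 Mb gap, 50 kb-per-SNP
density, and minimum runs of 100 SNPs and 1 Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeMatrix, PopulationMap, natural_chrom_key

logger = logging.getLogger("sweepscan")


@dataclass
class ROHParams:
    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    gap_kb: float = 1000.0
    density_kb_per_snp: float = 50.0
    min_snp: int = 100
    min_kb: float = 1000.0
    window_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("window_snp", "window_het", "window_missing", "min_snp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gap_kb", "density_kb_per_snp", "min_kb", "window_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


ROH_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]


def _sample_chrom_roh(
    genotypes: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int, float]]:
    """Runs for one sample on one chromosome: (start, end, n_snps, kb)."""
    m = len(pos)
    w = params.window_snp
    if m < w:
        return []
    het = genotypes == 1
    miss = genotypes == MISSING
    # window i covers SNPs [i, i+w); eligibility from rolling het/miss counts
    het_c = np.convolve(het.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
    mis_c = np.convolve(miss.astype(np.int32), np.ones(w, dtype=np.int32), "valid")
    eligible = (het_c <= params.window_het) & (mis_c <= params.window_missing)
    # SNP j is covered by windows max(0, j-w+1) .. min(n_win-1, j)
    n_win = m - w + 1
    csum = np.concatenate(([0], np.cumsum(eligible.astype(np.int64))))
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(n_win - 1, j)
    hits = csum[hi + 1] - csum[lo]
    total = hi - lo + 1
    passing = hits / total >= params.window_threshold

    runs: list[tuple[int, int, int, float]] = []
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return runs
    # consecutive passing SNPs, split where the physical gap is too large
    breaks = np.flatnonzero(
        (np.diff(idx) > 1)
        | (np.diff(pos[idx]) > params.gap_kb * 1000.0)
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        first, last = idx[s], idx[e]
        n_snps = int(e - s + 1)
        length_kb = (pos[last] - pos[first] + 1) / 1000.0
        if n_snps < params.min_snp or length_kb < params.min_kb:
            continue
        if n_snps > 0 and length_kb / n_snps > params.density_kb_per_snp:
            continue
        runs.append((int(pos[first]), int(pos[last]), n_snps, float(length_kb)))
    return runs


def detect_roh(gm: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect ROH segments for every sample.

    Returns a DataFrame with columns ``sample, chrom, start_bp, end_bp,
    n_snps, length_kb``; segment coordinates are the first/last SNP
    positions of the run.  Chromosomes with fewer SNPs than the window
    size yield no calls (logged).
    """
    params = params or ROHParams()
    rows = []
    chroms = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy(dtype=np.int64)
    for chrom in sorted(set(chroms), key=natural_chrom_key):
        m = chroms == chrom
        pos = pos_all[m]
        if len(pos) < params.window_snp:
            logger.info("detect_roh chrom=%s skipped (only %d SNPs)", chrom, len(pos))
            continue
        sub = gm.calls[:, m]
        for i, sample in enumerate(gm.sample_ids):
            for start, end, n_snps, kb in _sample_chrom_roh(sub[i], pos, params):
                rows.append((sample, chrom, start, end, n_snps, kb))
    df = pd.DataFrame(rows, columns=ROH_COLUMNS)
    # output invariants
    if len(df):
        assert (df["n_snps"] >= params.min_snp).all()
        assert (df["length_kb"] >= params.min_kb).all()
    return df


def summarize_roh(
    segments: pd.DataFrame,
    pops: PopulationMap,
    bin_mb: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Per-group ROH summaries: totals, length-bin percentages, per-chromosome
    shares, and the longest segment per group.

    Length bins are ``bin_mb``-wide (default 0.5 Mb: 1-1.5, 1.5-2, ...),
    starting at the shortest observed segment rounded down.
    """
    if segments is None or len(segments) == 0:
        empty = pd.DataFrame()
        return {"totals": empty, "length_bins": empty, "per_chrom": empty,
                "longest": empty}
    seg = segments.copy()
    seg["group"] = seg["sample"].map(pops.assignments)
    seg["length_mb"] = seg["length_kb"] / 1000.0

    totals = (
        seg.groupby("group")["sample"].count().rename("n_roh").reset_index()
    )

    lo = np.floor(seg["length_mb"].min() / bin_mb) * bin_mb
    hi = np.ceil(seg["length_mb"].max() / bin_mb) * bin_mb
    edges = np.arange(lo, hi + bin_mb / 2, bin_mb)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_mb])
    labels = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
    seg["length_bin_mb"] = pd.cut(
        seg["length_mb"], bins=edges, labels=labels, include_lowest=True
    )
    bins = (
        seg.groupby(["group", "length_bin_mb"], observed=False)["sample"]
        .count().rename("n").reset_index()
    )
    bins["pct"] = bins.groupby("group")["n"].transform(
        lambda x: 100.0 * x / max(x.sum(), 1)
    )

    per_chrom = (
        seg.groupby(["group", "chrom"])["sample"].count().rename("n").reset_index()
    )
    per_chrom["pct"] = per_chrom.groupby("group")["n"].transform(
        lambda x: 100.0 * x / x.sum()
    )
    per_chrom = per_chrom.sort_values(
        ["group", "chrom"],
        key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s,
    ).reset_index(drop=True)

    longest = seg.loc[
        seg.groupby("group")["length_kb"].idxmax(),
        ["group", "sample", "chrom", "start_bp", "end_bp", "length_kb"],
    ].reset_index(drop=True)
    return {"totals": totals, "length_bins": bins, "per_chrom": per_chrom,
            "longest": longest}
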