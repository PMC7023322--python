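"""Linkage-disequilibrium decay from genotype dosages.

r-squared is the squared sample correlation of diploid ALT-dosage vectors
(composite LD) computed over pairwise-complete samples — the standard
phase-free surrogate for haplotype r^2 on unphased data.  All
same-chromosome SNP pairs within a distance cap enter the curve; when a
chromosome is dense enough to exceed a pair budget, pairs are subsampled
with a seeded generator so the curve remains reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, natural_chrom_key

logger = logging.getLogger("sweepscan")


@dataclass
class LDPoint:
    distance_bin_bp: int
    mean_r2: float
    n_pairs: int


def pair_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared correlation of two dosage vectors over co-called samples."""
    ok = (g1 >= 0) & (g2 >= 0)
    if ok.sum() < 2:
        return float("nan")
    x = g1[ok].astype(float)
    y = g2[ok].astype(float)
    x -= x.mean()
    y -= y.mean()
    vx = (x * x).sum()
    vy = (y * y).sum()
    if vx == 0 or vy == 0:
        return float("nan")
    return float((x * y).sum() ** 2 / (vx * vy))


def _chrom_pairs(pos: np.ndarray, max_dist: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i < j, with pos[j] - pos[i] <= max_dist."""
    hi = np.searchsorted(pos, pos + max_dist, side="right")
    counts = hi - np.arange(len(pos)) - 1
    counts = np.maximum(counts, 0)
    i = np.repeat(np.arange(len(pos)), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    j = np.arange(len(i)) - offsets[i] + i + 1
    return i, j


def ld_decay_curve(
    gm: GenotypeMatrix,
    group_samples: list[str],
    max_dist_bp: int = 300_000,
    bin_bp: int = 10_000,
    max_pairs_per_chrom: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned mean r^2 vs physical distance for one group.

    Pairs where either site is monomorphic within the group are skipped.
    Returns columns ``bin_start, bin_end, distance_bin_bp`` (midpoint),
    ``mean_r2, n_pairs``; bins without pairs are omitted.
    """
    if len(group_samples) < 3:
        raise ValueError("LD decay needs >= 3 samples in the group")
    idx = gm.sample_indices(group_samples)
    calls = gm.calls[idx, :]
    chroms = gm.sites["chrom"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy(dtype=np.int64)
    rng = np.random.default_rng(seed)

    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for chrom in sorted(set(chroms), key=natural_chrom_key):
        m = chroms == chrom
        pos = pos_all[m]
        sub = calls[:, m]
        i, j = _chrom_pairs(pos, max_dist_bp)
        if i.size == 0:
            continue
        if i.size > max_pairs_per_chrom:
            pick = rng.choice(i.size, size=max_pairs_per_chrom, replace=False)
            pick.sort()
            i, j = i[pick], j[pick]
        dist = pos[j] - pos[i]
        # chunked vectorized r^2 with pairwise-complete masking
        for lo in range(0, i.size, 200_000):
            sl = slice(lo, lo + 200_000)
            g1 = sub[:, i[sl]].astype(float)
            g2 = sub[:, j[sl]].astype(float)
            ok = (g1 >= 0) & (g2 >= 0)
            n = ok.sum(axis=0)
            g1 = np.where(ok, g1, 0.0)
            g2 = np.where(ok, g2, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                m1 = g1.sum(axis=0) / n
                m2 = g2.sum(axis=0) / n
                sxy = (g1 * g2 * ok).sum(axis=0) - n * m1 * m2
                sxx = (g1 * g1 * ok).sum(axis=0) - n * m1 * m1
                syy = (g2 * g2 * ok).sum(axis=0) - n * m2 * m2
                r2 = sxy**2 / (sxx * syy)
            valid = (n >= 2) & (sxx > 0) & (syy > 0) & np.isfinite(r2)
            b = np.minimum((dist[sl] - 1) // bin_bp, n_bins - 1).astype(int)
            np.add.at(sums, b[valid], r2[valid])
            np.add.at(counts, b[valid], 1)

    rows = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        start = b * bin_bp + 1
        end = (b + 1) * bin_bp
        rows.append((start, end, (start + end) // 2, sums[b] / counts[b], int(counts[b])))
    if not rows:
        logger.warning("ld_decay_curve no eligible pairs")
    return pd.DataFrame(
        rows, columns=["bin_start", "bin_end", "distance_bin_bp", "mean_r2", "n_pairs"]
    )
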