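"""Candidate-window selection and downstream annotation.

Implements the scan's decision rule: take the top 1% of windows by
standardized F_st and (independently) by the log2 diversity ratio,
intersect the two sets by exact window identity, then keep only shared
windows whose focal-group Tajima's D is <= 0.  Supporting operations
annotate candidate windows with overlapping genes, intersect interval
sets (e.g. against ROH), and run a generic Fisher/Benjamini–Hochberg
gene-set enrichment in place of an external ontology service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import GeneAnnotation, natural_chrom_key

logger = logging.getLogger("sweepscan")

Window = tuple[str, int, int]


# ---------------------------------------------------------------------------
# Percentile selection
# ---------------------------------------------------------------------------

def top_percentile(
    window_keys: list[Window],
    values: np.ndarray,
    q: float = 0.01,
    method: str = "quantile",
) -> tuple[set[Window], float]:
    """Windows in the upper ``q`` tail of ``values``, plus the threshold.

    The threshold is the empirical (1-q) quantile (linear interpolation)
    of the defined values; every window with value >= threshold is
    selected, so ties at the threshold may push the set slightly past
    q*N.  +inf values are always selected.  ``method="count"`` instead
    selects a fixed ceil(q*N) windows (plus threshold ties).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    vals = values[defined]
    if vals.size < 2:
        raise ValueError("top_percentile needs >= 2 defined values")
    if method == "quantile":
        threshold = float(np.quantile(vals, 1.0 - q))
    elif method == "count":
        k = max(1, int(np.ceil(q * vals.size)))
        threshold = float(np.sort(vals)[::-1][k - 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = defined & ((values >= threshold) | np.isposinf(values))
    selected = {window_keys[i] for i in np.flatnonzero(mask)}
    return selected, threshold


@dataclass
class CandidateSet:
    """The nested window sets produced by the intersection scan."""

    top_fst: set[Window]
    top_ratio: set[Window]
    shared: set[Window]
    final: set[Window]
    thresholds: dict[str, float]
    genes: dict[Window, list[str]] = field(default_factory=dict)

    def assert_invariants(self) -> None:
        assert self.shared <= self.top_fst and self.shared <= self.top_ratio
        assert self.final <= self.shared


def candidate_windows(
    stats: pd.DataFrame,
    q: float = 0.01,
    absolute_z: bool = False,
    method: str = "quantile",
) -> CandidateSet:
    """Apply the top-q intersection rule to a window-statistics table.

    ``stats`` is the table from :func:`window_stats.compute_window_stats`.
    ``absolute_z`` ranks windows by \\|Z(F_st)\\| instead of the signed value
    (the signed, high-differentiation tail is the default).  Shared windows
    are retained in the final set only when the focal group's Tajima's D
    is <= 0; windows with undefined D (no segregating sites to carry a
    site-frequency-spectrum signature) are excluded and logged.
    """
    keys = [
        (r.chrom, int(r.start), int(r.end)) for r in stats.itertuples()
    ]
    z = stats["z_fst"].to_numpy(dtype=float)
    if absolute_z:
        z = np.abs(z)
    ratio = stats["log2_ratio"].to_numpy(dtype=float)
    top_fst, z_cut = top_percentile(keys, z, q, method=method)
    top_ratio, ratio_cut = top_percentile(keys, ratio, q, method=method)
    shared = top_fst & top_ratio

    d = dict(zip(keys, stats["tajima_d_focal"].to_numpy(dtype=float)))
    final = {w for w in shared if np.isfinite(d[w]) and d[w] <= 0}
    n_undef = sum(1 for w in shared if not np.isfinite(d[w]))
    if n_undef:
        logger.info("candidate_windows shared_windows_with_undefined_D=%d", n_undef)
    cs = CandidateSet(
        top_fst=top_fst,
        top_ratio=top_ratio,
        shared=shared,
        final=final,
        thresholds={"z_fst_cut": z_cut, "ratio_cut": ratio_cut},
    )
    cs.assert_invariants()
    return cs


# ---------------------------------------------------------------------------
# Gene annotation of windows
# ---------------------------------------------------------------------------

def annotate_genes(
    windows: set[Window] | list[Window], ann: GeneAnnotation
) -> tuple[dict[Window, list[str]], int]:
    """Genes overlapping each window by >= 1 bp (1-based inclusive).

    Returns the per-window gene-name lists (sorted, deduplicated) and the
    distinct-gene total across the whole window set (a gene spanning two
    windows counts once).
    """
    df = ann.records
    out: dict[Window, list[str]] = {}
    distinct: set[str] = set()
    by_chrom = {c: sub for c, sub in df.groupby("chrom", sort=False)}
    for w in sorted(windows, key=lambda w: (natural_chrom_key(w[0]), w[1])):
        chrom, start, end = w
        sub = by_chrom.get(chrom)
        if sub is None:
            out[w] = []
            continue
        hit = sub[(sub["start"] <= end) & (sub["end"] >= start)]
        names = sorted(set(hit["gene_name"]))
        out[w] = names
        distinct.update(names)
    return out, len(distinct)


# ---------------------------------------------------------------------------
# Interval intersection (e.g. candidates x ROH)
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[Window]) -> dict[str, list[tuple[int, int]]]:
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        per_chrom.setdefault(chrom, []).append((int(start), int(end)))
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        merged = [ivals[0]]
        for s, e in ivals[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        per_chrom[chrom] = merged
    return per_chrom


def overlap_regions(
    a: list[Window] | set[Window], b: list[Window] | set[Window]
) -> list[Window]:
    """Maximal intersection intervals between two interval sets.

    Both inputs are 1-based inclusive intervals; each set is merged first,
    so the output is the set-theoretic intersection as disjoint maximal
    intervals.  An empty result is valid (and logged): finding no overlap
    between selection candidates and ROH is a legitimate outcome.
    """
    am = _merge_intervals(list(a)) if a else {}
    bm = _merge_intervals(list(b)) if b else {}
    out: list[Window] = []
    for chrom in sorted(set(am) & set(bm), key=natural_chrom_key):
        for s1, e1 in am[chrom]:
            for s2, e2 in bm[chrom]:
                lo, hi = max(s1, s2), min(e1, e2)
                if lo <= hi:
                    out.append((chrom, lo, hi))
    if not out:
        logger.info("overlap_regions result=empty")
    return out


# ---------------------------------------------------------------------------
# Gene-set enrichment (Fisher + BH)
# ---------------------------------------------------------------------------

def enrichment_test(
    candidate_genes: set[str],
    background_genes: set[str],
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided Fisher over-representation test per gene set, BH-corrected.

    For each term the 2x2 table is (candidate vs not) x (in term vs not),
    restricted to the background universe; the one-sided p-value is the
    upper hypergeometric tail.  Terms with zero candidate overlap report
    p = 1.  Columns: term, n_term, n_overlap, overlap_genes, p_value, fdr_bh.
    """
    if not candidate_genes:
        raise ValueError("empty candidate gene set")
    extra = candidate_genes - background_genes
    if extra:
        raise ValueError(f"candidate genes missing from background: {sorted(extra)[:5]}")
    M = len(background_genes)
    N = len(candidate_genes)
    rows = []
    for term in sorted(gene_sets):
        members = gene_sets[term] & background_genes
        overlap = sorted(members & candidate_genes)
        k = len(overlap)
        n = len(members)
        # P(X >= k) with X ~ Hypergeom(M, n, N)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, M, n, N))
        rows.append((term, n, k, ",".join(overlap) if overlap else ".", min(1.0, p)))
    df = pd.DataFrame(
        rows, columns=["term", "n_term", "n_overlap", "overlap_genes", "p_value"]
    )
    if len(df):
        df["fdr_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr_bh"] = pd.Series(dtype=float)
    return df.sort_values(["p_value", "term"]).reset_index(drop=True)
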