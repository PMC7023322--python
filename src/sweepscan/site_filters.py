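"""Site- and sample-level QC defining the high-quality SNP set.

Filters mirror a standard resequencing workflow: minor-allele frequency,
an exact Hardy–Weinberg test, per-site call rate, optional thresholds on
caller-emitted quality annotations, and finally removal of samples with
excessive missingness.  Filters run once, in a fixed order, with per-filter
removal counts reported; sample QC runs after site QC and is not iterated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .data_io import MISSING, GenotypeMatrix

logger = logging.getLogger("sweepscan")

#: default thresholds on caller annotations (applied only when the VCF
#: carries the corresponding field): minimum mapping quality, minimum
#: quality-by-depth, minimum mean genotype quality, maximum Fisher-strand
#: phred score, minimum mapping-quality rank-sum.
DEFAULT_ANNOTATION_THRESHOLDS: dict[str, float] = {
    "mapping_quality_min": 25.0,
    "quality_by_depth_min": 2.0,
    "genotype_quality_min": 40.0,
    "fisher_strand_max": 60.0,
    "mq_rank_sum_min": -12.5,
}

# annotation-threshold name -> (site column, comparison direction)
_ANNOTATION_COLUMNS = {
    "mapping_quality_min": ("MQ", "min"),
    "quality_by_depth_min": ("QD", "min"),
    "genotype_quality_min": ("GQ_mean", "min"),
    "fisher_strand_max": ("FS", "max"),
    "mq_rank_sum_min": ("MQRankSum", "min"),
}


@dataclass
class QCConfig:
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    site_call_rate_min: float = 0.9
    sample_call_rate_min: float = 0.9
    annotation_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        for name in ("hwe_p_min", "site_call_rate_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _hwe_exact_cached(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_ref = 2 * n - n_alt
    rare = min(n_alt, n_ref)
    # heterozygote count shares the parity of the rare-allele count
    lgamma = math.lgamma

    def log_prob(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # P(h | n, rare) = n! 2^h / (hom_rare! h! hom_common!) * rare! common! / (2n)!
        return (
            lgamma(n + 1)
            - lgamma(hom_rare + 1)
            - lgamma(h + 1)
            - lgamma(hom_common + 1)
            + h * math.log(2.0)
            + lgamma(rare + 1)
            + lgamma(2 * n - rare + 1)
            - lgamma(2 * n + 1)
        )

    h_obs = n_het
    support = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in support}
    lmax = max(logs.values())
    probs = {h: math.exp(lp - lmax) for h, lp in logs.items()}
    total = sum(probs.values())
    p_obs = probs[h_obs]
    # two-sided exact p: total probability of configurations no more likely
    # than the observed one (small tolerance guards float round-off)
    p = sum(pr for pr in probs.values() if pr <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy–Weinberg test from diploid genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one (Levene/Haldane distribution).  A monomorphic site has
    a single possible configuration and returns p = 1.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    if n_hom_ref + n_het + n_hom_alt == 0:
        raise ValueError("all genotype counts are zero")
    return _hwe_exact_cached(int(n_hom_ref), int(n_het), int(n_hom_alt))


# ---------------------------------------------------------------------------
# Site QC
# ---------------------------------------------------------------------------

def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    hom_ref = (calls == 0).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    hom_alt = (calls == 2).sum(axis=0)
    missing = (calls == MISSING).sum(axis=0)
    return hom_ref, het, hom_alt, missing


def apply_site_qc(gm: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply MAF, HWE, call-rate and annotation filters, in that order.

    Each filter is evaluated on the sites surviving the previous one, so
    the removal counts sum with the retained count to the input site count.
    Annotation thresholds are applied only for columns present in
    ``gm.sites``; absent fields are skipped and logged.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    removed: dict[str, int] = {}
    keep = np.ones(gm.n_sites, dtype=bool)
    hom_ref, het, hom_alt, missing = _genotype_counts(gm.calls)
    called = hom_ref + het + hom_alt

    # MAF
    alt = het + 2 * hom_alt
    total = 2 * called
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    fail = keep & ((maf < cfg.maf_min) | (total == 0))
    removed["maf"] = int(fail.sum())
    keep &= ~fail

    # HWE (exact test, on surviving sites)
    p = np.ones(gm.n_sites)
    for j in np.flatnonzero(keep):
        if called[j] > 0:
            p[j] = hwe_exact_test(int(hom_ref[j]), int(het[j]), int(hom_alt[j]))
    fail = keep & (p < cfg.hwe_p_min)
    removed["hwe"] = int(fail.sum())
    keep &= ~fail

    # site call rate
    call_rate = called / gm.n_samples
    fail = keep & (call_rate < cfg.site_call_rate_min)
    removed["call_rate"] = int(fail.sum())
    keep &= ~fail

    # caller annotations, when present
    n_ann_fail = 0
    for name, threshold in (cfg.annotation_thresholds or {}).items():
        col, direction = _ANNOTATION_COLUMNS[name]
        if col not in gm.sites.columns:
            logger.info("site_qc annotation_skipped=%s (field %s absent)", name, col)
            continue
        vals = gm.sites[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if direction == "min":
                bad = vals < threshold
            else:
                bad = vals > threshold
        bad &= np.isfinite(vals)
        fail = keep & bad
        n_ann_fail += int(fail.sum())
        keep &= ~fail
    removed["annotations"] = n_ann_fail

    out = gm.take_sites(keep)
    if out.n_sites == 0:
        logger.warning("site_qc removed every site")
    logger.info(
        "site_qc input=%d retained=%d removed=%s", gm.n_sites, out.n_sites, removed
    )
    return out, removed


def apply_sample_qc(gm: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples whose missing-genotype fraction strictly exceeds the cap.

    With the default ``sample_call_rate_min`` of 0.9, a sample is removed
    when more than 10% of its genotypes are missing.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = (gm.calls == MISSING).mean(axis=1)
    cap = 1.0 - cfg.sample_call_rate_min
    drop = miss_frac > cap + 1e-12
    removed = [s for s, d in zip(gm.sample_ids, drop) if d]
    if len(removed) == gm.n_samples:
        raise ValueError("sample QC removed every sample")
    keep = [s for s, d in zip(gm.sample_ids, drop) if not d]
    logger.info("sample_qc removed=%d kept=%d", len(removed), len(keep))
    return gm.take_samples(keep), removed
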