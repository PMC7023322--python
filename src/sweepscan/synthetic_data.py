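"""Synthetic two-population genotype datasets with planted sweeps.

The generator emulates the statistical structure the scan assumes, at the
default two-population resequencing design (16 "sport" vs 35 "non-sport" diploids):

* background differentiation follows the Balding–Nichols model — each
  population's allele frequency is Beta-distributed around an ancestral
  frequency with differentiation parameter F, giving a closed-form
  expected F_st for parameter-recovery tests;
* planted sweep windows, aligned to the 100-kb analysis grid, push the
  focal (sport) population toward fixation of the non-focal minor allele,
  depress its diversity by a configurable factor, and leave only rare
  residual variants (an excess of singletons, hence negative Tajima's D);
* a separate neutral-coalescent window sampler (no recombination,
  infinite sites) provides calibration material for Tajima's D, with
  E[S] = theta * a1 and E[pi] = theta.

Sweeps are modeled phenomenologically — a frequency shift plus diversity
depression plus site-frequency-spectrum skew — because those are exactly
the signatures the scan detects; forward simulation of selection is out
of scope.  Randomness is fully seeded, with one child stream per
chromosome, so identical configurations give identical datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, PopulationMap, write_vcf, write_population_map, write_tsv
from .window_stats import DEFAULT_STEP_BP, DEFAULT_WINDOW_BP

logger = logging.getLogger("sweepscan")


@dataclass
class SimulationConfig:
    n_sport: int = 16
    n_nonsport: int = 35
    n_chrom: int = 20
    chrom_len_bp: int = 5_000_000
    snp_density_per_kb: float = 1.0
    background_F: float = 0.05
    theta_per_window: float = 10.0
    n_sweeps: int = 10
    sweep_pi_reduction: float = 5.0
    sweep_freq_shift: float = 0.6
    linkage_r2: float = 0.0
    window_size_bp: int = DEFAULT_WINDOW_BP
    step_bp: int = DEFAULT_STEP_BP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sport < 2 or self.n_nonsport < 2:
            raise ValueError("each population needs >= 2 diploids")
        if not 0.0 < self.background_F < 1.0:
            raise ValueError("background_F must be in (0, 1)")
        if self.sweep_pi_reduction < 1.0:
            raise ValueError("sweep_pi_reduction must be >= 1")
        if not 0.0 <= self.linkage_r2 < 1.0:
            raise ValueError("linkage_r2 must be in [0, 1)")


# ---------------------------------------------------------------------------
# Neutral coalescent window sampler
# ---------------------------------------------------------------------------

def simulate_coalescent_window(
    n_haplotypes: int, theta: float, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """One neutral-coalescent locus: 0/1 haplotypes and site positions.

    Standard Kingman coalescent without recombination under infinite
    sites: with k active lineages the waiting time is exponential with
    rate k(k-1)/2, a uniform pair merges, and each branch accumulates
    Poisson(theta/2 * length) mutations.  Returns a matrix of shape
    (n_haplotypes, S) and uniform positions in [0, 1), sorted.
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    # active lineages: (leaf set, accumulated branch length)
    active: list[tuple[frozenset[int], float]] = [
        (frozenset([i]), 0.0) for i in range(n_haplotypes)
    ]
    finished: list[tuple[frozenset[int], float]] = []
    while len(active) > 1:
        k = len(active)
        t = rng.exponential(2.0 / (k * (k - 1)))
        active = [(leaves, length + t) for leaves, length in active]
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        li, lj = active[i], active[j]
        finished.extend([li, lj])
        merged = (li[0] | lj[0], 0.0)
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append(merged)
    # the root branch carries no observable mutations

    columns: list[np.ndarray] = []
    for leaves, length in finished:
        n_mut = rng.poisson(theta / 2.0 * length)
        if n_mut == 0:
            continue
        col = np.zeros(n_haplotypes, dtype=np.int8)
        col[list(leaves)] = 1
        columns.extend([col] * n_mut)
    if not columns:
        return np.zeros((n_haplotypes, 0), dtype=np.int8), np.empty(0)
    hap = np.column_stack(columns)
    pos = rng.uniform(size=hap.shape[1])
    order = np.argsort(pos)
    return hap[:, order], pos[order]


# ---------------------------------------------------------------------------
# Balding–Nichols two-population dataset
# ---------------------------------------------------------------------------

def balding_nichols_freqs(
    p_anc: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Population allele frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def _haplotypes_from_freqs(
    q: np.ndarray, n_hap: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_hap, n_sites) haplotype alleles with optional chainwise correlation.

    With ``rho`` = 0 alleles are independent Bernoulli(q_j).  Otherwise a
    first-order chain makes adjacent sites correlated with target
    correlation ~rho (Gaussian-free construction: conditional Bernoulli
    with the exact product-moment correlation, clipped where the marginal
    constraints bind).
    """
    n_sites = len(q)
    hap = np.empty((n_hap, n_sites), dtype=np.int8)
    u = rng.uniform(size=(n_hap, n_sites))
    hap[:, 0] = u[:, 0] < q[0]
    if rho == 0.0:
        hap[:, 1:] = u[:, 1:] < q[1:]
        return hap
    for j in range(1, n_sites):
        qc, qp = q[j], q[j - 1]
        sd_ratio = np.sqrt(qc * (1 - qc) / max(qp * (1 - qp), 1e-12))
        prev = hap[:, j - 1]
        cond = np.clip(qc + rho * sd_ratio * (prev - qp), 0.0, 1.0)
        hap[:, j] = u[:, j] < cond
    return hap


def _sweep_residual_rate(cfg: SimulationConfig) -> tuple[float, float]:
    """Residual-polymorphism rate in sweep windows and its mixing weight.

    Background per-site expected diversity under Balding–Nichols with
    ancestral p ~ U(0.05, 0.95) is 2 (1-F) E[p(1-p)].  In a sweep window a
    site is polymorphic with probability eps, carrying a minor-allele
    count of 1 (w = 0.8) or 2 (1 - w) among the focal haplotypes; eps is
    set so the expected focal diversity is the background divided by
    ``sweep_pi_reduction``.
    """
    e_p1p = 0.25 - (0.95 - 0.05) ** 2 / 12.0
    background = 2.0 * (1.0 - cfg.background_F) * e_p1p
    target = background / cfg.sweep_pi_reduction
    c = 2 * cfg.n_sport
    w = 0.8
    div1 = 2.0 * 1 * (c - 1) / (c * (c - 1.0))      # singleton
    div2 = 2.0 * 2 * (c - 2) / (c * (c - 1.0))      # doubleton
    per_poly = w * div1 + (1 - w) * div2
    eps = min(1.0, target / per_poly)
    return eps, w


def _aligned_sweep_windows(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Choose non-overlapping sweep windows aligned to the analysis grid."""
    size = cfg.window_size_bp
    slots_per_chrom = cfg.chrom_len_bp // size
    if slots_per_chrom < 1:
        raise ValueError("chromosomes shorter than one window")
    capacity = cfg.n_chrom * max(1, slots_per_chrom // 2)
    if cfg.n_sweeps > capacity:
        raise ValueError("sweep windows exceed genome capacity")
    windows = []
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    order = rng.permutation(cfg.n_chrom)
    k = 0
    while len(windows) < cfg.n_sweeps:
        chrom = chroms[order[k % cfg.n_chrom]]
        # keep one full slot away from windows already placed on this chrom
        used = [s for c, s, _ in windows if c == chrom]
        for _ in range(100):
            slot = int(rng.integers(0, slots_per_chrom))
            start = slot * size + 1
            if all(abs(start - u) > size for u in used):
                windows.append((chrom, start, start + size - 1))
                break
        else:  # pragma: no cover - capacity guard above makes this unlikely
            raise ValueError("could not place non-overlapping sweep windows")
        k += 1
    windows.sort(key=lambda w: (int(w[0][3:]), w[1]))
    return windows


def simulate_two_pop_dataset(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Generate the full two-population dataset plus its truth table.

    Returns the genotype matrix, the sample-to-group map, and a DataFrame
    of planted sweep windows (chrom, start, end) with the parameters used.
    One RNG child stream per chromosome keeps the output deterministic
    under a fixed seed regardless of chromosome count.
    """
    ss = np.random.SeedSequence(cfg.seed)
    placement_rng = np.random.default_rng(ss.spawn(1)[0])
    chrom_streams = [np.random.default_rng(s) for s in ss.spawn(cfg.n_chrom + 1)[1:]]

    sweeps = _aligned_sweep_windows(cfg, placement_rng)
    eps, w_singleton = _sweep_residual_rate(cfg)

    sport_ids = [f"sport_{i + 1:02d}" for i in range(cfg.n_sport)]
    nonsport_ids = [f"nonsport_{i + 1:02d}" for i in range(cfg.n_nonsport)]
    samples = sport_ids + nonsport_ids
    assignments = {s: "sport" for s in sport_ids}
    assignments.update({s: "non_sport" for s in nonsport_ids})

    all_sites = []
    all_calls = []
    bases = np.array(list("ACGT"))
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        rng = chrom_streams[c]
        n_sites = int(round(cfg.chrom_len_bp / 1000.0 * cfg.snp_density_per_kb))
        # unique sorted integer positions (infinite-sites: redraw collisions)
        pos = np.unique(rng.integers(1, cfg.chrom_len_bp + 1, size=n_sites))
        while len(pos) < n_sites:
            extra = rng.integers(1, cfg.chrom_len_bp + 1, size=n_sites - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        if len(pos) > n_sites:
            pos = np.sort(rng.choice(pos, size=n_sites, replace=False))

        p_anc = rng.uniform(0.05, 0.95, size=n_sites)
        q_sport = balding_nichols_freqs(p_anc, cfg.background_F, rng)
        q_non = balding_nichols_freqs(p_anc, cfg.background_F, rng)

        g_sport = (
            _haplotypes_from_freqs(q_sport, 2 * cfg.n_sport, cfg.linkage_r2, rng)
            .reshape(cfg.n_sport, 2, n_sites).sum(axis=1)
        )
        g_non = (
            _haplotypes_from_freqs(q_non, 2 * cfg.n_nonsport, cfg.linkage_r2, rng)
            .reshape(cfg.n_nonsport, 2, n_sites).sum(axis=1)
        )

        for s_chrom, s_start, s_end in sweeps:
            if s_chrom != chrom:
                continue
            in_win = np.flatnonzero((pos >= s_start) & (pos <= s_end))
            for j in in_win:
                # swept allele: ancestral frequency shifted toward the
                # minor allele by sweep_freq_shift, then fixed
                p = p_anc[j]
                shifted = p + cfg.sweep_freq_shift if p < 0.5 else p - cfg.sweep_freq_shift
                fixed_allele = 2 if np.clip(shifted, 0.0, 1.0) >= 0.5 else 0
                g_sport[:, j] = fixed_allele
                if rng.uniform() < eps:
                    # residual rare variant: 1 or 2 heterozygous carriers
                    n_carriers = 1 if rng.uniform() < w_singleton else 2
                    carriers = rng.choice(cfg.n_sport, size=n_carriers, replace=False)
                    g_sport[carriers, j] = 1

        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        all_sites.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        }))
        all_calls.append(
            np.vstack([g_sport, g_non]).astype(np.int8)
        )

    sites = pd.concat(all_sites, ignore_index=True)
    calls = np.hstack(all_calls)
    gm = GenotypeMatrix(samples, sites, calls)
    gm.validate()

    truth = pd.DataFrame(sweeps, columns=["chrom", "start", "end"])
    for key, val in asdict(cfg).items():
        truth.attrs[key] = val
    logger.info(
        "simulate_two_pop_dataset n_sites=%d n_sweeps=%d eps_residual=%.3f",
        gm.n_sites, len(sweeps), eps,
    )
    return gm, PopulationMap(assignments), truth


def write_dataset(
    gm: GenotypeMatrix,
    pops: PopulationMap,
    truth: pd.DataFrame,
    prefix: str,
    chrom_len_bp: int | None = None,
) -> dict[str, str]:
    """Write prefix.vcf, prefix.popmap.tsv and prefix.truth.tsv."""
    extents = None
    if chrom_len_bp is not None:
        extents = {c: chrom_len_bp for c in gm.sites["chrom"].unique()}
    paths = {
        "vcf": f"{prefix}.vcf",
        "popmap": f"{prefix}.popmap.tsv",
        "truth": f"{prefix}.truth.tsv",
    }
    write_vcf(gm, paths["vcf"], extents=extents)
    write_population_map(pops, paths["popmap"])
    write_tsv(truth, paths["truth"])
    return paths
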