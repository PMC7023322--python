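# Methods

This note documents the statistical model behind each stage, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Window grid

Windows are defined by genomic coordinates, not SNP indices: per
chromosome they start at 1, 1+step, … (defaults 100,000 bp size,
50,000 bp step).  Starts continue while the start's step-sized slice
still fits the chromosome, with at least one window per chromosome and
additional windows appended if needed so every position up to the last
SNP is covered; the final window may extend past the last SNP, in which
case its SNP content simply ends.  Every windowed value is a pure
function of the SNPs inside the window.

## Nucleotide diversity (θπ)

Per site, with `c_ref + c_alt = c` observed alleles in the group, the
unbiased pairwise diversity is `2·c_ref·c_alt / (c·(c−1))`; a site with
fewer than two observed alleles contributes 0 and is logged.  The window
value divides the summed site diversities by the **full window size in
bp**, not by the number of variant sites — the convention of the
standard windowed-π tools, which makes values comparable across windows
with different SNP content.  Users who want per-variant-site diversity
can recompute it from the emitted `n_snps` column.

## Weir–Cockerham F_st

Per biallelic site the two-population variance components are

    a  (among populations)
    b  (among individuals within populations)
    c  (within individuals)

computed from each group's called-diploid count, ALT frequency and
observed heterozygote frequency.  Sites where a group has no called
diploid, or where the sample-size correction `n_c` degenerates, are
skipped; sites monomorphic in both groups yield a = b = c = 0 and drop
out of the ratio automatically.  The window estimate is the weighted
(ratio-of-sums) form `Σa / Σ(a+b+c)`.  Negative estimates — sampling
noise around zero differentiation — are deliberately **not clamped**:
clamping would distort the Z-transformation's mean and variance, while
the ranking of the upper tail is unaffected either way.

## Tajima's D

Per window, with `S` segregating sites among the group's observed
alleles and `Π` the mean pairwise difference count (the same per-site
diversities as θπ, summed but not divided by window size),

    D = (Π − S/a1) / sqrt(e1·S + e2·S·(S−1))

with the standard constants a1, a2, b1, b2, c1, c2, e1, e2 evaluated at
the full group haplotype count n = 2 × (group size).  Missing data are
handled per site (observed alleles only) while the constants keep the
full n; the pipeline runs after the 10%-missingness QC, which bounds the
approximation error.  `S = 0` or `n < 4` gives an undefined D,
serialized as `.`.

A caveat documented because the test suite measures it: under the
neutral coalescent the *expectation* of D is not exactly zero.  At
n = 20 haplotypes and θ = 10 the mean is ≈ −0.10 (confirmed here both
with the package's own coalescent sampler and with an independent
msprime/tskit simulation); the variance normalization makes D
approximately, not exactly, centered.  The sweep signal the pipeline
looks for (D ≪ 0) is an order of magnitude larger than this offset.

## Ranking and the candidate rule

Z(F_st) standardizes the windowed F_st to zero mean and unit sample
(n−1) standard deviation over windows with defined values.  Ranking uses
the signed Z by default — selection in the focal group is a one-tailed
hypothesis — with an `absolute_z` option for the two-tailed variant.
The diversity statistic is `log2(θπ_nonfocal / θπ_focal)`; a focal
diversity of exactly 0 with non-focal diversity > 0 maps to +∞ (selected
at any threshold), both zero to undefined (excluded from ranking).

The top-1% threshold is the empirical (1−q) quantile with linear
interpolation over defined values; all windows at or above the threshold
are kept, so ties can push a set slightly past q·N.  A fixed-count
variant (`method="count"`) is available.  Shared windows are the exact
window-identity intersection of the two top sets (both scans share one
grid, so bp-overlap intersection would only blur the rule).  The final
set keeps shared windows with focal-group D ≤ 0; windows with undefined
D are excluded — no segregating sites means no site-frequency-spectrum
evidence either way, so exclusion is the conservative choice, and the
count of such windows is logged.

## QC

Filters run once, in the order MAF → HWE → call rate → annotation
thresholds, each evaluated on the survivors of the previous one, so the
per-filter removal counts plus the retained count always sum to the
input count.  The Hardy–Weinberg test is the exact conditional test
(Levene–Haldane distribution of the heterozygote count given the allele
counts, summing all configurations no more probable than the observed
one) rather than chi-square: the per-group sample sizes this pipeline
targets are small enough that the asymptotic test misbehaves, and the
exact test is verifiable against rational-arithmetic enumeration.
Caller-annotation thresholds apply only when the corresponding VCF field
exists; absent fields are skipped and logged, so annotation-free
(e.g. simulated) VCFs pass through unchanged.  Genotype-quality
thresholds are applied per site using the mean FORMAT GQ.  Sample QC
(missingness strictly > 10%) runs once, after site QC; no iteration.

## ROH

The scanning-window algorithm: windows of `window_snp` consecutive SNPs
are eligible when they contain at most `window_het` heterozygous and
`window_missing` missing calls; each SNP's hit rate is the fraction of
its covering windows that are eligible, and SNPs with hit rate ≥
`window_threshold` (0.05, the scanning tool's default, included in the
parameter set because the algorithm cannot run without it) seed
candidate runs.  Runs split where adjacent SNPs are more than `gap_kb`
apart, then must satisfy `min_snp`, `min_kb`, and the density bound
(segment length / SNP count ≤ `density_kb_per_snp` — the direct reading
of a kb-per-SNP density parameter).  Segment coordinates are the
first/last SNP positions, not window edges.  Defaults: 50-SNP windows,
1 het, 5 missing, 1,000-kb gap, 50 kb/SNP, ≥ 100 SNPs, ≥ 1,000 kb.

## LD decay

r² is the squared sample correlation of diploid ALT-dosage vectors over
pairwise-complete samples (composite LD) — the standard phase-free
surrogate, chosen because the pipeline never phases genotypes and
composite r² has testable closed-form behavior: under independence its
expectation is ≈ 1/(n−1), and for the simulator's correlated-pair model
it recovers ρ² plus that bias.  Pairs with either site monomorphic in
the group are skipped.  All same-chromosome pairs within `max_dist_bp`
(default 300 kb) enter 10-kb distance bins; chromosomes exceeding 10⁶
pairs are subsampled with a seeded generator so curves stay
reproducible.

## Distances and trees

The individual-pair distance is the allele-sharing distance: the mean
over co-called sites of |dosage difference|/2, bounded in [0, 1] and
phase-free; the metric is pluggable since distance-based clustering
tools rarely document theirs.  Neighbor joining is the canonical
Saitou–Nei algorithm — join the Q-minimizing pair, two-point branch
lengths, matrix reduction, three-taxon closed form — with ties broken by
the lowest index pair so output is deterministic, and negative branch
lengths clamped to 0 with a warning.  On additive distances NJ
reconstructs the generating tree exactly; the test suite uses this
consistency property as its oracle (100% topology recovery, branch
lengths to 1e-9, on random 8-taxon trees).

## Synthetic data

The generator reproduces the statistical structure the scan assumes, at
the default design size (16 focal vs 35 non-focal diploids, 20 × 5 Mb
chromosomes, 1 SNP/kb):

* **Background**: ancestral frequency p ~ Uniform(0.05, 0.95); each
  population's frequency Beta-distributed around p with differentiation
  parameter F (Balding–Nichols; default F = 0.05), genotypes
  Binomial(2, q), i.i.d. across sites.  The closed-form relationship
  E[F_st] ≈ F enables parameter-recovery testing.  An optional
  `linkage_r2` knob makes adjacent haplotype alleles first-order
  Markov-correlated for LD tests; the default is 0 (no linkage).
* **Sweeps** (default 10): non-overlapping 100-kb regions aligned to the
  analysis grid.  Within them the focal population is fixed for the
  allele obtained by shifting p toward the minor allele by
  `sweep_freq_shift` (default 0.6) and rounding — a hard-sweep analogue
  — except that each site retains a rare variant (one or two
  heterozygous carriers) with probability ε, calibrated analytically so
  the expected focal diversity is the background level divided by
  `sweep_pi_reduction` (default 5).  The residual variants are
  singletons/doubletons, so sweep windows combine elevated F_st,
  depressed focal θπ, and strongly negative focal D.
* **Truth table**: the planted window coordinates are written next to
  the VCF for recovery scoring.

Randomness uses one child stream per chromosome spawned from the seed,
so datasets are reproducible and independent of chromosome iteration
order.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: recombination and realistic LD structure,
demographic history (bottlenecks, admixture, which inflate the F_st
tail), sequencing error and genotype-caller artifacts, and a neutral
site-frequency spectrum.  On the last point: the uniform ancestral
spectrum makes background windows' Tajima's D strongly positive
(≈ +1.7), unlike the near-zero values of neutral sequence data.  The
final-set D ≤ 0 filter therefore separates sweeps from this background
even more sharply than it would in real data; the neutral calibration of
D itself is tested separately with the coalescent window sampler.
A separate consequence of planting near-fixed focal genotypes is a
Wahlund-style heterozygote deficit at sweep sites, so the pooled-sample
HWE filter removes a minority of them (those with extreme ancestral
frequencies); enough signal survives that recovery is unaffected, and
the removal counts are visible in the run log.

## Numerical and serialization choices

Undefined values are NaN in memory and `.` in TSVs; ±∞ serialize as
`inf`/`-inf`.  Floats in TSVs are written at 6 significant digits;
thresholds in the run log likewise.  The run log is ordered key=value
text with no timestamps, so identical runs are byte-identical — the
determinism checks compare whole output bundles by content.  The exact
HWE test compares configuration probabilities with a 1 + 1e−12 relative
tolerance to absorb float round-off in the tail sum.  Problem sizes in
the test suite (2,000 coalescent replicates; 2,000 sites for parameter
recovery; the 20 × 5 Mb default design for end-to-end recovery) were
chosen as the smallest sizes at which Monte-Carlo error is well below
the assertion tolerances.

## Known limitations

* Tajima's D uses the full-n constants under missingness (bounded by
  QC, see above).
* The HWE filter is computed on the pooled sample, as standard VCF
  tooling does; with strong true differentiation it removes some
  legitimately differentiated sites (Wahlund effect).
* Composite r² upper-bounds haplotype r² only approximately at strong
  inbreeding; no EM phasing is attempted.
* The enrichment test treats gene sets as fixed and genes as
  exchangeable; no gene-length or SNP-density bias correction.
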