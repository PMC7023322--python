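"""Readers and writers for every external format the scan touches.

The pipeline is VCF-centric: genotypes live in a :class:`GenotypeMatrix`
whose coordinates are 1-based inclusive throughout.  BED input/output
converts between the 0-based half-open convention and the internal one at
the boundary.  Phase is discarded on read; every downstream statistic is a
function of diploid allele counts only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")

#: genotype codes: number of ALT alleles; -1 encodes a missing call.
MISSING = -1

_NUCLEOTIDES = frozenset("ACGT")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10 (numeric runs compared as ints)."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes for ``n_samples`` samples at ``n_sites`` biallelic SNPs.

    Parameters
    ----------
    sample_ids
        Unique sample names, one per row of ``calls``.
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions)
        plus any per-site quality annotations (``MQ``, ``QD``, ``FS``,
        ``MQRankSum``, ``GQ_mean`` ...).  Strictly sorted by
        (chromosome, position) in natural chromosome order.
    calls
        ``int8`` array of shape (n_samples, n_sites) holding ALT-allele
        counts 0/1/2, or :data:`MISSING`.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"sample {exc} not present in genotype matrix") from exc

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def take_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            sites=self.sites.copy(),
            calls=self.calls[idx, :],
        )

    def chrom_extents(self) -> dict[str, int]:
        """Maximum observed SNP position per chromosome."""
        ext = self.sites.groupby("chrom", sort=False)["pos"].max()
        return {c: int(p) for c, p in ext.items()}

    def validate(self) -> None:
        """Raise on any violated container invariant."""
        if not self.sites["pos"].ge(1).all():
            raise ValueError("positions must be 1-based (>= 1)")
        chroms = self.sites["chrom"].tolist()
        keys = [natural_chrom_key(c) for c in chroms]
        pos = self.sites["pos"].to_numpy()
        pairs = list(zip(keys, pos))
        if any(pairs[i] >= pairs[i + 1] for i in range(len(pairs) - 1)):
            raise ValueError("sites must be strictly sorted by (chrom, pos)")
        for col in ("ref", "alt"):
            bad = ~self.sites[col].isin(list(_NUCLEOTIDES))
            if bad.any():
                raise ValueError(f"non-SNP allele in column {col}")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("ref == alt at some site")
        ok = (self.calls >= 0) & (self.calls <= 2)
        if not (ok | (self.calls == MISSING)).all():
            raise ValueError("genotype codes must be in {0,1,2} or missing")


@dataclass
class PopulationMap:
    """Assignment of samples to population groups (two groups for the scan)."""

    assignments: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, group in self.assignments.items():
            out.setdefault(group, []).append(sample)
        return out

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def require_two_groups(self) -> tuple[str, str]:
        groups = sorted(self.groups)
        if len(groups) != 2:
            raise ValueError(
                f"two-group operation requires exactly 2 groups, got {groups}"
            )
        return groups[0], groups[1]


@dataclass
class GeneAnnotation:
    """Gene intervals, stored 1-based inclusive.

    ``records`` has columns ``chrom, start, end, gene_id, gene_name``.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "gene_id", "gene_name"]
        )
    )

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        if len(df):
            if (df["start"] > df["end"]).any():
                raise ValueError("gene interval with start > end")
            if (df["start"] < 1).any():
                raise ValueError("negative/zero coordinate in gene annotation")
            if df["gene_id"].eq("").any() or df["gene_id"].isna().any():
                raise ValueError("empty gene_id")
            df = df.sort_values(
                ["chrom", "start", "end"],
                key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s,
            ).reset_index(drop=True)
        self.records = df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_ANNOTATIONS = ("MQ", "QD", "FS", "MQRankSum")


def read_vcf(path: str, region_filter: set[str] | None = None) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; multiallelic sites, indels and
    chromosomes outside ``region_filter`` (when given) are dropped with
    counts logged.  Genotypes come from the GT field with phase ignored;
    half-calls count as missing.  GATK-style INFO annotations (MQ, QD, FS,
    MQRankSum) and the mean FORMAT GQ are carried along when present, so the
    QC stage can threshold them.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if len(samples) == 0:
        raise ValueError(f"VCF {path} contains no samples")

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    codes: list[np.ndarray] = []
    ann_rows: list[dict[str, float]] = []
    n_indel = n_multi = n_region = 0

    for var in vcf:
        if region_filter is not None and var.CHROM not in region_filter:
            n_region += 1
            continue
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if not var.is_snp:
            n_indel += 1
            continue
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = var.gt_types.astype(np.int8)  # 0/1/2 ALT copies, 3 = unknown
        gt[gt == 3] = MISSING
        codes.append(gt)
        row: dict[str, float] = {}
        for key in _INFO_ANNOTATIONS:
            val = var.INFO.get(key)
            if val is not None:
                row[key] = float(val)
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            vals = np.asarray(gq, dtype=float).ravel()
            vals = vals[np.isfinite(vals) & (vals >= 0)]
            if vals.size:
                row["GQ_mean"] = float(vals.mean())
        ann_rows.append(row)

    logger.info(
        "read_vcf path=%s kept=%d dropped_indel_or_nonsnp=%d dropped_multiallelic=%d "
        "dropped_region=%d",
        path, len(positions), n_indel, n_multi, n_region,
    )
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    ann_keys = sorted({k for row in ann_rows for k in row})
    for key in ann_keys:
        sites[key] = [row.get(key, np.nan) for row in ann_rows]
    calls = (
        np.vstack(codes).T if codes else np.empty((len(samples), 0), dtype=np.int8)
    )
    order = sorted(
        range(len(sites)),
        key=lambda i: (natural_chrom_key(chroms[i]), positions[i]),
    )
    gm = GenotypeMatrix(samples, sites.iloc[order], calls[:, order])
    gm.validate()
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str, extents: Mapping[str, int] | None = None) -> None:
    """Write a minimal unphased GT-only VCF 4.2 file."""
    if extents is None:
        extents = gm.chrom_extents()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom in sorted(extents, key=natural_chrom_key):
            fh.write(f"##contig=<ID={chrom},length={extents[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids) + "\n"
        )
        sites = gm.sites
        calls = gm.calls
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(c)] for c in calls[:, j])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

_POPMAP_HEADER_HINTS = {"sample", "sample_id", "id", "individual"}


def read_population_map(path: str) -> PopulationMap:
    """Read a two-column sample-to-group table (tab or whitespace delimited)."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"[\t,]| +", line)
            fields = [f for f in fields if f]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{line_no}: expected 2 columns, got {len(fields)}"
                )
            rows.append((fields[0], fields[1]))
    if rows and rows[0][0].lower() in _POPMAP_HEADER_HINTS:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"population map {path} is empty")
    assignments: dict[str, str] = {}
    for sample, group in rows:
        if sample in assignments:
            raise ValueError(f"sample {sample!r} listed more than once")
        assignments[sample] = group
    return PopulationMap(assignments)


def write_population_map(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in pm.assignments.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# Gene annotation (BED / GFF3)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str, fmt: str = "bed") -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    BED coordinates are converted to the internal 1-based inclusive
    convention (start+1, end).  For GFF3, only ``gene`` features are kept
    and ``ID``/``Name`` attributes provide the identifiers.
    """
    if fmt == "bed":
        return _read_bed_genes(path)
    if fmt == "gff3":
        return _read_gff3_genes(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_bed_genes(path: str) -> GeneAnnotation:
    recs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: BED needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if start0 < 0:
                raise ValueError(f"{path}:{line_no}: negative coordinate")
            if end0 <= start0:
                raise ValueError(f"{path}:{line_no}: end <= start")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start0}-{end0}"
            recs.append((chrom, start0 + 1, end0, name, name))
    return GeneAnnotation(
        pd.DataFrame(recs, columns=["chrom", "start", "end", "gene_id", "gene_name"])
    )


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _read_gff3_genes(path: str) -> GeneAnnotation:
    recs = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{line_no}: GFF3 needs 9 columns")
            if fields[2] != "gene":
                continue
            chrom, start, end = fields[0], int(fields[3]), int(fields[4])
            if start < 1:
                raise ValueError(f"{path}:{line_no}: GFF3 coordinates are 1-based")
            attrs = dict(_GFF_ATTR.findall(fields[8]))
            gene_id = attrs.get("ID", attrs.get("gene_id", ""))
            gene_name = attrs.get("Name", gene_id)
            recs.append((chrom, start, end, gene_id, gene_name))
    return GeneAnnotation(
        pd.DataFrame(recs, columns=["chrom", "start", "end", "gene_id", "gene_name"])
    )


def write_bed(ann_or_intervals, path: str) -> None:
    """Write intervals (1-based inclusive internally) as BED (0-based half-open)."""
    if isinstance(ann_or_intervals, GeneAnnotation):
        df = ann_or_intervals.records
        rows = [
            (r.chrom, int(r.start) - 1, int(r.end), r.gene_name)
            for r in df.itertuples()
        ]
    else:
        rows = [
            (chrom, int(start) - 1, int(end), ".")
            for chrom, start, end in ann_or_intervals
        ]
    with open(path, "w") as fh:
        for chrom, s, e, name in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, set[str]]:
    """Read gene sets in GMT format: term <tab> description <tab> gene..."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            gene_sets[fields[0]] = {g for g in fields[2:] if g}
    return gene_sets


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str) -> None:
    """Serialize an unrooted tree (``popstruct.Tree``) as Newick.

    The tree must have at least three uniquely-labelled leaves; the output
    string is terminated by ``;`` and round-trips through standard parsers.
    """
    leaves = tree.leaf_labels()
    if len(leaves) < 3:
        raise ValueError("a tree needs >= 3 leaves to be written")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def _format_float(v: float) -> str:
    if np.isnan(v):
        return "."
    if np.isinf(v):
        return "inf" if v > 0 else "-inf"
    return format(v, ".6g")


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Tab-delimited output with a header row; undefined values as '.'."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_format_float)
    out.to_csv(path, sep="\t", index=False, na_rep=".")
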