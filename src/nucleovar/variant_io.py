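"""Readers, writers and containers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
VCF records and pileup tables are 1-based; BED files and every interval held
in memory are 0-based half-open.  A 1-based position ``p`` maps to the 0-based
coordinate ``p - 1`` for interval membership.

Per-sample evidence is carried as explicit read counts (reference count plus
one count per alternate allele, in the style of the RO/AO FORMAT fields)
because every downstream filtering rule is count-based.  A sample with no
reads at a site is "no coverage", which is deliberately distinct from a
sample observed with zero alternate reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("nucleovar")

SNP_BASES = frozenset("ACGT")

#: canonical order of region labels
REGION_LABELS = ("CDS", "nonrepetitive", "repetitive")

_ALLELE_COUNT_CLASSES = {
    1: "biallelic",
    2: "triallelic",
    3: "tetraallelic",
    4: "pentaallelic",
}

PILEUP_COLUMNS = ["chrom", "pos", "ref", "allele", "sample", "reads"]


# ---------------------------------------------------------------------------
# interval helpers (0-based half-open, numpy (n, 2) arrays)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    arr = np.asarray(sorted((int(s), int(e)) for s, e in intervals), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged interval arrays."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intervals_total_bp(arr: np.ndarray) -> int:
    if arr.size == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def positions_in_intervals(pos0: np.ndarray, arr: np.ndarray) -> np.ndarray:
    """Boolean membership of 0-based positions in a merged interval array."""
    pos0 = np.asarray(pos0, dtype=np.int64)
    if arr.size == 0:
        return np.zeros(pos0.shape, dtype=bool)
    idx = np.searchsorted(arr[:, 0], pos0, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos0[ok] < arr[idx[ok], 1]
    return ok


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def classify_variant(ref: str, alts: Sequence[str]) -> str:
    """Classify a record as SNP, MNP, indel or mixed from its alleles."""
    kinds = set()
    for alt in alts:
        if len(ref) == 1 and len(alt) == 1 and ref in SNP_BASES and alt in SNP_BASES:
            kinds.add("SNP")
        elif len(ref) == len(alt):
            kinds.add("MNP")
        else:
            kinds.add("indel")
    return kinds.pop() if len(kinds) == 1 else "mixed"


def allele_count_class(n_alt: int) -> str:
    return _ALLELE_COUNT_CLASSES.get(n_alt, "higher")


@dataclass
class CalledVariant:
    """One VCF record with per-sample reference/alternate read counts.

    ``per_sample_counts`` maps sample name to ``(ref_reads, (alt_reads, ...))``
    with one alternate count per ALT allele; samples without data at the site
    are absent from the mapping.
    """

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    per_sample_counts: dict[str, tuple[int, tuple[int, ...]]]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.alt_alleles:
            raise ValueError("a variant needs at least one alternate allele")

    @property
    def variant_class(self) -> str:
        return classify_variant(self.ref_allele, self.alt_alleles)

    @property
    def allele_count_class(self) -> str:
        return allele_count_class(len(self.alt_alleles))

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) identity of a biallelic site."""
        return (self.chromosome, self.position, self.ref_allele, self.alt_alleles[0])


@dataclass
class RegionSet:
    """Labelled genome fractions (CDS / nonrepetitive / repetitive).

    Intervals are stored 0-based half-open and merged per (label, chromosome).
    """

    intervals: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, str]]) -> "RegionSet":
        bucket: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for chrom, start, end, label in records:
            if end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (end <= start)")
            bucket.setdefault(label, {}).setdefault(chrom, []).append((start, end))
        merged = {
            label: {chrom: merge_intervals(ivs) for chrom, ivs in per_chrom.items()}
            for label, per_chrom in bucket.items()
        }
        return cls(intervals=merged)

    def labels(self) -> list[str]:
        return sorted(self.intervals)

    def chrom_intervals(self, label: str, chrom: str) -> np.ndarray:
        if label not in self.intervals:
            raise KeyError(f"unknown region label {label!r}; have {self.labels()}")
        return self.intervals[label].get(chrom, np.empty((0, 2), dtype=np.int64))

    def covered_bp(self, label: str) -> int:
        if label not in self.intervals:
            raise KeyError(f"unknown region label {label!r}; have {self.labels()}")
        return sum(intervals_total_bp(a) for a in self.intervals[label].values())

    def contains(self, label: str, chrom: str, position: int) -> bool:
        """Membership of a 1-based position in a labelled fraction."""
        arr = self.chrom_intervals(label, chrom)
        return bool(positions_in_intervals(np.array([position - 1]), arr)[0])


@dataclass
class CoverageMask:
    """Per-sample interval set at >= ``threshold`` read depth."""

    sample: str
    threshold: int
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("depth threshold must be a positive integer")

    def chrom_intervals(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))

    def covered_bp(self) -> int:
        return sum(intervals_total_bp(a) for a in self.intervals.values())

    def contains(self, chrom: str, position: int) -> bool:
        return bool(
            positions_in_intervals(np.array([position - 1]), self.chrom_intervals(chrom))[0]
        )


@dataclass
class AlleleCountSite:
    """Naive read counts at one site: per sample, per observed allele."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    counts: dict[str, dict[str, int]]  # sample -> allele -> reads
    non_snp: bool = False  # an observed allele is not a single base
    no_coverage: bool = False  # no sample has any reads here

    def sample_ref_alt(self, sample: str) -> tuple[int, int]:
        """(ref reads, total non-reference reads) for one sample."""
        per = self.counts.get(sample, {})
        ref = per.get(self.ref_allele, 0)
        alt = sum(n for a, n in per.items() if a != self.ref_allele)
        return ref, alt

    def alt_alleles_observed(self, sample: str | None = None) -> list[str]:
        """Non-reference alleles with at least one read (in one or all samples)."""
        samples = [sample] if sample is not None else list(self.counts)
        seen: dict[str, int] = {}
        for s in samples:
            for a, n in self.counts.get(s, {}).items():
                if a != self.ref_allele and n > 0:
                    seen[a] = seen.get(a, 0) + n
        return sorted(seen, key=lambda a: (-seen[a], a))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(samples: Sequence[str], contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("RO", 1, "Integer", "Reference allele observation count")
    header.formats.add("AO", "A", "Integer", "Alternate allele observation count")
    for s in samples:
        header.add_sample(s)
    return header


def read_vcf(path: str | Path) -> list[CalledVariant]:
    """Parse a VCF v4.2 with per-sample RO/AO counts into CalledVariant records.

    Raises ValueError naming the offending record if a sample record lacks
    the count FORMAT fields.
    """
    out: list[CalledVariant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if samples and not {"RO", "AO"} <= set(vcf.header.formats):
            raise ValueError(f"{path}: header lacks the RO/AO count FORMAT fields")
        for rec in vcf:
            if rec.alts is None:
                n_skipped += 1
                continue
            counts: dict[str, tuple[int, tuple[int, ...]]] = {}
            for s in samples:
                fmt = rec.samples[s]
                ro = fmt.get("RO")
                ao = fmt.get("AO")
                if ro is None:
                    continue  # sample has no data at this site
                if not isinstance(ao, tuple):
                    ao = (ao,)
                if any(a is None for a in ao):
                    continue
                counts[s] = (int(ro), tuple(int(a) for a in ao))
            out.append(
                CalledVariant(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts),
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    per_sample_counts=counts,
                )
            )
    logger.info("read_vcf(%s): %d records read, %d skipped", path, len(out), n_skipped)
    return out


def write_vcf(
    variants: Sequence[CalledVariant],
    path: str | Path,
    samples: Sequence[str] | None = None,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as VCF v4.2 so that ``read_vcf(write_vcf(x)) == x``."""
    if samples is None:
        seen: dict[str, None] = {}
        for v in variants:
            for s in v.per_sample_counts:
                seen.setdefault(s)
        samples = list(seen) or ["sample"]
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.chromosome] = max(contigs.get(v.chromosome, 0), v.position + 1)
    header = _vcf_header(samples, contigs)
    order = {c: i for i, c in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (order.get(v.chromosome, 0), v.position)):
            rec = vcf.new_record(
                contig=v.chromosome,
                start=v.position - 1,
                stop=v.position - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, *v.alt_alleles),
                qual=round(v.qual, 2),
            )
            for s in samples:
                if s in v.per_sample_counts:
                    ro, ao = v.per_sample_counts[s]
                    rec.samples[s]["RO"] = ro
                    rec.samples[s]["AO"] = ao
            vcf.write(rec)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _read_bed(path: str | Path) -> list[tuple[str, int, int, str | None]]:
    rows: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            rows.append((chrom, start, end, parts[3] if len(parts) > 3 else None))
    return rows


def read_regions(path: str | Path) -> RegionSet:
    """Read a labelled BED (4th column = region label) into a RegionSet."""
    rows = _read_bed(path)
    records = []
    for chrom, start, end, label in rows:
        if label is None:
            raise ValueError(f"{path}: region BED requires a label in column 4")
        records.append((chrom, start, end, label))
    rs = RegionSet.from_records(records)
    logger.info("read_regions(%s): %d labels", path, len(rs.labels()))
    return rs


def read_coverage_mask(path: str | Path, threshold: int, sample: str | None = None) -> CoverageMask:
    """Read a per-sample coverage BED (positions at >= ``threshold`` depth)."""
    rows = _read_bed(path)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, _ in rows:
        per_chrom.setdefault(chrom, []).append((start, end))
    intervals = {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}
    return CoverageMask(
        sample=sample or Path(path).stem, threshold=threshold, intervals=intervals
    )


def write_regions(region_set: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in region_set.labels():
            for chrom in sorted(region_set.intervals[label]):
                for s, e in region_set.intervals[label][chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


def write_coverage_mask(mask: CoverageMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# pileup table
# ---------------------------------------------------------------------------

def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a pileup TSV (chrom, pos, ref, allele, sample, reads; pos 1-based)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": np.int64, "ref": str, "allele": str,
               "sample": str, "reads": np.int64},
    )
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pileup table missing columns {sorted(missing)}")
    logger.info("read_pileup(%s): %d rows", path, len(df))
    return df[PILEUP_COLUMNS]


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def extract_counts_at(
    positions: Sequence[tuple[str, int]],
    pileup: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[AlleleCountSite]:
    """Naive allele-count lookup at arbitrary 1-based positions.

    Positions absent from the table come back with empty counts and the
    ``no_coverage`` flag set; positions beyond the chromosome end raise.
    """
    grouped: dict[tuple[str, int], pd.DataFrame] = {
        key: g for key, g in pileup.groupby(["chrom", "pos"], sort=False)
    }
    out: list[AlleleCountSite] = []
    for chrom, pos in positions:
        if chrom_lengths is not None:
            if chrom not in chrom_lengths:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if not 1 <= pos <= chrom_lengths[chrom]:
                raise ValueError(f"position {chrom}:{pos} is off the chromosome")
        g = grouped.get((chrom, pos))
        if g is None or len(g) == 0:
            out.append(
                AlleleCountSite(chrom, pos, ref_allele="N", counts={}, no_coverage=True)
            )
            continue
        ref = str(g["ref"].iloc[0])
        counts: dict[str, dict[str, int]] = {}
        non_snp = False
        for row in g.itertuples(index=False):
            allele = str(row.allele)
            if len(allele) != 1 or allele not in SNP_BASES:
                non_snp = True
            counts.setdefault(str(row.sample), {})[allele] = (
                counts.get(str(row.sample), {}).get(allele, 0) + int(row.reads)
            )
        total = sum(n for per in counts.values() for n in per.values())
        out.append(
            AlleleCountSite(
                chrom, pos, ref, counts, non_snp=non_snp, no_coverage=(total == 0)
            )
        )
    return out
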