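"""The variant filter cascade for a population of haploid nuclei.

Four stages, applied in order:

1. quality / biallelic subsetting — keep biallelic SNPs with QUAL above 30
   (strict ``>`` by default; configurable because "at least 30" is the other
   defensible reading);
2. pooled whole-organism filter — at least 5 reads supporting the alternate
   allele;
3. nucleus-level haploid scoring — a nucleus needs >= 5 reads at the site;
   alternate allele fraction >= 0.9 scores ALT, <= 0.1 scores REF, anything
   between is masked MISSING (guards against MDA chimeras, sequencing error
   and mismapping, which produce intermediate fractions in a haploid);
4. population-level filter — keep sites polymorphic across nuclei with
   genotype data in at least 67% of the analysed nuclei
   (``ceil(0.67 * N)``, e.g. 9 of 13).

Every exclusion is recorded in a :class:`FilterAudit` so that downstream
concordance analysis can say *which* stage removed a site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import AlleleCountSite, CalledVariant, RegionSet

SiteKey = tuple[str, int, str, str]


class NucleusGenotype(IntEnum):
    """Haploid genotype score of one nucleus at one site."""

    MISSING = -1
    REF = 0
    ALT = 1


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the filter cascade (defaults are the published rules)."""

    min_qual: float = 30.0
    qual_strict: bool = True  # QUAL > 30 (False: QUAL >= 30)
    min_depth_nucleus: int = 5
    alt_fraction_alt_call: float = 0.9
    alt_fraction_ref_call: float = 0.1
    min_alt_reads_pooled: int = 5
    population_support_fraction: float = 0.67
    require_ref_allele: bool = True  # "polymorphic" needs >=1 REF besides >=1 ALT

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction_ref_call < self.alt_fraction_alt_call <= 1.0:
            raise ValueError("need 0 <= ref-call fraction < alt-call fraction <= 1")
        if self.min_depth_nucleus < 1 or self.min_alt_reads_pooled < 1:
            raise ValueError("depth thresholds must be >= 1")
        if not 0.0 < self.population_support_fraction <= 1.0:
            raise ValueError("population support fraction must be in (0, 1]")


@dataclass
class FilterAudit:
    """Site-level record of which stage excluded (or kept) each variant."""

    records: list[dict] = field(default_factory=list)

    def add(self, key: SiteKey, stage: str, outcome: str, detail: str = "") -> None:
        chrom, pos, ref, alt = key
        self.records.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "stage": stage, "outcome": outcome, "detail": detail}
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["chrom", "pos", "ref", "alt", "stage", "outcome", "detail"]
        return pd.DataFrame(self.records, columns=cols)

    def stage_of(self, key: SiteKey) -> str | None:
        """Stage that excluded the site, or None if never excluded."""
        chrom, pos, _, _ = key
        for rec in self.records:
            if (rec["chrom"], rec["pos"]) == (chrom, pos) and rec["outcome"] == "excluded":
                return rec["stage"]
        return None


# ---------------------------------------------------------------------------
# stage 1: quality / biallelic subsetting
# ---------------------------------------------------------------------------

def filter_quality_biallelic(
    variants: Sequence[CalledVariant],
    params: FilterParams = FilterParams(),
    audit: FilterAudit | None = None,
) -> tuple[list[CalledVariant], list[CalledVariant], list[CalledVariant]]:
    """Keep biallelic SNPs passing the QUAL threshold.

    Returns (retained, excluded multiallelic, excluded other); "other" covers
    non-SNP classes and QUAL failures.
    """
    kept: list[CalledVariant] = []
    multi: list[CalledVariant] = []
    other: list[CalledVariant] = []
    for v in variants:
        if v.allele_count_class != "biallelic":
            multi.append(v)
            if audit is not None:
                audit.add(v.key, "quality_biallelic", "excluded", v.allele_count_class)
            continue
        if v.variant_class != "SNP":
            other.append(v)
            if audit is not None:
                audit.add(v.key, "quality_biallelic", "excluded", v.variant_class)
            continue
        qual_ok = v.qual > params.min_qual if params.qual_strict else v.qual >= params.min_qual
        if not qual_ok:
            other.append(v)
            if audit is not None:
                audit.add(v.key, "quality_biallelic", "excluded", "low_qual")
            continue
        kept.append(v)
    return kept, multi, other


# ---------------------------------------------------------------------------
# stage 2: pooled whole-organism filter
# ---------------------------------------------------------------------------

def filter_pooled(
    variants: Sequence[CalledVariant],
    params: FilterParams = FilterParams(),
    sample: str = "pool",
    audit: FilterAudit | None = None,
) -> list[CalledVariant]:
    """Keep biallelic sites with >= ``min_alt_reads_pooled`` alternate reads."""
    kept: list[CalledVariant] = []
    for v in variants:
        if sample not in v.per_sample_counts:
            raise ValueError(
                f"record {v.chromosome}:{v.position}: no counts for sample {sample!r}"
            )
        _, ao = v.per_sample_counts[sample]
        if ao[0] >= params.min_alt_reads_pooled:
            kept.append(v)
        elif audit is not None:
            audit.add(v.key, "pooled_alt_reads", "excluded", f"alt_reads={ao[0]}")
    return kept


# ---------------------------------------------------------------------------
# stage 3: nucleus-level haploid genotype scoring
# ---------------------------------------------------------------------------

def score_nucleus_genotype(
    ref_reads: int, alt_reads: int, params: FilterParams = FilterParams()
) -> NucleusGenotype:
    """Score one nucleus at one site from its reference/alternate read counts.

    Total depth below 5 is MISSING; otherwise the alternate allele fraction
    decides: >= 0.9 ALT, <= 0.1 REF, intermediate MISSING.  Both boundaries
    are inclusive.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total < params.min_depth_nucleus:
        return NucleusGenotype.MISSING
    fraction = alt_reads / total
    if fraction >= params.alt_fraction_alt_call:
        return NucleusGenotype.ALT
    if fraction <= params.alt_fraction_ref_call:
        return NucleusGenotype.REF
    return NucleusGenotype.MISSING


@dataclass
class GenotypeMatrix:
    """Sites x nuclei grid of haploid genotype scores."""

    sites: list[SiteKey]
    nuclei: list[str]
    grid: np.ndarray  # int8, values from NucleusGenotype

    def __post_init__(self) -> None:
        if self.grid.shape != (len(self.sites), len(self.nuclei)):
            raise ValueError("grid dimensions do not match site/nucleus lists")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def row(self, i: int) -> np.ndarray:
        return self.grid[i]

    def non_missing_counts(self) -> np.ndarray:
        return (self.grid != NucleusGenotype.MISSING).sum(axis=1)

    def alt_counts(self) -> np.ndarray:
        return (self.grid == NucleusGenotype.ALT).sum(axis=1)

    def ref_counts(self) -> np.ndarray:
        return (self.grid == NucleusGenotype.REF).sum(axis=1)

    def subset(self, keys: Iterable[SiteKey]) -> "GenotypeMatrix":
        wanted = set(keys)
        idx = [i for i, k in enumerate(self.sites) if k in wanted]
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx], nuclei=self.nuclei, grid=self.grid[idx]
        )


def score_site_counts(
    site: AlleleCountSite, alt: str, sample: str, params: FilterParams = FilterParams()
) -> NucleusGenotype:
    """Score a nucleus from an AlleleCountSite, counting all non-reference
    reads against the reference when forming the allele fraction."""
    if sample not in site.counts:
        return NucleusGenotype.MISSING
    ref_reads, alt_total = site.sample_ref_alt(sample)
    return score_nucleus_genotype(ref_reads, alt_total, params)


def build_genotype_matrix(
    pileup: pd.DataFrame,
    sites: Sequence[SiteKey],
    nuclei: Sequence[str],
    params: FilterParams = FilterParams(),
) -> GenotypeMatrix:
    """Score every (site, nucleus) cell from a tidy per-nucleus pileup table.

    Sites with no reads for a nucleus are MISSING.  Duplicate
    (site, nucleus, allele) rows in the pileup raise.
    """
    if pileup.duplicated(subset=["chrom", "pos", "sample", "allele"]).any():
        raise ValueError("duplicate (site, nucleus, allele) entries in pileup")
    nuclei = list(nuclei)
    col = {s: j for j, s in enumerate(nuclei)}
    grid = np.full((len(sites), len(nuclei)), int(NucleusGenotype.MISSING), dtype=np.int8)
    key = pileup.groupby(["chrom", "pos"], sort=False)
    grouped = {k: g for k, g in key}
    for i, (chrom, pos, ref, alt) in enumerate(sites):
        g = grouped.get((chrom, pos))
        if g is None:
            continue
        for sample, gs in g.groupby("sample"):
            if sample not in col:
                continue
            counts = dict(zip(gs["allele"], gs["reads"]))
            ref_reads = int(counts.get(ref, 0))
            alt_reads = int(sum(n for a, n in counts.items() if a != ref))
            grid[i, col[sample]] = score_nucleus_genotype(ref_reads, alt_reads, params)
    return GenotypeMatrix(sites=list(sites), nuclei=nuclei, grid=grid)


# ---------------------------------------------------------------------------
# stage 4: population-level filter
# ---------------------------------------------------------------------------

def population_support_threshold(n_nuclei: int, support_fraction: float) -> int:
    """Smallest integer count satisfying "at least ``fraction`` of N nuclei".

    The product is rounded to 9 decimals before the ceiling so that binary
    float noise (0.67 * 100 = 67.000...01) cannot inflate the threshold.
    """
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    return math.ceil(round(support_fraction * n_nuclei, 9))


def population_filter(
    matrix: GenotypeMatrix,
    params: FilterParams = FilterParams(),
    audit: FilterAudit | None = None,
) -> list[SiteKey]:
    """Sites polymorphic across nuclei with data from >= 67% of the nuclei.

    Polymorphic means at least one ALT and (by default) at least one REF
    among the non-missing genotypes.
    """
    if matrix.n_nuclei == 0:
        raise ValueError("genotype matrix has zero nuclei")
    threshold = population_support_threshold(
        matrix.n_nuclei, params.population_support_fraction
    )
    non_missing = matrix.non_missing_counts()
    n_alt = matrix.alt_counts()
    n_ref = matrix.ref_counts()
    kept: list[SiteKey] = []
    for i, key in enumerate(matrix.sites):
        if non_missing[i] < threshold:
            if audit is not None:
                audit.add(key, "population_support", "excluded",
                          f"non_missing={non_missing[i]}<{threshold}")
            continue
        polymorphic = n_alt[i] >= 1 and (n_ref[i] >= 1 or not params.require_ref_allele)
        if not polymorphic:
            if audit is not None:
                stage = "nucleus_scoring" if n_alt[i] == 0 else "population_polymorphism"
                audit.add(key, stage, "excluded", f"alt={n_alt[i]},ref={n_ref[i]}")
            continue
        kept.append(key)
    return kept


# ---------------------------------------------------------------------------
# region subsetting
# ---------------------------------------------------------------------------

def subset_by_regions(
    sites: Iterable[SiteKey], region_set: RegionSet, label: str
) -> list[SiteKey]:
    """Keep sites whose (1-based) position falls inside a labelled fraction."""
    if label not in region_set.intervals:
        raise KeyError(f"unknown region label {label!r}; have {region_set.labels()}")
    return [k for k in sites if region_set.contains(label, k[0], k[1])]


def exclusion_tally(audit: FilterAudit) -> pd.DataFrame:
    """Counts of excluded sites per (stage, detail) — the audit TSV content."""
    df = audit.to_frame()
    if df.empty:
        return pd.DataFrame(columns=["stage", "detail", "n"])
    excl = df[df["outcome"] == "excluded"]
    return (
        excl.groupby(["stage", "detail"]).size().rename("n").reset_index()
    )
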