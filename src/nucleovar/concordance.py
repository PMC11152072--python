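"""Cross-design comparison of call sets: intersection, uncalled-site
classification, random-site null sampling and the chi-square comparison.

Sites detected in one sampling design but not the other are interrogated in
the *other* design's raw counts: an uncalled site with minimal alternate
evidence (one supporting read in the pooled design; one supporting nucleus in
the single-nucleus design) is a "potential SNP", i.e. a plausible false
negative.  The proportion of potential SNPs among uncalled sites is compared
against the same proportion at randomly sampled sites, one Pearson 2x2
chi-square test per random replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import FilterAudit, FilterParams, NucleusGenotype, SiteKey
from .spectrum import round_half_up
from .variant_io import AlleleCountSite, RegionSet

POOLED_CATEGORIES = ("potential_snp", "other_variants", "invariant", "no_coverage")
NUCLEI_CATEGORIES = ("potential_snp", "invariant", "missing_data")

PROVENANCE_FLAGS = (
    "initially_called_failed_population_filter",
    "initially_called_failed_nucleus_filter",
    "never_called_potential",
    "never_called_invariant_or_missing",
    "not_applicable",
)


@dataclass(frozen=True)
class ConcordanceResult:
    """Shared and design-exclusive site sets between two call sets."""

    shared: frozenset[SiteKey]
    a_exclusive: frozenset[SiteKey]
    b_exclusive: frozenset[SiteKey]

    @property
    def union_size(self) -> int:
        return len(self.shared) + len(self.a_exclusive) + len(self.b_exclusive)

    @property
    def shared_percentage(self) -> float:
        """Percent of the union shared by both designs (half-up, 1 decimal)."""
        if self.union_size == 0:
            return 0.0
        return float(round_half_up(Fraction(100 * len(self.shared), self.union_size), 1))


@dataclass(frozen=True)
class UncalledClassification:
    site: tuple[str, int]
    mode: str  # pooled | nuclei
    category: str
    provenance: str = "not_applicable"

    def __post_init__(self) -> None:
        allowed = POOLED_CATEGORIES if self.mode == "pooled" else NUCLEI_CATEGORIES
        if self.mode not in ("pooled", "nuclei"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.category not in allowed:
            raise ValueError(f"category {self.category!r} invalid for mode {self.mode!r}")
        if self.provenance not in PROVENANCE_FLAGS:
            raise ValueError(f"unknown provenance flag {self.provenance!r}")


def intersect_callsets(
    set_a: Iterable[SiteKey], set_b: Iterable[SiteKey]
) -> ConcordanceResult:
    """Exact-key intersection of two call sets keyed by (chrom, pos, ref, alt)."""
    a_list, b_list = list(set_a), list(set_b)
    a, b = set(a_list), set(b_list)
    if len(a) != len(a_list) or len(b) != len(b_list):
        raise ValueError("duplicate site keys within a call set")
    return ConcordanceResult(
        shared=frozenset(a & b),
        a_exclusive=frozenset(a - b),
        b_exclusive=frozenset(b - a),
    )


# ---------------------------------------------------------------------------
# uncalled-site classification
# ---------------------------------------------------------------------------

def classify_uncalled_pooled(site: AlleleCountSite) -> UncalledClassification:
    """Score an uncalled site from pooled naive counts.

    no reads -> no_coverage; any non-SNP observation or more than one
    alternate allele with reads -> other_variants; exactly one alternate
    allele with >= 1 read -> potential_snp; otherwise invariant.
    """
    loc = (site.chromosome, site.position)
    total = sum(n for per in site.counts.values() for n in per.values())
    if site.no_coverage or total == 0:
        return UncalledClassification(loc, "pooled", "no_coverage")
    alts = site.alt_alleles_observed()
    if site.non_snp or len(alts) > 1:
        return UncalledClassification(loc, "pooled", "other_variants")
    if len(alts) == 1:
        return UncalledClassification(loc, "pooled", "potential_snp")
    return UncalledClassification(loc, "pooled", "invariant")


def classify_uncalled_nuclei(
    genotypes: Sequence[int] | np.ndarray, site: tuple[str, int] = ("", 0)
) -> UncalledClassification:
    """Score an uncalled site from a nucleus-filtered genotype row.

    >= 1 nucleus ALT -> potential_snp; all nuclei with data REF -> invariant;
    no nucleus with data -> missing_data.
    """
    g = np.asarray(genotypes)
    if (g == NucleusGenotype.ALT).any():
        return UncalledClassification(site, "nuclei", "potential_snp")
    if (g == NucleusGenotype.REF).any():
        return UncalledClassification(site, "nuclei", "invariant")
    return UncalledClassification(site, "nuclei", "missing_data")


def annotate_provenance(
    classification: UncalledClassification,
    initial_callset: Iterable[SiteKey] | Iterable[tuple[str, int]],
    audit: FilterAudit,
) -> UncalledClassification:
    """Label an uncalled site with the filter stage that removed it.

    A site present in the initial (quality-passing) call set was "initially
    called"; the audit trail says whether the nucleus-level scoring or the
    population-level filter excluded it.  Sites never called are split by
    whether minimal alternate evidence remains.
    """
    loc = classification.site
    initial_locs = {k[:2] for k in initial_callset}
    if loc in initial_locs:
        stage = None
        for rec in audit.records:
            if (rec["chrom"], rec["pos"]) == loc and rec["outcome"] == "excluded":
                stage = rec["stage"]
                break
        if stage is None:
            raise KeyError(f"initially called site {loc} missing from the filter audit")
        if stage == "nucleus_scoring":
            flag = "initially_called_failed_nucleus_filter"
        else:
            flag = "initially_called_failed_population_filter"
    elif classification.category == "potential_snp":
        flag = "never_called_potential"
    else:
        flag = "never_called_invariant_or_missing"
    return UncalledClassification(
        site=loc, mode=classification.mode,
        category=classification.category, provenance=flag,
    )


def category_table(classifications: Sequence[UncalledClassification]) -> pd.DataFrame:
    """Counts and printed-style percentages per category."""
    if not classifications:
        raise ValueError("no classifications to tabulate")
    mode = classifications[0].mode
    order = POOLED_CATEGORIES if mode == "pooled" else NUCLEI_CATEGORIES
    total = len(classifications)
    rows = []
    for cat in order:
        n = sum(1 for c in classifications if c.category == cat)
        rows.append(
            {"category": cat, "count": n,
             "percent": float(round_half_up(Fraction(100 * n, total), 1))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-site null
# ---------------------------------------------------------------------------

def sample_random_sites(
    region_set: RegionSet, label: str, n: int, seed: int, replicate: int = 0
) -> list[tuple[str, int]]:
    """Uniform positions (1-based) without replacement over a labelled fraction.

    Replicate draws use ``seed + replicate`` so the ten null sets of a run
    are distinct but individually reproducible.
    """
    if label not in region_set.intervals:
        raise KeyError(f"unknown region label {label!r}")
    per_chrom = region_set.intervals[label]
    chroms = sorted(per_chrom)
    arrays = [per_chrom[c] for c in chroms]
    sizes = np.array([int((a[:, 1] - a[:, 0]).sum()) if a.size else 0 for a in arrays])
    total = int(sizes.sum())
    if n > total:
        raise ValueError(f"cannot draw {n} sites from a {total} bp fraction")
    if n == 0:
        return []
    rng = np.random.default_rng([seed + replicate, 101])
    flat = np.sort(rng.choice(total, size=n, replace=False))
    out: list[tuple[str, int]] = []
    offset = 0
    for chrom, arr, size in zip(chroms, arrays, sizes):
        if size == 0:
            continue
        local = flat[(flat >= offset) & (flat < offset + size)] - offset
        if local.size:
            starts = arr[:, 0]
            widths = arr[:, 1] - arr[:, 0]
            cum = np.concatenate([[0], np.cumsum(widths)])
            idx = np.searchsorted(cum, local, side="right") - 1
            pos0 = starts[idx] + (local - cum[idx])
            out.extend((chrom, int(p) + 1) for p in pos0)
        offset += size
    return out


# ---------------------------------------------------------------------------
# chi-square comparison
# ---------------------------------------------------------------------------

def pearson_chi2_2x2(table: np.ndarray, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) on a 2x2 table of observed counts."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # a zero margin carries no information about a difference in proportions
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


def compare_proportions(
    uncalled: tuple[int, int],
    random_sets: Sequence[tuple[int, int]],
    continuity: bool = False,
) -> pd.DataFrame:
    """One 2x2 chi-square test per random replicate.

    ``uncalled`` and each element of ``random_sets`` are
    (n potential SNPs, n other sites); rows of the tested table are the
    uncalled set and one random set.  Returns the per-replicate statistics
    and p-values; the final row is the least significant (maximum p)
    replicate.
    """
    if sum(uncalled) == 0:
        raise ValueError("empty uncalled category table")
    rows = []
    for r, rand in enumerate(random_sets):
        if sum(rand) == 0:
            raise ValueError(f"empty random-set category table (replicate {r})")
        table = np.array([list(uncalled), list(rand)], dtype=float)
        stat, p = pearson_chi2_2x2(table, continuity=continuity)
        rows.append({"replicate": r, "statistic": stat, "p_value": p})
    df = pd.DataFrame(rows)
    worst = df.loc[df["p_value"].idxmax()]
    df.attrs["max_p"] = float(worst["p_value"])
    df.attrs["min_statistic"] = float(df["statistic"].min())
    return df


def mcnemar_paired(
    uncalled_flags: Sequence[bool], random_flags: Sequence[bool]
) -> tuple[float, float]:
    """Matched-pair alternative to the per-replicate Pearson test.

    Pairs the i-th uncalled site with the i-th random site; the exact test
    is a two-sided binomial test on the discordant pairs.  Returns (number
    of discordant pairs in the smaller cell, p-value).
    """
    u = np.asarray(uncalled_flags, dtype=bool)
    r = np.asarray(random_flags, dtype=bool)
    if u.shape != r.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(u & ~r))
    c = int(np.sum(~u & r))
    if b + c == 0:
        return 0.0, 1.0
    res = stats.binomtest(min(b, c), b + c, 0.5, alternative="two-sided")
    return float(min(b, c)), float(res.pvalue)
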