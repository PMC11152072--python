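"""Alternate allele frequencies (AAF) under the two sampling designs.

``read_based`` mode divides alternate reads by total reads at a site (pooled
whole-organism data); ``nucleus_based`` mode divides alternate-carrying
nuclei by nuclei with data (single-nucleus data).  Frequencies fall into
three bins: low (AAF <= 0.1667), intermediate (0.1668 <= AAF <= 0.3333) and
high (AAF > 0.3333).  The bin bounds leave no gap once an AAF is rounded to
4 decimals, which is the default comparison scale; an exact-fraction scheme
(bounds 1/6 and 1/3) is available for callers that keep numerator and
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .filtering import NucleusGenotype

BINS = ("low", "intermediate", "high")

_LOW_BOUND = Decimal("0.1667")
_INT_BOUND = Decimal("0.3333")


def round_half_up(value: float | Fraction, decimals: int) -> Decimal:
    """Decimal rounding with ties away from zero (printed-table convention)."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value)))
    return d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class AAFRecord:
    """One site's alternate allele frequency with its provenance and bin."""

    site: tuple
    aaf: float
    mode: str  # read_based | nucleus_based
    bin: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.aaf <= 1.0:
            raise ValueError("AAF must lie in [0, 1]")
        if self.denominator <= 0:
            raise ValueError("AAF denominator must be positive")


@dataclass(frozen=True)
class SpectrumSummary:
    """Bin counts with printed-style percentages (half-up, 1 decimal)."""

    low: int
    intermediate: int
    high: int

    @property
    def total(self) -> int:
        return self.low + self.intermediate + self.high

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.low, self.intermediate, self.high)

    @property
    def percentages(self) -> tuple[float, float, float]:
        return tuple(
            float(round_half_up(Fraction(100 * c, self.total), 1)) for c in self.counts
        )


def aaf_from_reads(ref_reads: int, alt_reads: int) -> float:
    """Read-based AAF: alternate reads over total reads at the site."""
    total = ref_reads + alt_reads
    if total <= 0:
        raise ValueError("cannot compute an AAF with zero total reads")
    return alt_reads / total


def aaf_from_nuclei(genotypes: Sequence[int] | np.ndarray) -> float:
    """Nucleus-based AAF: ALT nuclei over nuclei with data at the site.

    MISSING genotypes are excluded from the denominator; a row with no data
    raises (such sites are excluded upstream by the population filter).
    """
    g = np.asarray(genotypes)
    n_alt = int((g == NucleusGenotype.ALT).sum())
    n_ref = int((g == NucleusGenotype.REF).sum())
    if n_alt + n_ref == 0:
        raise ValueError("AAF undefined: no nucleus has data at the site")
    return n_alt / (n_alt + n_ref)


def bin_aaf(aaf: float, scheme: str = "rounded") -> str:
    """Assign an AAF to the low / intermediate / high bin.

    ``rounded`` (default): the AAF is rounded half-up to 4 decimals and
    compared with the printed bounds 0.1667 / 0.3333.  ``exact``: compare
    the raw value with 1/6 and 1/3.
    """
    if not 0.0 <= aaf <= 1.0:
        raise ValueError("AAF must lie in [0, 1]")
    if scheme == "rounded":
        v = round_half_up(aaf, 4)
        if v <= _LOW_BOUND:
            return "low"
        if v <= _INT_BOUND:
            return "intermediate"
        return "high"
    if scheme == "exact":
        f = Fraction(aaf).limit_denominator(10**12)
        if f <= Fraction(1, 6):
            return "low"
        if f <= Fraction(1, 3):
            return "intermediate"
        return "high"
    raise ValueError(f"unknown bin scheme {scheme!r}")


def make_record(
    site: tuple, numerator: int, denominator: int, mode: str, scheme: str = "rounded"
) -> AAFRecord:
    if mode not in ("read_based", "nucleus_based"):
        raise ValueError(f"unknown AAF mode {mode!r}")
    aaf = numerator / denominator
    return AAFRecord(
        site=site, aaf=aaf, mode=mode, bin=bin_aaf(aaf, scheme),
        numerator=numerator, denominator=denominator,
    )


def summarize_spectrum(
    records: Iterable[AAFRecord] | None = None,
    counts: tuple[int, int, int] | None = None,
) -> SpectrumSummary:
    """Tally records per bin (or wrap pre-tallied counts) into a summary."""
    if counts is None:
        if records is None:
            raise ValueError("provide either AAF records or bin counts")
        tally = {b: 0 for b in BINS}
        n = 0
        for rec in records:
            tally[rec.bin] += 1
            n += 1
        if n == 0:
            raise ValueError("cannot summarize an empty spectrum")
        counts = (tally["low"], tally["intermediate"], tally["high"])
    if sum(counts) == 0:
        raise ValueError("cannot summarize an empty spectrum")
    return SpectrumSummary(*[int(c) for c in counts])


def spectrum_table(summary: SpectrumSummary) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {"bin": BINS, "count": summary.counts, "percent": summary.percentages}
    )
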