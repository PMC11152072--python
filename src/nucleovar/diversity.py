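"""Intraorganismal diversity: SNP densities, the alternate-allele
accumulation curve and the Chao2 asymptotic richness estimate.

Densities are biallelic SNPs per kilobase of a genome fraction; for a single
nucleus both the numerator and the denominator are restricted to the part of
the fraction covered at >= 5x in that nucleus, since an MDA-amplified nucleus
only reports on the genome it covered.

Richness treats nuclei as incidence sampling units: the accumulation curve is
the classical sample-based rarefaction

    S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t)

(the expected number of distinct alternate-allele sites seen in t of the T
nuclei), extended beyond T with the standard incidence-based extrapolation
driven by the uniques Q1 and duplicates Q2.  The asymptote is Chao2 with the
(T-1)/T small-sample factor:

    S_Chao2 = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)        (Q2 > 0)
    S_Chao2 = S_obs + ((T-1)/T) * Q1 (Q1 - 1) / 2      (Q2 = 0)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import SiteKey
from .variant_io import (
    CoverageMask,
    RegionSet,
    intersect_intervals,
    intervals_total_bp,
    positions_in_intervals,
)


@dataclass(frozen=True)
class DensityEstimate:
    """SNPs per kilobase of one genome fraction for one scope."""

    scope: str  # "whole_organism" or a nucleus id
    label: str
    snp_count: int
    denominator_bp: int

    def __post_init__(self) -> None:
        if self.denominator_bp <= 0:
            raise ValueError("density denominator must be positive")

    @property
    def snps_per_kb(self) -> float:
        return 1000.0 * self.snp_count / self.denominator_bp


def snp_density_pooled(
    sites: Sequence[SiteKey], region_set: RegionSet, label: str
) -> DensityEstimate:
    """Whole-organism density: sites in the fraction over the fraction's size."""
    denom = region_set.covered_bp(label)
    if denom == 0:
        raise ValueError(f"region fraction {label!r} has zero size")
    n = sum(1 for k in sites if region_set.contains(label, k[0], k[1]))
    return DensityEstimate("whole_organism", label, n, denom)


def snp_density_nucleus(
    alt_sites: Sequence[tuple[str, int]],
    region_set: RegionSet,
    label: str,
    mask: CoverageMask,
) -> DensityEstimate:
    """Per-nucleus density on the >=5x-covered part of a genome fraction.

    ``alt_sites`` are the sites the nucleus-level filter scored as carrying
    the alternate allele in this nucleus (no population-level filter).
    """
    denom = 0
    inter: dict[str, np.ndarray] = {}
    chroms = set(region_set.intervals.get(label, {})) | set(mask.intervals)
    for chrom in chroms:
        arr = intersect_intervals(
            region_set.chrom_intervals(label, chrom), mask.chrom_intervals(chrom)
        )
        inter[chrom] = arr
        denom += intervals_total_bp(arr)
    if denom == 0:
        raise ValueError(f"fraction {label!r} and the 5x mask do not intersect")
    n = 0
    for chrom, pos in alt_sites:
        arr = inter.get(chrom)
        if arr is not None and arr.size and bool(
            positions_in_intervals(np.array([pos - 1]), arr)[0]
        ):
            n += 1
    return DensityEstimate(mask.sample, label, n, denom)


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------

@dataclass
class IncidenceMatrix:
    """Sites x nuclei presence/absence of the alternate allele."""

    sites: list[tuple]
    nuclei: list[str]
    matrix: np.ndarray  # bool, shape (S_obs, T)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sites), len(self.nuclei)):
            raise ValueError("incidence matrix shape mismatch")
        if len(self.sites) and not self.matrix.any(axis=1).all():
            raise ValueError("every included site must occur in >= 1 nucleus")

    @property
    def T(self) -> int:
        return len(self.nuclei)

    @property
    def s_obs(self) -> int:
        return len(self.sites)

    @property
    def incidence_counts(self) -> np.ndarray:
        """Y_i: number of nuclei in which each site was detected."""
        return self.matrix.sum(axis=1).astype(np.int64)

    def q(self, k: int) -> int:
        """Q_k: number of sites detected in exactly k nuclei."""
        return int((self.incidence_counts == k).sum())

    @property
    def singleton_fraction(self) -> float:
        if self.s_obs == 0:
            return float("nan")
        return self.q(1) / self.s_obs


def build_incidence(per_nucleus_sites: Mapping[str, Iterable[tuple]]) -> IncidenceMatrix:
    """Assemble the incidence matrix from per-nucleus alternate-allele site sets."""
    if not per_nucleus_sites:
        raise ValueError("need at least one nucleus")
    nuclei = sorted(per_nucleus_sites)
    sets = {n: set(per_nucleus_sites[n]) for n in nuclei}
    sites = sorted(set().union(*sets.values()))
    matrix = np.zeros((len(sites), len(nuclei)), dtype=bool)
    idx = {s: i for i, s in enumerate(sites)}
    for j, n in enumerate(nuclei):
        for s in sets[n]:
            matrix[idx[s], j] = True
    return IncidenceMatrix(sites=sites, nuclei=nuclei, matrix=matrix)


# ---------------------------------------------------------------------------
# accumulation curve and Chao2
# ---------------------------------------------------------------------------

def _rarefied_s(y: np.ndarray, T: int, t: int) -> float:
    """S(t) via the product form of C(T-Y, t)/C(T, t) (exact, stable)."""
    if t == T:
        return float(len(y))
    miss = np.ones(len(y), dtype=float)
    for j in range(t):
        miss *= np.clip(T - y - j, 0, None) / (T - j)
    return float(len(y) - miss.sum())


def _chao2_extra(s_obs: int, q1: int, q2: int, T: int) -> float:
    """Estimated number of undetected sites (Chao2 extra richness)."""
    factor = (T - 1) / T
    if q2 > 0:
        return factor * q1 * q1 / (2.0 * q2)
    return factor * q1 * (q1 - 1) / 2.0


@dataclass(frozen=True)
class RichnessEstimate:
    """Observed and asymptotic alternate-allele richness."""

    s_obs: int
    q1: int
    q2: int
    T: int
    estimate: float
    curve: pd.DataFrame = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.estimate < self.s_obs - 1e-9:
            raise ValueError("asymptotic estimate cannot fall below S_obs")


def accumulation_curve(
    incidence: IncidenceMatrix,
    t_values: Sequence[int] | None = None,
    extrapolate_to: int | None = None,
) -> pd.DataFrame:
    """Expected distinct sites at each sampling effort t (nuclei sequenced).

    Rarefaction for t <= T; incidence-based extrapolation for t > T (default
    horizon 3T).  Columns: t, s_estimate, method in
    {rarefied, observed, extrapolated}.
    """
    T = incidence.T
    if T < 1:
        raise ValueError("need at least one sampling unit")
    if extrapolate_to is None:
        extrapolate_to = 3 * T
    if t_values is None:
        t_values = list(range(1, extrapolate_to + 1))
    if min(t_values) < 1:
        raise ValueError("sampling effort t must be >= 1")
    y = incidence.incidence_counts
    s_obs = incidence.s_obs
    q1, q2 = incidence.q(1), incidence.q(2)
    extra = _chao2_extra(s_obs, q1, q2, T)
    rows = []
    for t in t_values:
        if t < T:
            s, method = _rarefied_s(y, T, t), "rarefied"
        elif t == T:
            s, method = float(s_obs), "observed"
        else:
            m = t - T
            if extra <= 0 or q1 == 0:
                s = float(s_obs)
            else:
                s = s_obs + extra * (1.0 - (1.0 - q1 / (q1 + T * extra)) ** m)
            method = "extrapolated"
        rows.append({"t": int(t), "s_estimate": s, "method": method})
    return pd.DataFrame(rows)


def chao2_estimate(
    incidence: IncidenceMatrix, with_curve: bool = True
) -> RichnessEstimate:
    """Chao2 asymptotic richness with the (T-1)/T small-sample correction."""
    T = incidence.T
    if T < 2:
        raise ValueError("Chao2 needs at least two sampling units")
    s_obs = incidence.s_obs
    q1, q2 = incidence.q(1), incidence.q(2)
    estimate = s_obs + _chao2_extra(s_obs, q1, q2, T)
    curve = accumulation_curve(incidence) if with_curve else None
    return RichnessEstimate(s_obs=s_obs, q1=q1, q2=q2, T=T, estimate=estimate, curve=curve)


def density_from_asymptote(richness: RichnessEstimate, fraction_bp: int) -> float:
    """Asymptotic SNP density (SNPs/kb) over a genome fraction."""
    if fraction_bp <= 0:
        raise ValueError("fraction size must be positive")
    return 1000.0 * richness.estimate / fraction_bp
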