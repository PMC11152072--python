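"""Synthetic populations of haploid nuclei and the two derived sequencing designs.

The generator emulates the study system behind the pipeline: one organism
whose genome exists as a population of asexually reproducing haploid nuclei.
Each variant site is carried by a subset of nuclei (most sites by exactly one
nucleus); the organism is then observed two ways:

* **pooled** — deep whole-organism sequencing (mean depth ~86x) where a site's
  alternate read fraction estimates its carrier fraction, plus a per-read
  base-error channel;
* **per nucleus** — MDA-amplified single nuclei with patchy coverage (a random
  interval-union mask holding 30-60% of the genome at >= 5x), overdispersed
  depth, and a small allele cross-contamination rate.

All randomness is derived from ``SimulationConfig.seed``.  Counts at a given
genomic position use a position-keyed substream, so querying extra positions
(e.g. random-site nulls) never perturbs the counts simulated elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import (
    CalledVariant,
    CoverageMask,
    RegionSet,
    merge_intervals,
    positions_in_intervals,
    write_coverage_mask,
    write_pileup,
    write_regions,
    write_vcf,
)

BASES = np.array(list("ACGT"))

# substream tags (second word of the per-purpose seed sequence)
_TAG_TRUTH = 1
_TAG_POOLED = 2
_TAG_NUCLEUS = 3
_TAG_MASK = 4
_TAG_REGIONS = 5
_TAG_SAMPLING = 6


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated organism.

    Defaults mirror the system the pipeline was built for: deep pooled
    sequencing at 86x mean depth, 13 single nuclei sampled from a population
    of 200, 76% of variant sites private to one nucleus, per-nucleus >=5x
    coverage drawn uniformly from 30-60% of the genome, and a genome-wide
    truth density of 0.37 SNPs/kb.
    """

    genome_length: tuple[int, ...] = (10_000_000, 10_000_000)
    n_nuclei_total: int = 200
    n_variant_sites: int = 7_400
    singleton_fraction: float = 0.76
    carrier_geometric_p: float = 0.065  # non-singleton carrier count = 2 + Geom(p), truncated
    pooled_depth_mean: float = 86.0
    base_error_rate: float = 0.002
    n_nuclei_sampled: int = 13
    nucleus_coverage_fraction_5x: tuple[float, float] = (0.30, 0.60)
    nucleus_depth_mean: float = 20.0
    nucleus_depth_dispersion: float = 3.0
    mda_noise_rate: float = 0.01
    region_fractions: tuple[float, float, float] = (0.20, 0.50, 0.30)  # CDS, nonrep, rep
    region_block_size: int = 10_000
    mask_interval_mean_bp: float = 5_000.0
    multiallelic_fraction: float = 0.0
    seed: int = 0

    @property
    def chromosomes(self) -> dict[str, int]:
        return {f"chr{i + 1}": int(l) for i, l in enumerate(self.genome_length)}

    @property
    def total_genome_bp(self) -> int:
        return int(sum(self.genome_length))

    def validate(self) -> None:
        probs = {
            "singleton_fraction": self.singleton_fraction,
            "carrier_geometric_p": self.carrier_geometric_p,
            "base_error_rate": self.base_error_rate,
            "mda_noise_rate": self.mda_noise_rate,
            "multiallelic_fraction": self.multiallelic_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.nucleus_coverage_fraction_5x
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("nucleus_coverage_fraction_5x must be a range within [0, 1]")
        if self.n_nuclei_sampled > self.n_nuclei_total:
            raise ValueError("cannot sample more nuclei than the population holds")
        if self.n_variant_sites > self.total_genome_bp:
            raise ValueError(
                f"genome of {self.total_genome_bp} bp cannot hold "
                f"{self.n_variant_sites} distinct variant sites"
            )
        if abs(sum(self.region_fractions) - 1.0) > 1e-9:
            raise ValueError("region_fractions must sum to 1")
        if min(self.n_nuclei_total, self.pooled_depth_mean, self.nucleus_depth_mean) <= 0:
            raise ValueError("counts and depths must be positive")


@dataclass
class SimulationTruth:
    """Ground truth: variant sites, their carrier nuclei, carrier fractions."""

    variant_sites: list[tuple[str, int, str, str]]  # (chrom, pos 1-based, ref, alt)
    carrier_sets: list[frozenset[int]]
    carrier_fraction: np.ndarray
    n_nuclei_total: int
    chromosomes: dict[str, int]
    extra_alts: dict[int, tuple[str, frozenset[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for (chrom, pos, _, _), carriers, cf in zip(
            self.variant_sites, self.carrier_sets, self.carrier_fraction
        ):
            if (chrom, pos) in seen:
                raise ValueError(f"duplicate variant position {chrom}:{pos}")
            seen.add((chrom, pos))
            if len(carriers) == 0:
                raise ValueError("every carrier set must be nonempty")
            if not 0.0 < cf <= 1.0:
                raise ValueError("carrier fractions must lie in (0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.variant_sites)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(c, p): i for i, (c, p, _, _) in enumerate(self.variant_sites)}

    def sampled_carrier_fraction(self, i: int, sampled: Sequence[int]) -> float:
        """Carrier fraction of site ``i`` within a sampled nucleus subset."""
        k = len(self.carrier_sets[i] & set(sampled))
        return k / len(sampled)


def _rng(config: SimulationConfig, *words: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *words])


def _ref_base_at(config: SimulationConfig, chrom_idx: int, pos: int) -> str:
    """Deterministic reference base for a non-variant position."""
    r = _rng(config, _TAG_POOLED, 0, chrom_idx, pos)
    return str(BASES[r.integers(4)])


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _draw_positions(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Uniform distinct positions across the genome (rejection sampling)."""
    chroms = list(config.chromosomes.items())
    lengths = np.array([l for _, l in chroms], dtype=float)
    probs = lengths / lengths.sum()
    taken: set[tuple[int, int]] = set()
    out: list[tuple[str, int]] = []
    while len(out) < config.n_variant_sites:
        ci = int(rng.choice(len(chroms), p=probs))
        pos = int(rng.integers(1, chroms[ci][1] + 1))
        if (ci, pos) in taken:
            continue
        taken.add((ci, pos))
        out.append((chroms[ci][0], pos))
    return out


def _draw_carrier_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Mixture: point mass at 1 carrier, else 2 + Geometric(p) truncated at N."""
    if rng.random() < config.singleton_fraction:
        return 1
    k = 2 + int(rng.geometric(config.carrier_geometric_p)) - 1
    return min(k, config.n_nuclei_total)


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Place variant sites and assign each a carrier set of nuclei."""
    config.validate()
    rng = _rng(config, _TAG_TRUTH)
    positions = _draw_positions(config, rng)
    sites: list[tuple[str, int, str, str]] = []
    carrier_sets: list[frozenset[int]] = []
    fractions = np.empty(config.n_variant_sites)
    extra_alts: dict[int, tuple[str, frozenset[int]]] = {}
    for i, (chrom, pos) in enumerate(positions):
        ref, alt = rng.choice(4, size=2, replace=False)
        k = _draw_carrier_count(config, rng)
        carriers = frozenset(int(x) for x in rng.choice(config.n_nuclei_total, k, replace=False))
        sites.append((chrom, pos, str(BASES[ref]), str(BASES[alt])))
        carrier_sets.append(carriers)
        fractions[i] = k / config.n_nuclei_total
        if config.multiallelic_fraction > 0 and rng.random() < config.multiallelic_fraction:
            alt2 = [b for b in range(4) if b not in (ref, alt)][int(rng.integers(2))]
            pool = [n for n in range(config.n_nuclei_total) if n not in carriers]
            if pool:
                k2 = max(1, k // 2)
                extra = frozenset(
                    int(x) for x in rng.choice(pool, min(k2, len(pool)), replace=False)
                )
                extra_alts[i] = (str(BASES[alt2]), extra)
    return SimulationTruth(
        variant_sites=sites,
        carrier_sets=carrier_sets,
        carrier_fraction=fractions,
        n_nuclei_total=config.n_nuclei_total,
        chromosomes=config.chromosomes,
        extra_alts=extra_alts,
    )


def sampled_nuclei(config: SimulationConfig) -> list[int]:
    """The nuclei drawn (without replacement) for single-nucleus sequencing."""
    rng = _rng(config, _TAG_SAMPLING)
    return sorted(
        int(x) for x in rng.choice(config.n_nuclei_total, config.n_nuclei_sampled, replace=False)
    )


def nucleus_sample_name(nucleus_id: int) -> str:
    return f"nucleus_{nucleus_id:03d}"


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def simulate_regions(config: SimulationConfig) -> RegionSet:
    """Tile the genome into blocks labelled CDS / nonrepetitive / repetitive."""
    rng = _rng(config, _TAG_REGIONS)
    labels = ("CDS", "nonrepetitive", "repetitive")
    records: list[tuple[str, int, int, str]] = []
    for chrom, length in config.chromosomes.items():
        start = 0
        while start < length:
            end = min(start + config.region_block_size, length)
            lab = labels[int(rng.choice(3, p=list(config.region_fractions)))]
            records.append((chrom, start, end, lab))
            start = end
    return RegionSet.from_records(records)


# ---------------------------------------------------------------------------
# pooled design
# ---------------------------------------------------------------------------

def _pooled_counts_one(
    config: SimulationConfig,
    chrom: str,
    chrom_idx: int,
    pos: int,
    ref: str,
    alt: str | None,
    carrier_fraction: float,
) -> dict[str, int]:
    """Allele read counts for the pool at one position (position-keyed stream)."""
    rng = _rng(config, _TAG_POOLED, 1, chrom_idx, pos)
    depth = int(rng.poisson(config.pooled_depth_mean))
    counts: dict[str, int] = {}
    n_alt = 0
    if alt is not None and carrier_fraction > 0:
        n_alt = int(rng.binomial(depth, carrier_fraction))
        if n_alt:
            counts[alt] = n_alt
    remaining = depth - n_alt
    if config.base_error_rate > 0 and remaining > 0:
        n_err = int(rng.binomial(remaining, config.base_error_rate))
        if n_err:
            others = [b for b in "ACGT" if b != ref]
            split = rng.multinomial(n_err, [1 / 3] * 3)
            for b, n in zip(others, split):
                if n:
                    counts[b] = counts.get(b, 0) + int(n)
            remaining -= n_err
    if remaining > 0:
        counts[ref] = counts.get(ref, 0) + remaining
    return counts


def simulate_pooled_counts(
    truth: SimulationTruth,
    config: SimulationConfig,
    positions: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Pooled whole-organism read counts as a tidy pileup table.

    ``positions`` defaults to the truth's variant sites; arbitrary extra
    positions (1-based) may be queried and receive error-channel-only counts.
    """
    chrom_order = {c: i for i, c in enumerate(truth.chromosomes)}
    index = truth.site_index()
    if positions is None:
        positions = [(c, p) for c, p, _, _ in truth.variant_sites]
    rows: list[tuple] = []
    for chrom, pos in positions:
        ci = chrom_order[chrom]
        i = index.get((chrom, pos))
        if i is not None:
            _, _, ref, alt = truth.variant_sites[i]
            counts = _pooled_counts_one(
                config, chrom, ci, pos, ref, alt, float(truth.carrier_fraction[i])
            )
            if i in truth.extra_alts:
                alt2, extra = truth.extra_alts[i]
                rng2 = _rng(config, _TAG_POOLED, 2, ci, pos)
                n2 = int(rng2.binomial(counts.get(ref, 0), len(extra) / truth.n_nuclei_total))
                if n2:
                    counts[ref] = counts.get(ref, 0) - n2
                    counts[alt2] = counts.get(alt2, 0) + n2
        else:
            ref = _ref_base_at(config, ci, pos)
            counts = _pooled_counts_one(config, chrom, ci, pos, ref, None, 0.0)
        for allele, n in sorted(counts.items()):
            if n > 0:
                rows.append((chrom, pos, ref, allele, "pool", n))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "allele", "sample", "reads"])


# ---------------------------------------------------------------------------
# single-nucleus design
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def simulate_coverage_mask(config: SimulationConfig, nucleus_id: int) -> CoverageMask:
    """Patchy MDA coverage: exponentially sized intervals merged to the target
    >=5x fraction, then trimmed so the covered total hits the target exactly.

    Deterministic in (config, nucleus_id), hence safely memoised."""
    rng = _rng(config, _TAG_MASK, nucleus_id)
    lo, hi = config.nucleus_coverage_fraction_5x
    frac = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    target = int(round(frac * config.total_genome_bp))
    chroms = list(config.chromosomes.items())
    if frac >= 1.0:
        return CoverageMask(
            sample=nucleus_sample_name(nucleus_id),
            threshold=5,
            intervals={c: np.array([[0, l]], dtype=np.int64) for c, l in chroms},
        )
    lengths = np.array([l for _, l in chroms], dtype=float)
    probs = lengths / lengths.sum()
    raw: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in chroms}
    covered = 0
    while covered < target:
        # draw a batch sized to the expected remaining shortfall, merge once
        shortfall = target - covered
        batch = max(8, int(shortfall / config.mask_interval_mean_bp))
        cis = rng.choice(len(chroms), size=batch, p=probs)
        sizes = np.maximum(1, rng.exponential(config.mask_interval_mean_bp, batch).astype(int))
        for ci, size in zip(cis, sizes):
            chrom, length = chroms[int(ci)]
            start = int(rng.integers(0, length))
            raw[chrom].append((start, min(start + int(size), length)))
        merged = {c: merge_intervals(ivs) for c, ivs in raw.items() if ivs}
        raw = {c: [tuple(iv) for iv in a] for c, a in merged.items()}
        for c, _ in chroms:
            raw.setdefault(c, [])
        covered = sum(int((a[:, 1] - a[:, 0]).sum()) for a in merged.values())
    # trim the overshoot from the end of the last chromosome's interval list
    intervals: dict[str, np.ndarray] = {}
    budget = target
    for chrom, _ in chroms:
        arr = merge_intervals(raw[chrom]) if raw[chrom] else np.empty((0, 2), dtype=np.int64)
        kept: list[tuple[int, int]] = []
        for s, e in arr:
            if budget <= 0:
                break
            span = min(int(e - s), budget)
            kept.append((int(s), int(s) + span))
            budget -= span
        intervals[chrom] = np.asarray(kept, dtype=np.int64).reshape(-1, 2)
    return CoverageMask(
        sample=nucleus_sample_name(nucleus_id), threshold=5, intervals=intervals
    )


def _nucleus_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    """Overdispersed MDA depth, guaranteed >= 5 inside the >=5x mask."""
    mu = max(config.nucleus_depth_mean - 5.0, 0.1)
    r = config.nucleus_depth_dispersion
    return 5 + int(rng.negative_binomial(r, r / (r + mu)))


def _nucleus_counts_one(
    config: SimulationConfig,
    chrom_idx: int,
    pos: int,
    nucleus_id: int,
    ref: str,
    alt: str | None,
    is_carrier: bool,
) -> dict[str, int]:
    rng = _rng(config, _TAG_NUCLEUS, nucleus_id, chrom_idx, pos)
    depth = _nucleus_depth(config, rng)
    counts: dict[str, int] = {}
    if alt is not None:
        # cross-contamination between the carried and the non-carried allele
        carried, other = (alt, ref) if is_carrier else (ref, alt)
        n_other = int(rng.binomial(depth, config.mda_noise_rate))
        if depth - n_other:
            counts[carried] = depth - n_other
        if n_other:
            counts[other] = n_other
    else:
        n_err = int(rng.binomial(depth, config.base_error_rate))
        if n_err:
            others = [b for b in "ACGT" if b != ref]
            split = rng.multinomial(n_err, [1 / 3] * 3)
            for b, n in zip(others, split):
                if n:
                    counts[b] = int(n)
        if depth - n_err:
            counts[ref] = depth - n_err
    return counts


def simulate_nucleus_counts(
    truth: SimulationTruth,
    config: SimulationConfig,
    positions: Sequence[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, dict[str, CoverageMask]]:
    """Per-nucleus read counts (tidy pileup) plus the >=5x coverage masks.

    Sites outside a nucleus's mask produce no rows for that nucleus.
    """
    sampled = sampled_nuclei(config)
    masks = {nucleus_sample_name(n): simulate_coverage_mask(config, n) for n in sampled}
    chrom_order = {c: i for i, c in enumerate(truth.chromosomes)}
    index = truth.site_index()
    if positions is None:
        positions = [(c, p) for c, p, _, _ in truth.variant_sites]
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append((chrom, pos))
    rows: list[tuple] = []
    for nid in sampled:
        sample = nucleus_sample_name(nid)
        mask = masks[sample]
        for chrom, sites in by_chrom.items():
            pos0 = np.array([p - 1 for _, p in sites], dtype=np.int64)
            inside = positions_in_intervals(pos0, mask.chrom_intervals(chrom))
            ci = chrom_order[chrom]
            for (c, pos), ok in zip(sites, inside):
                if not ok:
                    continue
                i = index.get((c, pos))
                if i is not None:
                    _, _, ref, alt = truth.variant_sites[i]
                    carrier = nid in truth.carrier_sets[i]
                    counts = _nucleus_counts_one(config, ci, pos, nid, ref, alt, carrier)
                    if i in truth.extra_alts and not carrier:
                        alt2, extra = truth.extra_alts[i]
                        if nid in extra:
                            counts = {alt2: sum(counts.values())}
                else:
                    ref = _ref_base_at(config, ci, pos)
                    counts = _nucleus_counts_one(config, ci, pos, nid, ref, None, False)
                for allele, n in sorted(counts.items()):
                    if n > 0:
                        rows.append((c, pos, ref, allele, sample, n))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "allele", "sample", "reads"])
    if not df.empty:
        df = df.sort_values(["chrom", "pos", "sample", "allele"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df, masks


# ---------------------------------------------------------------------------
# VCF call-set emulation and fixture output
# ---------------------------------------------------------------------------

def _variants_from_pileup(
    pileup: pd.DataFrame,
    truth: SimulationTruth,
    samples: Sequence[str],
) -> list[CalledVariant]:
    """Emulate a caller: truth sites with >=1 alternate read become records.

    QUAL grows with the alternate evidence (10 per supporting read), so sites
    with minimal support fall below a QUAL>30 filter just as marginal calls do
    in real call sets.
    """
    out: list[CalledVariant] = []
    if pileup.empty:
        return out
    grouped = {k: g for k, g in pileup.groupby(["chrom", "pos"], sort=False)}
    for i, (chrom, pos, ref, alt) in enumerate(truth.variant_sites):
        g = grouped.get((chrom, pos))
        if g is None:
            continue
        alts: list[str] = [alt]
        if i in truth.extra_alts:
            observed2 = truth.extra_alts[i][0]
            if (g["allele"] == observed2).any():
                alts.append(observed2)
        per_sample: dict[str, tuple[int, tuple[int, ...]]] = {}
        total_alt = 0
        for s, gs in g.groupby("sample"):
            counts = dict(zip(gs["allele"], gs["reads"]))
            ro = int(counts.get(ref, 0))
            ao = tuple(int(counts.get(a, 0)) for a in alts)
            per_sample[str(s)] = (ro, ao)
            total_alt += sum(ao)
        if total_alt >= 1:
            out.append(
                CalledVariant(
                    chromosome=chrom,
                    position=pos,
                    ref_allele=ref,
                    alt_alleles=tuple(alts),
                    qual=float(min(10.0 * total_alt, 10_000.0)),
                    per_sample_counts=per_sample,
                )
            )
    return out


def pooled_callset(truth: SimulationTruth, config: SimulationConfig) -> list[CalledVariant]:
    pileup = simulate_pooled_counts(truth, config)
    return _variants_from_pileup(pileup, truth, ["pool"])


def nucleus_callset(
    truth: SimulationTruth, config: SimulationConfig
) -> tuple[list[CalledVariant], pd.DataFrame, dict[str, CoverageMask]]:
    pileup, masks = simulate_nucleus_counts(truth, config)
    return _variants_from_pileup(pileup, truth, sorted(masks)), pileup, masks


def write_truth_tsv(truth: SimulationTruth, path: str | Path) -> None:
    rows = [
        {
            "chrom": c,
            "pos": p,
            "ref": r,
            "alt": a,
            "n_carriers": len(cs),
            "carrier_fraction": cf,
            "carriers": ",".join(str(x) for x in sorted(cs)),
        }
        for (c, p, r, a), cs, cf in zip(
            truth.variant_sites, truth.carrier_sets, truth.carrier_fraction
        )
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fixtures(truth: SimulationTruth, config: SimulationConfig, out_dir: str | Path) -> dict:
    """Emit the full fixture bundle: VCFs, region BED, mask BEDs, pileups, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = simulate_regions(config)
    pooled_pileup = simulate_pooled_counts(truth, config)
    pooled_vars = _variants_from_pileup(pooled_pileup, truth, ["pool"])
    nuclei_vars, nuclei_pileup, masks = nucleus_callset(truth, config)
    paths = {
        "truth": out / "truth.tsv",
        "regions": out / "regions.bed",
        "pooled_vcf": out / "pooled.vcf",
        "pooled_pileup": out / "pooled_pileup.tsv",
        "nuclei_vcf": out / "nuclei.vcf",
        "nuclei_pileup": out / "nuclei_pileup.tsv",
        "masks": {},
    }
    write_truth_tsv(truth, paths["truth"])
    write_regions(regions, paths["regions"])
    write_pileup(pooled_pileup, paths["pooled_pileup"])
    write_pileup(nuclei_pileup, paths["nuclei_pileup"])
    write_vcf(pooled_vars, paths["pooled_vcf"], samples=["pool"], contigs=truth.chromosomes)
    write_vcf(nuclei_vars, paths["nuclei_vcf"], samples=sorted(masks), contigs=truth.chromosomes)
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for sample, mask in masks.items():
        p = mask_dir / f"{sample}.5x.bed"
        write_coverage_mask(mask, p)
        paths["masks"][sample] = p
    return paths


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """The recovery-limit conditions: no errors, full coverage everywhere."""
    return replace(
        config,
        base_error_rate=0.0,
        mda_noise_rate=0.0,
        nucleus_coverage_fraction_5x=(1.0, 1.0),
    )
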