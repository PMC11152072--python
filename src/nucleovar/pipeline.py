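"""End-to-end orchestration: simulate (or load), filter, and run the three
analyses (spectra, concordance, diversity) into one machine-readable report.

Stage order follows the method: I/O -> quality/biallelic subsetting ->
design-specific filters -> allele-frequency spectra -> cross-design
concordance with random-site nulls -> densities and richness.  The whole run
is a pure function of the configuration, so identical config + seed yields an
identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    UncalledClassification,
    annotate_provenance,
    category_table,
    classify_uncalled_nuclei,
    classify_uncalled_pooled,
    compare_proportions,
    intersect_callsets,
    sample_random_sites,
)
from .diversity import (
    build_incidence,
    chao2_estimate,
    density_from_asymptote,
    snp_density_nucleus,
    snp_density_pooled,
)
from .filtering import (
    FilterAudit,
    FilterParams,
    NucleusGenotype,
    build_genotype_matrix,
    filter_pooled,
    filter_quality_biallelic,
    population_filter,
    subset_by_regions,
)
from .simulate import (
    SimulationConfig,
    nucleus_callset,
    pooled_callset,
    simulate_nucleus_counts,
    simulate_pooled_counts,
    simulate_regions,
    simulate_truth,
)
from .spectrum import make_record, spectrum_table, summarize_spectrum
from .variant_io import extract_counts_at

logger = logging.getLogger("nucleovar")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; simulation-driven by default."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterParams = field(default_factory=FilterParams)
    bin_scheme: str = "rounded"
    region_label: str = "CDS"
    density_labels: tuple[str, ...] = ("CDS", "nonrepetitive")
    random_replicates: int = 10
    random_sites_n: int | None = None  # default: match the uncalled-set size

    def __post_init__(self) -> None:
        if self.random_replicates < 1:
            raise ValueError("need at least one random replicate")

    def fingerprint(self) -> str:
        payload = json.dumps(
            {"config": _as_jsonable(self), "version": __version__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


@dataclass
class RunReport:
    """All results of one pipeline run, JSON-serialisable."""

    fingerprint: str
    stage_counts: dict[str, int]
    pooled_spectrum: pd.DataFrame
    nucleus_spectrum: pd.DataFrame | None
    concordance: dict[str, Any]
    uncalled_pooled: pd.DataFrame | None
    uncalled_nuclei: pd.DataFrame | None
    provenance_nuclei: dict[str, int] | None
    chi_square_pooled: pd.DataFrame | None
    chi_square_nuclei: pd.DataFrame | None
    densities: pd.DataFrame
    richness: dict[str, Any]
    aaf_records: dict[str, list] = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(self).items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def validate_report(report_dict: dict) -> None:
    """Check a report dict against the shipped JSON schema (required keys
    and primitive types only)."""
    schema = json.loads(
        resources.files("nucleovar").joinpath("schemas/run_report.schema.json").read_text()
    )
    _check_schema(report_dict, schema, path="report")


def _check_schema(obj: Any, schema: dict, path: str) -> None:
    t = schema.get("type")
    mapping = {"object": dict, "array": list, "string": str, "number": (int, float),
               "integer": int, "boolean": bool}
    if t == "null_or_object":
        if obj is not None:
            _check_schema(obj, {**schema, "type": "object"}, path)
        return
    if t in mapping and not isinstance(obj, mapping[t]) and obj is not None:
        raise ValueError(f"{path}: expected {t}, got {type(obj).__name__}")
    for key, sub in schema.get("properties", {}).items():
        if key in schema.get("required", []) and (not isinstance(obj, dict) or key not in obj):
            raise ValueError(f"{path}: missing required key {key!r}")
        if isinstance(obj, dict) and key in obj:
            _check_schema(obj[key], sub, f"{path}.{key}")


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis on one simulated organism."""
    sim = config.simulation
    params = config.filters
    logger.info("pipeline start: seed=%d fingerprint=%s", sim.seed, config.fingerprint())

    truth = simulate_truth(sim)
    regions = simulate_regions(sim)
    stage_counts: dict[str, int] = {"truth_sites": truth.n_sites}

    # --- pooled branch -----------------------------------------------------
    audit_pooled = FilterAudit()
    pooled_vars = pooled_callset(truth, sim)
    stage_counts["pooled_initial_calls"] = len(pooled_vars)
    pooled_bi, pooled_multi, pooled_other = filter_quality_biallelic(
        pooled_vars, params, audit_pooled
    )
    stage_counts["pooled_biallelic_qual"] = len(pooled_bi)
    pooled_kept = filter_pooled(pooled_bi, params, audit=audit_pooled)
    stage_counts["pooled_filtered"] = len(pooled_kept)
    pooled_by_key = {v.key: v for v in pooled_kept}
    pooled_cds = subset_by_regions(pooled_by_key, regions, config.region_label)
    stage_counts["pooled_filtered_cds"] = len(pooled_cds)

    pooled_records = []
    for v in pooled_kept:
        ro, ao = v.per_sample_counts["pool"]
        pooled_records.append(
            make_record(v.key, ao[0], ro + ao[0], "read_based", config.bin_scheme)
        )
    pooled_summary = summarize_spectrum(pooled_records)

    # --- single-nucleus branch --------------------------------------------
    audit_nuc = FilterAudit()
    nuc_vars, nuc_pileup, masks = nucleus_callset(truth, sim)
    nuclei = sorted(masks)
    stage_counts["nuclei_initial_calls"] = len(nuc_vars)
    nuc_bi, _, _ = filter_quality_biallelic(nuc_vars, params, audit_nuc)
    stage_counts["nuclei_biallelic_qual"] = len(nuc_bi)
    nuc_sites = [v.key for v in nuc_bi]
    matrix = build_genotype_matrix(nuc_pileup, nuc_sites, nuclei, params)
    nuc_kept = population_filter(matrix, params, audit_nuc)
    stage_counts["nuclei_filtered"] = len(nuc_kept)
    nuc_cds = subset_by_regions(nuc_kept, regions, config.region_label)
    stage_counts["nuclei_filtered_cds"] = len(nuc_cds)

    site_row = {k: i for i, k in enumerate(matrix.sites)}
    nuc_records = []
    for k in nuc_kept:
        row = matrix.row(site_row[k])
        n_alt = int((row == NucleusGenotype.ALT).sum())
        n_ref = int((row == NucleusGenotype.REF).sum())
        nuc_records.append(
            make_record(k, n_alt, n_alt + n_ref, "nucleus_based", config.bin_scheme)
        )
    nucleus_summary = summarize_spectrum(nuc_records) if nuc_records else None

    # --- concordance (within the focal region label) -----------------------
    conc = intersect_callsets(pooled_cds, nuc_cds)
    concordance_summary = {
        "shared": len(conc.shared),
        "pooled_exclusive": len(conc.a_exclusive),
        "nuclei_exclusive": len(conc.b_exclusive),
        "shared_percentage": conc.shared_percentage,
    }

    def classify_in_nuclei(positions: Sequence[tuple[str, int]]):
        pileup, _ = simulate_nucleus_counts(truth, sim, positions=positions)
        idx = truth.site_index()
        keys = []
        for c, p in positions:
            i = idx.get((c, p))
            ref, alt = (truth.variant_sites[i][2], truth.variant_sites[i][3]) if i is not None else ("N", "N")
            keys.append((c, p, ref, alt))
        m = build_genotype_matrix(pileup, keys, nuclei, params)
        return [
            classify_uncalled_nuclei(m.row(i), site=(k[0], k[1]))
            for i, k in enumerate(keys)
        ]

    def classify_in_pooled(positions: Sequence[tuple[str, int]]):
        pileup = simulate_pooled_counts(truth, sim, positions=positions)
        sites = extract_counts_at(positions, pileup)
        return [classify_uncalled_pooled(s) for s in sites]

    uncalled_pooled_tbl = uncalled_nuclei_tbl = None
    chi_pooled = chi_nuclei = None
    provenance_counts = None

    # sites exclusive to the single-nucleus design, interrogated in the pool
    if conc.b_exclusive:
        positions = sorted((k[0], k[1]) for k in conc.b_exclusive)
        cls_pooled = classify_in_pooled(positions)
        uncalled_pooled_tbl = category_table(cls_pooled)
        n_rand = config.random_sites_n or len(positions)
        rand_sets = []
        for r in range(config.random_replicates):
            rpos = sample_random_sites(regions, config.region_label, n_rand, sim.seed, r)
            rand_sets.append(classify_in_pooled(rpos))
        chi_pooled = compare_proportions(
            _potential_split(cls_pooled), [_potential_split(c) for c in rand_sets]
        )

    # sites exclusive to the pooled design, interrogated across nuclei
    if conc.a_exclusive:
        positions = sorted((k[0], k[1]) for k in conc.a_exclusive)
        cls_nuc = classify_in_nuclei(positions)
        initial_locs = {v.key for v in nuc_bi}
        cls_nuc = [annotate_provenance(c, initial_locs, audit_nuc) for c in cls_nuc]
        uncalled_nuclei_tbl = category_table(cls_nuc)
        provenance_counts = {
            flag: sum(1 for c in cls_nuc if c.provenance == flag)
            for flag in sorted({c.provenance for c in cls_nuc})
        }
        n_rand = config.random_sites_n or len(positions)
        rand_sets = []
        for r in range(config.random_replicates):
            rpos = sample_random_sites(
                regions, config.region_label, n_rand, sim.seed + 1000, r
            )
            rand_sets.append(classify_in_nuclei(rpos))
        chi_nuclei = compare_proportions(
            _potential_split(cls_nuc), [_potential_split(c) for c in rand_sets]
        )

    # --- diversity ---------------------------------------------------------
    density_rows = []
    for label in config.density_labels:
        d = snp_density_pooled(list(pooled_by_key), regions, label)
        density_rows.append(_density_row(d))
    per_nucleus_alt: dict[str, list] = {}
    for j, sample in enumerate(matrix.nuclei):
        alt_keys = [
            matrix.sites[i] for i in range(matrix.n_sites)
            if matrix.grid[i, j] == NucleusGenotype.ALT
        ]
        per_nucleus_alt[sample] = alt_keys
        for label in config.density_labels:
            try:
                d = snp_density_nucleus(
                    [(k[0], k[1]) for k in alt_keys], regions, label, masks[sample]
                )
            except ValueError:
                # a patchy nucleus may not cover this fraction at all
                logger.info("nucleus %s covers no %s bp; density skipped", sample, label)
                continue
            density_rows.append(_density_row(d))
    densities = pd.DataFrame(density_rows)

    per_nucleus_cds = {
        s: subset_by_regions(keys, regions, config.region_label)
        for s, keys in per_nucleus_alt.items()
    }
    richness: dict[str, Any] = {}
    if any(per_nucleus_cds.values()):
        incidence = build_incidence(per_nucleus_cds)
        est = chao2_estimate(incidence)
        richness = {
            "s_obs": est.s_obs, "q1": est.q1, "q2": est.q2, "T": est.T,
            "estimate": est.estimate,
            "singleton_fraction": incidence.singleton_fraction,
            "asymptotic_density_per_kb": density_from_asymptote(
                est, regions.covered_bp(config.region_label)
            ),
            "curve": est.curve,
        }

    report = RunReport(
        fingerprint=config.fingerprint(),
        stage_counts=stage_counts,
        pooled_spectrum=spectrum_table(pooled_summary),
        nucleus_spectrum=spectrum_table(nucleus_summary) if nucleus_summary else None,
        concordance=concordance_summary,
        uncalled_pooled=uncalled_pooled_tbl,
        uncalled_nuclei=uncalled_nuclei_tbl,
        provenance_nuclei=provenance_counts,
        chi_square_pooled=chi_pooled,
        chi_square_nuclei=chi_nuclei,
        densities=densities,
        richness=richness,
        aaf_records={
            "read_based": [r.aaf for r in pooled_records],
            "nucleus_based": [r.aaf for r in nuc_records],
        },
    )
    logger.info("pipeline done: %s", concordance_summary)
    return report


def _potential_split(classifications: Sequence[UncalledClassification]) -> tuple[int, int]:
    n_pot = sum(1 for c in classifications if c.category == "potential_snp")
    return n_pot, len(classifications) - n_pot


def _density_row(d) -> dict:
    return {
        "scope": d.scope, "label": d.label, "snp_count": d.snp_count,
        "denominator_bp": d.denominator_bp, "snps_per_kb": d.snps_per_kb,
    }


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_tables(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report and its tabular sections as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    frames = {
        "pooled_spectrum": report.pooled_spectrum,
        "nucleus_spectrum": report.nucleus_spectrum,
        "uncalled_pooled": report.uncalled_pooled,
        "uncalled_nuclei": report.uncalled_nuclei,
        "chi_square_pooled": report.chi_square_pooled,
        "chi_square_nuclei": report.chi_square_nuclei,
        "densities": report.densities,
    }
    if isinstance(report.richness.get("curve"), pd.DataFrame):
        frames["accumulation_curve"] = report.richness["curve"]
    for name, df in frames.items():
        if df is None:
            continue
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = out / "report.json"
    p.write_text(report.to_json(indent=2))
    paths["report"] = p
    return paths


#: fixed plotting order of the uncalled-site categories
CATEGORY_PLOT_ORDER = ("potential_snp", "invariant", "other_variants",
                       "missing_data", "no_coverage")


def render_figures(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Spectrum histograms, accumulation curve and category bar plots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, mode, title in zip(
        axes, ("read_based", "nucleus_based"), ("pooled (read-based AAF)", "single nuclei (nucleus-based AAF)")
    ):
        vals = report.aaf_records.get(mode, [])
        ax.hist(vals, bins=np.arange(0, 1.05, 0.05), color="#41668c")
        ax.set_xlabel("alternate allele frequency")
        ax.set_ylabel("SNPs")
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    p = out / "aaf_spectrum.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["aaf_spectrum"] = p

    curve = report.richness.get("curve")
    if isinstance(curve, pd.DataFrame):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for method, style in (("rarefied", "-"), ("observed", "o"), ("extrapolated", "--")):
            part = curve[curve["method"] == method]
            ax.plot(part["t"], part["s_estimate"], style, color="#2d6a4f", label=method)
        ax.set_xlabel("nuclei sampled")
        ax.set_ylabel("distinct alternate-allele sites")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / "accumulation_curve.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths["accumulation_curve"] = p

    for name, df in (("uncalled_pooled", report.uncalled_pooled),
                     ("uncalled_nuclei", report.uncalled_nuclei)):
        if df is None:
            continue
        df = df.set_index("category").reindex(
            [c for c in CATEGORY_PLOT_ORDER if c in set(df["category"])]
        ).reset_index()
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(df["category"], df["percent"], color="#9d4e4e")
        ax.set_ylabel("% of uncalled sites")
        ax.tick_params(axis="x", labelrotation=30, labelsize=8)
        fig.tight_layout()
        p = out / f"{name}_categories.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[name] = p
    return paths
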