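"""Simulator: determinism, distributional targets, masks, fixtures."""

import numpy as np
import pandas as pd
import pytest

from nucleovar.simulate import (
    SimulationConfig,
    SimulationTruth,
    noise_free,
    sampled_nuclei,
    simulate_coverage_mask,
    simulate_nucleus_counts,
    simulate_pooled_counts,
    simulate_regions,
    simulate_truth,
    write_fixtures,
)
from nucleovar.variant_io import read_pileup, read_regions, read_vcf

TINY = SimulationConfig(genome_length=(100_000,), n_variant_sites=40, seed=5)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            SimulationConfig(base_error_rate=1.5).validate()

    def test_oversampling(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_nuclei_total=10, n_nuclei_sampled=11).validate()

    def test_genome_too_small(self):
        with pytest.raises(ValueError, match="cannot hold"):
            simulate_truth(SimulationConfig(genome_length=(100,), n_variant_sites=200))


class TestTruth:
    def test_empty_truth(self):
        truth = simulate_truth(
            SimulationConfig(genome_length=(10_000,), n_variant_sites=0, seed=1)
        )
        assert truth.n_sites == 0

    def test_seeded_determinism(self):
        cfg = SimulationConfig(genome_length=(50_000,), n_variant_sites=30, seed=7)
        a, b = simulate_truth(cfg), simulate_truth(cfg)
        assert a.variant_sites == b.variant_sites
        assert a.carrier_sets == b.carrier_sets

    def test_positions_unique_alleles_valid(self):
        truth = simulate_truth(TINY)
        assert len({(c, p) for c, p, _, _ in truth.variant_sites}) == truth.n_sites
        for _, _, ref, alt in truth.variant_sites:
            assert ref != alt and ref in "ACGT" and alt in "ACGT"

    def test_singleton_fraction_binomial(self):
        cfg = SimulationConfig(
            genome_length=(5_000_000,), n_variant_sites=1000, singleton_fraction=0.76, seed=9
        )
        truth = simulate_truth(cfg)
        n1 = sum(1 for cs in truth.carrier_sets if len(cs) == 1)
        # 4-sigma binomial band around 760 of 1000
        sigma = np.sqrt(1000 * 0.76 * 0.24)
        assert abs(n1 - 760) < 4 * sigma

    def test_truth_invariants_enforced(self):
        with pytest.raises(ValueError, match="carrier set"):
            SimulationTruth(
                [("chr1", 1, "A", "T")], [frozenset()], np.array([0.5]), 10, {"chr1": 100}
            )
        with pytest.raises(ValueError, match="duplicate"):
            SimulationTruth(
                [("chr1", 1, "A", "T"), ("chr1", 1, "C", "G")],
                [frozenset({1})] * 2,
                np.array([0.5, 0.5]),
                10,
                {"chr1": 100},
            )


def _uniform_truth(n_sites, carriers, n_total, chrom_len=10_000_000):
    """Hand-built truth with identical carrier fraction at every site."""
    sites = [("chr1", 10 * (i + 1), "A", "T") for i in range(n_sites)]
    cs = [frozenset(range(carriers))] * n_sites
    cf = np.full(n_sites, carriers / n_total)
    return SimulationTruth(sites, cs, cf, n_total, {"chr1": chrom_len})


class TestPooledCounts:
    def test_error_channel_off(self):
        cfg = SimulationConfig(
            genome_length=(10_000_000,), n_variant_sites=1, base_error_rate=0.0, seed=1
        )
        truth = _uniform_truth(1, 100, 200)
        df = simulate_pooled_counts(truth, cfg, positions=[("chr1", 999_999)])
        assert set(df["allele"]) <= {df["ref"].iloc[0]}  # non-variant: only ref reads

    def test_fixation_limit(self):
        cfg = SimulationConfig(
            genome_length=(10_000_000,), n_variant_sites=1, base_error_rate=0.0, seed=1
        )
        truth = _uniform_truth(1, 200, 200)
        df = simulate_pooled_counts(truth, cfg)
        assert (df["allele"] == "T").all()

    def test_mean_alt_fraction_unbiased(self):
        cfg = SimulationConfig(
            genome_length=(10_000_000,), n_variant_sites=10_000, base_error_rate=0.0, seed=2
        )
        truth = _uniform_truth(10_000, 100, 200)
        df = simulate_pooled_counts(truth, cfg)
        totals = df.groupby("pos")["reads"].sum()
        alts = df[df["allele"] == "T"].groupby("pos")["reads"].sum().reindex(totals.index, fill_value=0)
        mean_frac = float((alts / totals).mean())
        # Monte-Carlo error of the mean over 10,000 Binomial(86, .5) sites
        assert mean_frac == pytest.approx(0.5, abs=0.003)

    def test_depth_conservation(self):
        truth = simulate_truth(TINY)
        df = simulate_pooled_counts(truth, TINY)
        depth = df.groupby(["chrom", "pos"])["reads"].sum()
        assert (depth > 0).all()  # ref + alt + error reads account for full depth

    def test_position_keyed_determinism(self):
        truth = simulate_truth(TINY)
        full = simulate_pooled_counts(truth, TINY)
        chrom, pos = truth.variant_sites[3][:2]
        alone = simulate_pooled_counts(truth, TINY, positions=[(chrom, pos)])
        merged = full[(full["pos"] == pos)].reset_index(drop=True)
        pd.testing.assert_frame_equal(alone.reset_index(drop=True), merged)


class TestCoverageMask:
    def test_target_fraction_exact(self):
        cfg = SimulationConfig(
            genome_length=(1_000_000,), nucleus_coverage_fraction_5x=(0.4, 0.4), seed=3
        )
        mask = simulate_coverage_mask(cfg, 0)
        assert mask.covered_bp() == 400_000

    def test_full_coverage(self):
        cfg = SimulationConfig(
            genome_length=(50_000,), nucleus_coverage_fraction_5x=(1.0, 1.0), seed=3
        )
        mask = simulate_coverage_mask(cfg, 1)
        assert mask.covered_bp() == 50_000

    def test_deterministic_per_nucleus(self):
        cfg = SimulationConfig(genome_length=(200_000,), seed=4)
        a = simulate_coverage_mask(cfg, 2)
        b = simulate_coverage_mask(cfg, 2)
        c = simulate_coverage_mask(cfg, 3)
        assert a.covered_bp() == b.covered_bp()
        assert a.intervals.keys() == b.intervals.keys()
        assert c.covered_bp() != a.covered_bp() or not np.array_equal(
            a.intervals["chr1"], c.intervals["chr1"]
        )


class TestNucleusCounts:
    def test_noise_off_pure_carrier(self):
        cfg = noise_free(
            SimulationConfig(genome_length=(100_000,), n_variant_sites=20, seed=6)
        )
        truth = simulate_truth(cfg)
        df, masks = simulate_nucleus_counts(truth, cfg)
        sampled = sampled_nuclei(cfg)
        idx = truth.site_index()
        for row in df.itertuples(index=False):
            i = idx[(row.chrom, row.pos)]
            nid = int(row.sample.split("_")[1])
            carrier = nid in truth.carrier_sets[i]
            expected = truth.variant_sites[i][3] if carrier else truth.variant_sites[i][2]
            assert row.allele == expected

    def test_dropout_outside_mask(self):
        cfg = SimulationConfig(
            genome_length=(500_000,),
            n_variant_sites=50,
            nucleus_coverage_fraction_5x=(0.2, 0.2),
            seed=8,
        )
        truth = simulate_truth(cfg)
        df, masks = simulate_nucleus_counts(truth, cfg)
        for row in df.itertuples(index=False):
            assert masks[row.sample].contains(row.chrom, row.pos)

    def test_depth_at_least_five_in_mask(self):
        truth = simulate_truth(TINY)
        df, _ = simulate_nucleus_counts(truth, TINY)
        depth = df.groupby(["chrom", "pos", "sample"])["reads"].sum()
        assert (depth >= 5).all()

    def test_sampling_without_replacement(self):
        s = sampled_nuclei(TINY)
        assert len(s) == len(set(s)) == TINY.n_nuclei_sampled
        assert max(s) < TINY.n_nuclei_total


class TestFixtures:
    def test_bundle_round_trips(self, tmp_path):
        truth = simulate_truth(TINY)
        paths = write_fixtures(truth, TINY, tmp_path)
        pooled = read_vcf(paths["pooled_vcf"])
        nuclei = read_vcf(paths["nuclei_vcf"])
        assert 0 < len(pooled) <= truth.n_sites
        assert 0 < len(nuclei) <= truth.n_sites
        pileup = read_pileup(paths["pooled_pileup"])
        assert set(pileup["pos"]) == {p for _, p, _, _ in truth.variant_sites}
        regions = read_regions(paths["regions"])
        assert sum(regions.covered_bp(l) for l in regions.labels()) == TINY.total_genome_bp
        truth_df = pd.read_csv(paths["truth"], sep="\t")
        assert len(truth_df) == truth.n_sites
        # VCF content agrees with the pileup at a shared site
        v = pooled[0]
        rows = pileup[(pileup["pos"] == v.position) & (pileup["allele"] == v.alt_alleles[0])]
        assert int(rows["reads"].sum()) == v.per_sample_counts["pool"][1][0]

    def test_empty_dataset_writes_valid_header_only_vcf(self, tmp_path):
        cfg = SimulationConfig(genome_length=(10_000,), n_variant_sites=0, seed=1)
        truth = simulate_truth(cfg)
        paths = write_fixtures(truth, cfg, tmp_path)
        assert read_vcf(paths["pooled_vcf"]) == []

    def test_seeded_files_identical(self, tmp_path):
        truth = simulate_truth(TINY)
        p1 = write_fixtures(truth, TINY, tmp_path / "a")
        p2 = write_fixtures(truth, TINY, tmp_path / "b")
        assert (p1["truth"].read_bytes() == p2["truth"].read_bytes())
        assert (p1["pooled_pileup"].read_bytes() == p2["pooled_pileup"].read_bytes())
        assert (p1["nuclei_pileup"].read_bytes() == p2["nuclei_pileup"].read_bytes())
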