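"""Densities, incidence, accumulation curve and the Chao2 asymptote."""

import itertools

import numpy as np
import pytest

from nucleovar.diversity import (
    IncidenceMatrix,
    accumulation_curve,
    build_incidence,
    chao2_estimate,
    density_from_asymptote,
    snp_density_nucleus,
    snp_density_pooled,
)
from nucleovar.variant_io import CoverageMask, RegionSet


def _regions(size=240_000):
    return RegionSet.from_records([("chr1", 0, size, "CDS")])


def _sites(n, start=1000, step=10):
    return [("chr1", start + i * step, "A", "T") for i in range(n)]


class TestPooledDensity:
    def test_direct_ratio(self):
        d = snp_density_pooled(_sites(12), _regions(), "CDS")
        assert d.snps_per_kb == pytest.approx(0.05)

    def test_zero_sites(self):
        d = snp_density_pooled([], _regions(), "CDS")
        assert d.snps_per_kb == 0.0

    def test_scale_invariance(self):
        d1 = snp_density_pooled(_sites(12), _regions(240_000), "CDS")
        d2 = snp_density_pooled(_sites(24), _regions(480_000), "CDS")
        assert d1.snps_per_kb == pytest.approx(d2.snps_per_kb)

    def test_zero_size_fraction_errors(self):
        rs = RegionSet(intervals={"CDS": {}})
        with pytest.raises(ValueError):
            snp_density_pooled([], rs, "CDS")


class TestNucleusDensity:
    def test_mask_intersection(self):
        mask = CoverageMask("n1", 5, {"chr1": np.array([[0, 160_000]])})
        alt = [("chr1", p) for p in (100, 150_000, 200_000)]  # last outside mask
        d = snp_density_nucleus(alt, _regions(), "CDS", mask)
        assert d.snp_count == 2
        assert d.denominator_bp == 160_000
        assert d.snps_per_kb == pytest.approx(2000 / 160_000)

    def test_full_coverage_equals_pooled(self):
        mask = CoverageMask("n1", 5, {"chr1": np.array([[0, 240_000]])})
        alt_keys = _sites(12)
        d_nuc = snp_density_nucleus([(c, p) for c, p, _, _ in alt_keys], _regions(), "CDS", mask)
        d_pool = snp_density_pooled(alt_keys, _regions(), "CDS")
        assert d_nuc.snps_per_kb == pytest.approx(d_pool.snps_per_kb)

    def test_disjoint_mask_errors(self):
        mask = CoverageMask("n1", 5, {"chr2": np.array([[0, 100]])})
        with pytest.raises(ValueError):
            snp_density_nucleus([], _regions(), "CDS", mask)


class TestIncidence:
    def test_small_example(self):
        inc = build_incidence({"n1": ["A"], "n2": ["A", "B"]})
        assert inc.s_obs == 2 and inc.T == 2
        assert inc.q(1) == 1 and inc.q(2) == 1

    def test_disjoint_sets_all_uniques(self):
        inc = build_incidence({f"n{i}": [f"s{i}"] for i in range(5)})
        assert inc.q(1) == inc.s_obs == 5
        assert inc.singleton_fraction == 1.0

    def test_q_sums_to_s_obs(self):
        rng = np.random.default_rng(2)
        m = rng.random((30, 6)) < 0.3
        m = m[m.any(axis=1)]
        inc = IncidenceMatrix([f"s{i}" for i in range(m.shape[0])],
                              [f"n{j}" for j in range(6)], m)
        assert sum(inc.q(k) for k in range(1, 7)) == inc.s_obs

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_incidence({})


def _brute_force_curve(matrix: np.ndarray, t: int) -> float:
    """Average distinct-site count over all nucleus subsets of size t."""
    T = matrix.shape[1]
    vals = [
        int(matrix[:, list(combo)].any(axis=1).sum())
        for combo in itertools.combinations(range(T), t)
    ]
    return float(np.mean(vals))


class TestAccumulationCurve:
    def test_two_unit_example(self):
        inc = build_incidence({"n1": ["A"], "n2": ["A", "B"]})
        curve = accumulation_curve(inc, t_values=[1, 2])
        assert curve.loc[curve["t"] == 1, "s_estimate"].item() == pytest.approx(1.5)
        assert curve.loc[curve["t"] == 2, "s_estimate"].item() == 2.0

    def test_observed_at_full_effort(self):
        rng = np.random.default_rng(7)
        m = (rng.random((40, 9)) < 0.25)
        m = m[m.any(axis=1)]
        inc = IncidenceMatrix(list(range(m.shape[0])), list(range(9)), m)
        curve = accumulation_curve(inc, t_values=[9])
        assert curve["s_estimate"].item() == inc.s_obs

    def test_matches_subset_average_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            T = int(rng.integers(3, 9))
            m = rng.random((int(rng.integers(5, 25)), T)) < 0.35
            m = m[m.any(axis=1)]
            if not len(m):
                continue
            inc = IncidenceMatrix(list(range(m.shape[0])), list(range(T)), m)
            curve = accumulation_curve(inc, t_values=list(range(1, T + 1)))
            for t in range(1, T + 1):
                assert curve.loc[curve["t"] == t, "s_estimate"].item() == pytest.approx(
                    _brute_force_curve(m, t), abs=1e-9
                )

    def test_monotone_and_bounded_by_asymptote(self):
        rng = np.random.default_rng(13)
        m = rng.random((60, 8)) < 0.2
        m = m[m.any(axis=1)]
        inc = IncidenceMatrix(list(range(m.shape[0])), list(range(8)), m)
        est = chao2_estimate(inc)
        s = est.curve["s_estimate"].to_numpy()
        assert (np.diff(s) >= -1e-12).all()
        assert (s <= est.estimate + 1e-9).all()

    def test_invalid_effort_errors(self):
        inc = build_incidence({"n1": ["A"], "n2": ["B"]})
        with pytest.raises(ValueError):
            accumulation_curve(inc, t_values=[0])


class TestChao2:
    def test_direct_formula(self):
        m = np.zeros((100, 21), dtype=bool)
        m[:50, 0] = True  # 50 uniques
        for i in range(50, 60):  # 10 duplicates
            m[i, 1] = m[i, 2] = True
        for i in range(60, 100):  # the rest in 3 nuclei
            m[i, 3] = m[i, 4] = m[i, 5] = True
        inc = IncidenceMatrix(list(range(100)), list(range(21)), m)
        est = chao2_estimate(inc, with_curve=False)
        assert est.q1 == 50 and est.q2 == 10
        assert est.estimate == pytest.approx(100 + (20 / 21) * 2500 / 20, abs=1e-9)

    def test_no_uniques_no_extrapolation(self):
        inc = build_incidence({"n1": ["A", "B"], "n2": ["A", "B"]})
        est = chao2_estimate(inc, with_curve=False)
        assert est.q1 == 0 and est.estimate == est.s_obs

    def test_bias_corrected_branch_when_no_duplicates(self):
        inc = build_incidence({"n1": ["A", "C"], "n2": ["B", "C"], "n3": ["C"]})
        # C in 3 nuclei, A and B unique: Q1=2, Q2=0
        est = chao2_estimate(inc, with_curve=False)
        assert est.estimate == pytest.approx(3 + (2 / 3) * 2 * 1 / 2)

    def test_estimate_never_below_observed(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = rng.random((int(rng.integers(2, 40)), int(rng.integers(2, 12)))) < 0.3
            m = m[m.any(axis=1)]
            if not len(m):
                continue
            inc = IncidenceMatrix(list(range(m.shape[0])), list(range(m.shape[1])), m)
            assert chao2_estimate(inc, with_curve=False).estimate >= inc.s_obs

    def test_single_unit_errors(self):
        inc = build_incidence({"n1": ["A"]})
        with pytest.raises(ValueError):
            chao2_estimate(inc)


class TestAsymptoticDensity:
    def test_published_style_ratio(self):
        m = np.zeros((100, 5), dtype=bool)
        m[:, 0] = True
        inc = IncidenceMatrix(list(range(100)), list(range(5)), m)
        est = chao2_estimate(inc, with_curve=False)
        assert density_from_asymptote(est, 27_000_000) == pytest.approx(
            1000 * est.estimate / 27_000_000
        )

    def test_direct_values(self):
        est = chao2_estimate(
            build_incidence({"n1": ["A"], "n2": ["A"]}), with_curve=False
        )
        assert density_from_asymptote(est, 1_000_000) == pytest.approx(0.001)
        with pytest.raises(ValueError):
            density_from_asymptote(est, 0)

    def test_halves_with_doubled_fraction(self):
        est = chao2_estimate(build_incidence({"n1": ["A"], "n2": ["A"]}), with_curve=False)
        assert density_from_asymptote(est, 2_000_000) == pytest.approx(
            density_from_asymptote(est, 1_000_000) / 2
        )


def test_chao2_order_of_magnitude_on_simulated_population():
    """Sampling 10-20 of 200 nuclei, the asymptote lands within an order of
    magnitude of the true site count (it is a lower-bound style estimator)."""
    from nucleovar import (
        FilterParams,
        SimulationConfig,
        build_genotype_matrix,
        filter_quality_biallelic,
        nucleus_callset,
        simulate_truth,
    )
    from nucleovar.filtering import NucleusGenotype

    cfg = SimulationConfig(
        genome_length=(2_000_000,), n_variant_sites=800, n_nuclei_sampled=16, seed=23
    )
    truth = simulate_truth(cfg)
    vars_, pileup, masks = nucleus_callset(truth, cfg)
    params = FilterParams()
    bi, _, _ = filter_quality_biallelic(vars_, params)
    m = build_genotype_matrix(pileup, [v.key for v in bi], sorted(masks), params)
    per = {
        s: [m.sites[i] for i in range(m.n_sites) if m.grid[i, j] == NucleusGenotype.ALT]
        for j, s in enumerate(m.nuclei)
    }
    est = chao2_estimate(build_incidence(per), with_curve=False)
    assert est.s_obs < cfg.n_variant_sites  # partial sampling undercounts
    assert cfg.n_variant_sites / 10 <= est.estimate <= cfg.n_variant_sites * 10
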