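"""Per-site and population-level statistics: FIS, Ts/Tv, pi, DRI, Fst, scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capcore import (
    PopAssignment,
    SimulationConfig,
    TsTvUndefined,
    Zone,
    dri,
    expected_fis_selfing,
    fst_scan,
    mean_depth_per_zone_per_sample,
    nucleotide_diversity,
    pairwise_fst,
    simulate_genotypes,
    site_stats,
    site_stats_from_array,
    tstv_ratio,
)
from capcore.filtering import GenotypeCall


class TestSiteStats:
    def test_rare_homozygote_site(self):
        stats = site_stats_from_array([0] * 9 + [2])
        assert stats.p == pytest.approx(0.1)
        assert stats.he == pytest.approx(0.18)
        assert stats.ho == 0.0
        assert stats.fis == 1.0
        assert stats.minor_hom_count == 1

    def test_all_heterozygous(self):
        stats = site_stats_from_array([1] * 10)
        assert stats.p == 0.5 and stats.he == 0.5 and stats.ho == 1.0
        assert stats.fis == -1.0  # 1 - 1/0.5, clipped bound reached exactly

    def test_monomorphic_fis_undefined(self):
        stats = site_stats_from_array([0] * 10)
        assert stats.he == 0.0 and stats.fis is None

    def test_missing_calls_excluded_from_n(self):
        stats = site_stats_from_array([0, 2, -1, -1])
        assert stats.n == 2 and stats.p == 0.5

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            site_stats_from_array([-1, -1])

    def test_accepts_genotype_call_mapping(self):
        calls = {"a": GenotypeCall((0, 1)), "b": GenotypeCall((1, 1)),
                 "c": GenotypeCall(None)}
        stats = site_stats(calls)
        assert stats.n == 2 and stats.p == pytest.approx(0.75)

    def test_fis_recovers_simulated_inbreeding(self):
        """Mean per-site FIS tracks the generative inbreeding coefficient."""
        for f in (0.0, 0.5, 0.92):
            cfg = SimulationConfig(
                seed=101, populations=(("P", 200),), target_fst=0.0,
                inbreeding_f=f, n_sites=500,
            )
            sites, _s, _p, _t = simulate_genotypes(cfg)
            values = [
                st_.fis for st_ in (site_stats_from_array(s.dosages()) for s in sites)
                if st_.fis is not None
            ]
            assert np.mean(values) == pytest.approx(f, abs=0.05)


class TestSelfingFormula:
    def test_use_case_outcrossing_rate(self):
        assert expected_fis_selfing(0.04) == pytest.approx(0.9231, abs=1e-4)
        assert round(expected_fis_selfing(0.04), 2) == 0.92

    @pytest.mark.parametrize("t, expected", [(0.0, 1.0), (1.0, 0.0)])
    def test_boundaries(self, t, expected):
        assert expected_fis_selfing(t) == expected

    @pytest.mark.parametrize("t", [-0.1, 1.5])
    def test_domain(self, t):
        with pytest.raises(ValueError):
            expected_fis_selfing(t)

    @given(st.floats(0.0, 0.999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, t):
        assert expected_fis_selfing(t) > expected_fis_selfing(t + 0.001)


class TestTsTv:
    def test_classification(self):
        assert tstv_ratio([("A", "G"), ("C", "T"), ("A", "C")]) == 2.0

    def test_uniform_substitution_classes_give_half(self):
        classes = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
        assert tstv_ratio(classes) == 0.5

    def test_zero_transversions_signalled(self):
        with pytest.raises(TsTvUndefined):
            tstv_ratio([("A", "G")])

    def test_random_substitutions_converge_to_half(self, rng):
        classes = [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"), ("C", "G"), ("G", "T")]
        picks = [classes[i] for i in rng.integers(0, 6, size=10_000)]
        assert tstv_ratio(picks) == pytest.approx(0.5, abs=0.05)


class TestDiversity:
    def test_single_site_small_sample_correction(self):
        # p = 0.5 over 10 diploids: pi = 20/19 * 0.5
        dosages = [[1] * 4 + [0] * 3 + [2] * 3]
        pop = PopAssignment({f"s{i}": "P" for i in range(10)}, min_per_pop=10)
        out = nucleotide_diversity(dosages, pop, "P", [f"s{i}" for i in range(10)])
        assert out.pi == pytest.approx((20 / 19) * 0.5)
        assert out.n_sites == 1

    def test_monomorphic_sites_give_zero(self):
        pop = PopAssignment({f"s{i}": "P" for i in range(10)}, min_per_pop=5)
        out = nucleotide_diversity([[0] * 10, [2] * 10], pop, "P", [f"s{i}" for i in range(10)])
        assert out.pi == 0.0 and out.n_sites == 2

    def test_doubling_individuals_shrinks_correction(self):
        small = [[1] * 4]
        big = [[1] * 8]
        pop_s = PopAssignment({f"s{i}": "P" for i in range(4)}, min_per_pop=2)
        pop_b = PopAssignment({f"s{i}": "P" for i in range(8)}, min_per_pop=2)
        pi_small = nucleotide_diversity(small, pop_s, "P", [f"s{i}" for i in range(4)]).pi
        pi_big = nucleotide_diversity(big, pop_b, "P", [f"s{i}" for i in range(8)]).pi
        assert 0.5 < pi_big < pi_small  # both above 2p(1-p), approaching it

    def test_sites_below_sample_floor_excluded(self):
        pop = PopAssignment({f"s{i}": "P" for i in range(10)}, min_per_pop=10)
        dosages = [[1] * 10, [1] * 5 + [-1] * 5]  # second site has only 5 genotyped
        out = nucleotide_diversity(dosages, pop, "P", [f"s{i}" for i in range(10)])
        assert out.n_sites == 1


class TestDri:
    @pytest.mark.parametrize(
        "pi_a, pi_d, expected", [(0.012, 0.010, 1.2), (0.01, 0.01, 1.0),
                                 (0.010, 0.012, 0.8333)]
    )
    def test_ratio(self, pi_a, pi_d, expected):
        assert dri(pi_a, pi_d) == pytest.approx(expected, abs=1e-4)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            dri(0.01, 0.0)

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reciprocal_product_is_one(self, x, y):
        assert dri(x, y) * dri(y, x) == pytest.approx(1.0)


def _two_pop(n_a, n_b):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    assignment = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return samples, PopAssignment(assignment, min_per_pop=min(n_a, n_b))


class TestPairwiseFst:
    def test_fixed_difference_is_one(self):
        samples, pop = _two_pop(10, 10)
        dosages = [[0] * 10 + [2] * 10]
        assert pairwise_fst(dosages, pop, "A", "B", samples) == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        samples, pop = _two_pop(30, 30)
        dosages = []
        for _ in range(500):
            p = rng.uniform(0.2, 0.8)
            dosages.append(rng.binomial(2, p, size=60).tolist())
        assert abs(pairwise_fst(dosages, pop, "A", "B", samples)) < 0.02

    def test_monomorphic_input_is_an_error(self):
        samples, pop = _two_pop(10, 10)
        with pytest.raises(ValueError):
            pairwise_fst([[0] * 20], pop, "A", "B", samples)

    @pytest.mark.parametrize("target", [0.1, 0.3])
    def test_balding_nichols_recovery(self, target):
        cfg = SimulationConfig(
            seed=303, populations=(("A", 50), ("B", 50)), target_fst=target,
            inbreeding_f=0.0, n_sites=1000,
        )
        sites, samples, pops, _t = simulate_genotypes(cfg)
        pop = PopAssignment(pops, min_per_pop=10)
        est = pairwise_fst([s.dosages() for s in sites], pop, "A", "B", samples)
        assert est == pytest.approx(target, abs=0.03)

    def test_sites_below_floor_excluded(self):
        samples, pop = _two_pop(10, 10)
        informative = [0] * 3 + [1] * 7 + [2] * 6 + [1] * 4
        sparse = [0, 2] + [-1] * 18  # only one genotyped individual per pop
        with_sparse = pairwise_fst([informative, sparse], pop, "A", "B", samples)
        alone = pairwise_fst([informative], pop, "A", "B", samples)
        assert with_sparse == alone


class TestFstScan:
    def test_order_statistic_threshold(self):
        values = {f"z{i}": float(i) for i in range(1, 21)}
        thresholds, outliers = fst_scan({"c1": values})
        assert thresholds["c1"] == pytest.approx(19.05)
        assert outliers["c1"] == ["z20"]

    def test_constant_values_give_no_outliers(self):
        thresholds, outliers = fst_scan({"c1": {f"z{i}": 0.2 for i in range(10)}})
        assert outliers["c1"] == []

    def test_at_most_five_percent_flagged(self, rng):
        for n in (20, 57, 100):
            values = {f"z{i}": float(v) for i, v in enumerate(rng.random(n))}
            _thr, outliers = fst_scan({"c1": values})
            assert len(outliers["c1"]) <= math.ceil(0.05 * n)

    def test_undefined_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than two"):
            thresholds, _ = fst_scan({"bad": {"z1": math.nan, "z2": math.nan}})
        assert "bad" not in thresholds


class TestMeanDepthPerZone:
    def test_zone_means_against_bruteforce(self, rng):
        zones = [Zone("c1", 0, 4), Zone("c1", 10, 20)]
        depths = {
            "s1": {"c1": [2, 2, 4, 4] + [0] * 6 + [1] * 10},
            "s2": {"c1": [0] * 20},
        }
        table = mean_depth_per_zone_per_sample(depths, zones)
        assert table.loc["c1_0_4", "s1"] == 3.0
        assert table.loc["c1_10_20", "s1"] == 1.0
        assert (table["s2"] == 0.0).all()
        # brute force cross-check on random data
        rand = {"r": {"c1": rng.integers(0, 30, size=20).tolist()}}
        t2 = mean_depth_per_zone_per_sample(rand, zones)
        for zone in zones:
            expected = sum(rand["r"]["c1"][zone.start:zone.end]) / len(zone)
            assert t2.loc[zone.name, "r"] == pytest.approx(expected)

    def test_zone_outside_depth_range(self):
        with pytest.raises(ValueError):
            mean_depth_per_zone_per_sample(
                {"s": {"c1": [1, 1]}}, [Zone("c1", 0, 5)]
            )
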