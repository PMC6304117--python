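"""Instance generation, enumeration, normalization and serialization."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amoebatsp.instances import (
    EnumerationCapError,
    ExperimentMapConfig,
    InstanceParseError,
    InvalidTourError,
    NormalizationError,
    Tour,
    TSPInstance,
    affine_normalize,
    default_labels,
    enumerate_tour_lengths,
    enumerate_tours,
    generate_experiment_instance,
    generate_simulation_instance,
    is_unimodal,
    percentile_rank,
    read_instance,
    tour_distribution_stats,
    tour_length,
    write_instance,
)
from conftest import brute_force_tour_lengths, make_instance


class TestTourLength:
    def test_all_equal_distances(self):
        d = np.full((5, 5), 100.0)
        np.fill_diagonal(d, 0)
        inst = make_instance(d)
        assert tour_length(inst, Tour(tuple("ABCDE"))) == pytest.approx(500.0)

    def test_three_city_hand_sum(self):
        inst = make_instance([[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        assert tour_length(inst, Tour(("A", "B", "C"))) == pytest.approx(6.0)

    def test_generated_optimum_matches_enumeration(self, exp6):
        # the generator pins the unique shortest tour at length 100
        lengths = brute_force_tour_lengths(exp6)
        assert min(lengths) == pytest.approx(100.0, rel=1e-9)
        best_pkg = min(enumerate_tours(exp6), key=lambda tl: tl[1])
        assert best_pkg[1] == pytest.approx(min(lengths), rel=1e-12)

    @pytest.mark.parametrize("bad", [("A", "B"), ("A", "B", "X", "D"), ("A", "B", "C", "C")])
    def test_invalid_tours_rejected(self, ladder4, bad):
        with pytest.raises(InvalidTourError):
            if len(set(bad)) == len(bad) and len(bad) >= 3:
                tour_length(ladder4, Tour(bad))
            else:
                tour_length(ladder4, bad)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 12), (8, 2520)])
    def test_tour_counts(self, n, count):
        d = np.abs(np.random.default_rng(n).normal(100, 20, (n, n))) + 1
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        inst = make_instance(d)
        assert len(enumerate_tours(inst)) == count == math.factorial(n - 1) // 2

    def test_cap_refused(self):
        d = np.full((11, 11), 5.0)
        np.fill_diagonal(d, 0)
        with pytest.raises(EnumerationCapError, match="cap"):
            enumerate_tour_lengths(make_instance(d))

    def test_lengths_match_bruteforce_oracle(self, exp6):
        ours = sorted(enumerate_tour_lengths(exp6))
        oracle = sorted(brute_force_tour_lengths(exp6))
        assert np.allclose(ours, oracle, rtol=1e-12)

    def test_no_duplicates_under_rotation_reflection(self, exp6):
        seen = set()
        for tour, _ in enumerate_tours(exp6):
            assert tour.is_canonical
            cls = frozenset(
                tuple(np.roll(tour.order, r)) for r in range(tour.n)
            ) | frozenset(tuple(np.roll(tour.order[::-1], r)) for r in range(tour.n))
            assert cls not in seen
            seen.add(cls)

    def test_canonical_constant_on_equivalence_class(self):
        order = tuple("DAFCBE")
        base = Tour(order).canonical()
        for r in range(len(order)):
            rot = order[r:] + order[:r]
            assert Tour(rot).canonical() == base
            assert Tour(rot[::-1]).canonical() == base
        assert base.canonical() == base  # idempotent


class TestDistributionStats:
    def test_degenerate_all_equal(self, equi6):
        s = tour_distribution_stats(equi6)
        assert s.count == 60
        assert s.min_len == s.max_len == s.mean_len == pytest.approx(600.0)
        assert not s.min_unique and not s.max_unique

    def test_shaped_map_stats(self, exp6):
        s = tour_distribution_stats(exp6)
        assert s.min_len == pytest.approx(100.0, rel=1e-9)
        assert s.max_len == pytest.approx(200.0, rel=1e-9)
        assert 148.0 <= s.mean_len <= 152.0
        assert s.min_unique and s.max_unique

    @pytest.mark.parametrize("n", [5, 6])
    def test_mean_equals_n_times_mean_distance(self, n):
        # every edge appears in the same number of tours, so the mean tour
        # length is exactly n times the mean off-diagonal distance
        rng = np.random.default_rng(7 + n)
        d = rng.uniform(5, 50, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        inst = make_instance(d)
        s = tour_distribution_stats(inst)
        assert s.mean_len == pytest.approx(n * inst.off_diagonal().mean(), rel=1e-12)

    def test_unimodality_detector(self):
        assert is_unimodal([1, 3, 7, 4, 2])
        assert is_unimodal([1, 2, 2, 3, 1])  # plateau merged
        assert is_unimodal([1, 2, 3])  # monotone counts as unimodal
        assert not is_unimodal([3, 1, 4])
        assert not is_unimodal([1, 0, 2, 5, 3])


class TestAffineNormalize:
    def test_identity_when_already_on_target(self, exp6):
        again = affine_normalize(exp6, 100.0, 200.0)
        assert again.gen_meta["affine"]["a"] == pytest.approx(1.0)
        assert again.gen_meta["affine"]["b"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(again.dist, exp6.dist)

    def test_coefficients_solve_linear_system(self):
        # wide tour-length spread (120..320) so the rescale stays positive
        inst = make_instance(
            [
                [0, 10, 100, 20],
                [10, 0, 30, 150],
                [100, 30, 0, 60],
                [20, 150, 60, 0],
            ]
        )
        s = tour_distribution_stats(inst)
        out = affine_normalize(inst, 100.0, 200.0)
        a = out.gen_meta["affine"]["a"]
        b = out.gen_meta["affine"]["b"]
        # hand-solved 2x2 system: a*min + n*b = 100, a*max + n*b = 200
        assert a == pytest.approx(100.0 / (s.max_len - s.min_len))
        assert b == pytest.approx((100.0 - a * s.min_len) / 4)
        s2 = tour_distribution_stats(out)
        assert s2.min_len == pytest.approx(100.0, rel=1e-6)
        assert s2.max_len == pytest.approx(200.0, rel=1e-6)

    def test_hand_arithmetic_min50_max90(self):
        # with enumerated extremes (50, 90) and n=4 the solution is
        # a = 100/40 = 2.5, b = (100 - 2.5*50)/4 = -6.25
        a = (200.0 - 100.0) / (90.0 - 50.0)
        assert a == 2.5
        assert (100.0 - a * 50.0) / 4 == -6.25

    def test_degenerate_rejected(self, equi6):
        with pytest.raises(NormalizationError):
            affine_normalize(equi6, 100.0, 200.0)


class TestExperimentGenerator:
    def test_deterministic(self):
        one = generate_experiment_instance(6, seed=1)
        two = generate_experiment_instance(6, seed=1)
        assert np.array_equal(one.dist, two.dist)
        other = generate_experiment_instance(6, seed=2)
        assert not np.array_equal(one.dist, other.dist)

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_accepted_maps_hit_design_targets(self, n):
        inst = generate_experiment_instance(n, seed=11)
        lengths = np.array(brute_force_tour_lengths(inst))
        assert np.isclose(lengths, 100.0, rtol=1e-9).sum() == 1
        assert np.isclose(lengths, 200.0, rtol=1e-9).sum() == 1
        assert abs(lengths.mean() - 150.0) <= 2.0
        off = inst.dist[~np.eye(n, dtype=bool)]
        assert np.all(off > 0)

    def test_mode_and_meta(self):
        inst = generate_experiment_instance(5, seed=3)
        assert inst.mode == "experiment"
        assert inst.gen_meta["seed"] == 3
        assert {"a", "b"} <= set(inst.gen_meta["affine"])
        assert inst.gen_meta["rejections"] >= 0

    def test_impossible_band_exhausts_budget(self):
        from amoebatsp.instances import GenerationError

        cfg = ExperimentMapConfig(mean_tol=1e-9, max_attempts=50)
        with pytest.raises(GenerationError):
            generate_experiment_instance(6, seed=0, config=cfg)


class TestSimulationGenerator:
    def test_truncation_and_size(self):
        inst = generate_simulation_instance(20, seed=7)
        off = inst.off_diagonal()
        assert off.size == 190
        assert np.all(off >= 10.0)

    def test_sample_mean_near_100(self):
        for seed in range(5):
            inst = generate_simulation_instance(12, seed=seed)
            assert abs(inst.off_diagonal().mean() - 100.0) <= 2.0

    def test_mean_tour_length_identity_at_small_n(self):
        inst = generate_simulation_instance(5, seed=9)
        s = tour_distribution_stats(inst)
        assert s.mean_len == pytest.approx(5 * inst.off_diagonal().mean(), rel=1e-12)

    def test_deterministic(self):
        a = generate_simulation_instance(10, seed=4)
        b = generate_simulation_instance(10, seed=4)
        assert np.array_equal(a.dist, b.dist)


class TestPercentileRank:
    def test_four_city_score_row(self):
        # third tour length recovered from the mean: 3*153.3 - 100 - 200
        lengths = [100.0, 3 * 153.3 - 300.0, 200.0]
        assert percentile_rank(lengths, 142.0) == pytest.approx(100.0 / 3)

    def test_extremes(self):
        lengths = [10.0, 20.0, 30.0, 40.0]
        assert percentile_rank(lengths, 40.0) == 100.0
        assert percentile_rank(lengths, 10.0) == 25.0
        assert percentile_rank(lengths, 5.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank([], 1.0)

    @given(st.floats(min_value=0, max_value=300))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_L(self, L):
        lengths = [100.0, 120.0, 150.0, 180.0, 200.0]
        assert percentile_rank(lengths, L) <= percentile_rank(lengths, L + 10.0)


class TestSerialization:
    def test_round_trip(self, exp6, tmp_path):
        p = tmp_path / "map.tsp"
        write_instance(exp6, p)
        back = read_instance(p)
        assert back.n == exp6.n
        assert back.labels == exp6.labels
        assert np.array_equal(back.dist, exp6.dist)
        assert back.mode == "experiment"
        assert back.gen_meta["seed"] == exp6.gen_meta["seed"]

    def test_asymmetric_matrix_rejected(self, tmp_path):
        p = tmp_path / "bad.tsp"
        p.write_text(
            "TYPE: TSP\nDIMENSION: 3\nEDGE_WEIGHT_TYPE: EXPLICIT\n"
            "EDGE_WEIGHT_FORMAT: FULL_MATRIX\nEDGE_WEIGHT_SECTION\n"
            "0 1 2\n9 0 3\n2 3 0\nEOF\n"
        )
        with pytest.raises(InstanceParseError, match=r"\(1,2\)|\(2,1\)"):
            read_instance(p)

    def test_hand_written_ladder(self, tmp_path):
        p = tmp_path / "ladder.tsp"
        p.write_text(
            "NAME: ladder\nTYPE: TSP\nDIMENSION: 4\n"
            "EDGE_WEIGHT_TYPE: EXPLICIT\nEDGE_WEIGHT_FORMAT: FULL_MATRIX\n"
            "EDGE_WEIGHT_SECTION\n"
            "0 10 20 30\n10 0 40 50\n20 40 0 60\n30 50 60 0\nEOF\n"
        )
        inst = read_instance(p)
        assert inst.mode == "external"
        assert tour_length(inst, Tour(tuple("ABCD"))) == pytest.approx(140.0)

    def test_negative_distance_named(self, tmp_path):
        p = tmp_path / "neg.tsp"
        p.write_text(
            "TYPE: TSP\nDIMENSION: 3\nEDGE_WEIGHT_TYPE: EXPLICIT\n"
            "EDGE_WEIGHT_FORMAT: FULL_MATRIX\nEDGE_WEIGHT_SECTION\n"
            "0 -1 2\n-1 0 3\n2 3 0\nEOF\n"
        )
        with pytest.raises(InstanceParseError, match="non-positive"):
            read_instance(p)


def test_default_labels_extend_past_alphabet():
    labels = default_labels(28)
    assert labels[:3] == ("A", "B", "C")
    assert labels[25:28] == ("Z", "AA", "AB")
    assert len(set(labels)) == 28


def test_instance_validation_rejects_asymmetry():
    with pytest.raises(ValueError, match="asymmetric"):
        TSPInstance(
            n=3,
            labels=("A", "B", "C"),
            dist=np.array([[0, 1, 2], [9, 0, 3], [2, 3, 0]], dtype=float),
        )
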