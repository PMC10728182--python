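"""Retrieval curves, the jump-set optimizer, and MVT invariants."""

import numpy as np
import pytest

from semforage import foraging
from semforage.coding import Cluster
from semforage.foraging import (
    RetrievalCurve,
    average_retrieval_curve,
    cluster_step_function,
    mean_leave_time,
    mean_switch_time,
    optimal_leave_time,
)
from tests.conftest import build_dataset


def make_cluster(offsets, switch=None, pid="p1", trial=1):
    return Cluster(pid, trial, 1, len(offsets), list(map(float, offsets)), switch)


def grid_argmax(curve: RetrievalCurve, S: float, step: float = 1.0):
    """Independent brute-force oracle: evaluate the rate on a dense grid."""
    ts = np.arange(0.0, curve.t_max_ms + step, step)
    rates = curve(ts) / (S + ts)
    i = int(np.argmax(rates))
    return float(ts[i]), float(rates[i])


def random_curve(rng):
    """A random integer-jump step curve (non-decreasing, g(0) >= 1)."""
    n_jumps = rng.integers(1, 15)
    jumps = np.concatenate(
        ([0.0], np.sort(rng.choice(np.arange(1, 20001), n_jumps, replace=False)).astype(float))
    )
    values = 1.0 + np.cumsum(rng.uniform(0.0, 1.0, len(jumps)))
    return RetrievalCurve(jumps, values, n_clusters=1, t_max_ms=float(jumps[-1]))


class TestClusterStepFunction:
    def test_offsets_map_to_counts(self):
        times, counts = cluster_step_function(make_cluster([0, 1000, 2500]))
        assert times.tolist() == [0.0, 1000.0, 2500.0]
        assert counts.tolist() == [1.0, 2.0, 3.0]

    def test_singleton_is_constant_one(self):
        times, counts = cluster_step_function(make_cluster([0]))
        assert times.tolist() == [0.0] and counts.tolist() == [1.0]

    def test_step_function_is_non_decreasing_from_coded_data(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("giraffe", 5000), ("dog", 6000), ("fox", 1500),
                        ("wolf", 2500)])],
            small_lexicon,
        )
        clusters = foraging.dataset_clusters(ds)
        c = clusters[-1]  # dog..wolf cluster entered from giraffe
        times, counts = cluster_step_function(c)
        assert np.all(np.diff(counts) > 0) and times[0] == 0.0
        assert c.switch_time_ms == 6000.0 and c.leave_time_ms == 4000.0


class TestAverageRetrievalCurve:
    def test_two_cluster_hand_average(self):
        curve = average_retrieval_curve(
            [make_cluster([0, 1000, 3000]), make_cluster([0, 2000])]
        )
        assert curve.jump_times_ms.tolist() == [0.0, 1000.0, 2000.0, 3000.0]
        assert curve.values.tolist() == [1.0, 1.5, 2.0, 2.5]

    def test_n_identical_clusters_average_to_one(self):
        clusters = [make_cluster([0, 800, 2000]) for _ in range(7)]
        curve = average_retrieval_curve(clusters)
        assert curve.values.tolist() == [1.0, 2.0, 3.0]

    def test_average_of_averages_equals_pooled_for_equal_counts(self):
        rng = np.random.default_rng(3)
        groups = [
            [make_cluster(np.concatenate(([0.0], np.sort(rng.uniform(1, 9000, rng.integers(1, 5))))))
             for _ in range(4)]
            for _ in range(3)
        ]
        pooled = average_retrieval_curve([c for g in groups for c in g])
        ts = np.linspace(0, pooled.t_max_ms, 50)
        per_group = [average_retrieval_curve(g, t_max=pooled.t_max_ms) for g in groups]
        mean_of_means = np.mean([g(ts) for g in per_group], axis=0)
        assert np.allclose(mean_of_means, pooled(ts))

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            average_retrieval_curve([])

    def test_hold_curve_is_non_decreasing_with_g0_at_least_one(self):
        rng = np.random.default_rng(9)
        clusters = [
            make_cluster(np.concatenate(([0.0], np.sort(rng.uniform(1, 8000, rng.integers(0, 6))))))
            for _ in range(30)
        ]
        curve = average_retrieval_curve(clusters)
        assert curve.values[0] >= 1.0
        assert np.all(np.diff(curve.values) >= 0)

    def test_truncate_policy_conditions_on_active_clusters(self):
        # two clusters: [0,1000,3000] and [0,2000]; at t=2500 only the first is
        # active (leave 3000 >= 2500) holding 2 items
        curve = average_retrieval_curve(
            [make_cluster([0, 1000, 3000]), make_cluster([0, 2000])],
            hold_policy="truncate",
        )
        assert curve(2500.0) == 2.0
        # at t=1500 both active: counts 2 and 1 -> mean 1.5
        assert curve(1500.0) == 1.5


class TestMeans:
    def test_mean_switch_time(self):
        clusters = [make_cluster([0], None), make_cluster([0], 2000.0),
                    make_cluster([0], 4000.0)]
        assert mean_switch_time(clusters) == 3000.0

    def test_mean_leave_time(self):
        clusters = [make_cluster([0, 3000]), make_cluster([0, 2000])]
        assert mean_leave_time(clusters) == 2500.0

    def test_no_defined_switch_times_is_an_error(self):
        with pytest.raises(ValueError, match="switch"):
            mean_switch_time([make_cluster([0, 1000], None)])


class TestOptimalLeaveTime:
    def test_hand_computed_example(self):
        curve = RetrievalCurve(
            np.array([0.0, 1000.0, 2000.0, 3000.0]),
            np.array([1.0, 1.5, 2.0, 2.5]),
            n_clusters=2, t_max_ms=3000.0,
        )
        t_star, rate = optimal_leave_time(curve, S=3000.0)
        assert t_star == 3000.0
        assert rate == pytest.approx(2.5 / 6000.0)

    def test_flat_curve_leaves_immediately(self):
        curve = RetrievalCurve(np.array([0.0]), np.array([1.0]), 1, 5000.0)
        t_star, rate = optimal_leave_time(curve, S=4000.0)
        assert t_star == 0.0 and rate == pytest.approx(1 / 4000.0)

    def test_jump_set_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            curve = random_curve(rng)
            S = float(rng.integers(500, 12000))
            t_star, rate = optimal_leave_time(curve, S)
            t_grid, rate_grid = grid_argmax(curve, S)
            assert t_star == t_grid
            assert rate == pytest.approx(rate_grid, rel=1e-12)

    def test_earliest_maximizer_wins_ties(self):
        # two jumps with identical rates: g proportional to (S + t)
        S = 1000.0
        curve = RetrievalCurve(np.array([0.0, 1000.0]), np.array([1.0, 2.0]),
                               1, 1000.0)
        t_star, _ = optimal_leave_time(curve, S)
        assert t_star == 0.0

    def test_nonpositive_switch_time_rejected(self):
        curve = RetrievalCurve(np.array([0.0]), np.array([1.0]), 1, 0.0)
        with pytest.raises(ValueError):
            optimal_leave_time(curve, 0.0)


class TestMVTAnalysis:
    def test_max_rate_is_the_tangent_slope(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("fox", 1200), ("whale", 5000),
                        ("fish", 2000), ("lion", 6000), ("zebra", 1800)])],
            small_lexicon,
        )
        res = foraging.mvt_analysis(ds, scope="group")[0]
        clusters = foraging.dataset_clusters(ds)
        curve = average_retrieval_curve(clusters)
        g_at_tstar = float(curve(res.optimal_leave_ms))
        slope = g_at_tstar / (res.switch_time_mean_ms + res.optimal_leave_ms)
        assert res.max_rate_per_ms == pytest.approx(slope)

    def test_scale_invariance_of_all_quantities(self, small_lexicon):
        items = [("dog", 800), ("fox", 1200), ("whale", 5000), ("fish", 2000),
                 ("lion", 6000), ("zebra", 1800)]
        base = foraging.mvt_analysis(
            build_dataset([("p1", 1, items)], small_lexicon), scope="group")[0]
        for c in (0.5, 2.0, 10.0):
            scaled_items = [(i, rt * c) for i, rt in items]
            scaled = foraging.mvt_analysis(
                build_dataset([("p1", 1, scaled_items)], small_lexicon),
                scope="group")[0]
            assert scaled.switch_time_mean_ms == pytest.approx(c * base.switch_time_mean_ms, rel=1e-12)
            assert scaled.empirical_leave_mean_ms == pytest.approx(c * base.empirical_leave_mean_ms, rel=1e-12)
            assert scaled.optimal_leave_ms == pytest.approx(c * base.optimal_leave_ms, rel=1e-12)
            assert scaled.relative_deviance == pytest.approx(base.relative_deviance, abs=1e-12)

    def test_participant_scope_partitions_clusters(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("whale", 5000), ("fish", 2000)]),
             ("p2", 1, [("lion", 900), ("zebra", 700), ("dog", 4000)])],
            small_lexicon,
        )
        results = {r.label: r for r in foraging.mvt_analysis(ds, scope="participant")}
        assert set(results) == {"p1", "p2"}
        assert results["p1"].n_clusters == 2 and results["p2"].n_clusters == 2

    def test_trial_scope_pools_within_trial(self, small_lexicon):
        ds = build_dataset(
            [("p1", 1, [("dog", 800), ("whale", 5000), ("fish", 2000)]),
             ("p2", 1, [("lion", 900), ("zebra", 700), ("dog", 4000)]),
             ("p1", 2, [("cat", 850), ("giraffe", 4000), ("lion", 1500)])],
            small_lexicon,
        )
        results = {r.label: r for r in foraging.mvt_analysis(ds, scope="trial")}
        assert set(results) == {"1", "2"}
        assert results["1"].n_clusters == 4 and results["2"].n_clusters == 2
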