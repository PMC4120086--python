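"""LTT curves, the median-distance statistic, and the Monte-Carlo test."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wgdwave import (
    DataError,
    LTTCurve,
    ParameterError,
    SimulationConfig,
    clustering_p_value,
    ltt_from_tree,
    median_distance,
    sample_null,
    simulate_event_set,
)
from wgdwave.clustering import sample_ages_from_ltt


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestLTT:
    def test_two_tip_tree(self):
        ltt = ltt_from_tree(_tree("(A:80,B:80);"), window=(0, 100), dt=1.0)
        assert np.all(ltt.counts[ltt.times < 80] == 2)
        assert np.all(ltt.counts[ltt.times > 80] == 1)

    def test_balanced_four_tip_tree(self):
        # root at 90, both cherries at 30
        ltt = ltt_from_tree(
            _tree("((A:30,B:30):60,(C:30,D:30):60);"), window=(0, 100), dt=1.0
        )
        assert np.all(ltt.counts[ltt.times > 90] == 1)
        mid = (ltt.times > 30) & (ltt.times < 90)
        assert np.all(ltt.counts[mid] == 2)
        assert np.all(ltt.counts[ltt.times < 30] == 4)

    def test_adding_a_tip_never_decreases_counts(self):
        base = ltt_from_tree(
            _tree("((A:30,B:30):60,(C:30,D:30):60);"), window=(0, 100), dt=1.0
        )
        more = ltt_from_tree(
            _tree("((A:30,(B:10,E:10):20):60,(C:30,D:30):60);"),
            window=(0, 100),
            dt=1.0,
        )
        assert np.all(more.counts >= base.counts)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(DataError):
            ltt_from_tree(_tree("(A:80,B:50);"))


class TestMedianDistance:
    def test_pairwise_example(self):
        # all 10 pairwise differences of {10, 20, 60, 61, 62}, enumerated by
        # hand: 10, 50, 51, 52, 40, 41, 42, 1, 2, 1 -> median 40.5
        assert median_distance([10, 20, 60, 61, 62]) == pytest.approx(40.5)

    @pytest.mark.parametrize("kind", ["median_pairwise", "median_nearest_neighbor"])
    def test_degenerate_sets(self, kind):
        assert median_distance([5.0, 5.0, 5.0], kind=kind) == 0.0
        assert median_distance([0.0, 100.0], kind=kind) == 100.0

    def test_too_few_ages(self):
        with pytest.raises(ParameterError):
            median_distance([1.0])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=100), min_size=2, max_size=7),
        st.sampled_from(["median_pairwise", "median_nearest_neighbor"]),
    )
    def test_matches_brute_force_enumeration(self, ages, kind):
        ages = [float(a) for a in ages]
        if kind == "median_pairwise":
            diffs = [abs(a - b) for a, b in itertools.combinations(ages, 2)]
        else:
            diffs = [
                min(abs(a - b) for j, b in enumerate(ages) if j != i)
                for i, a in enumerate(ages)
            ]
        assert median_distance(ages, kind=kind) == pytest.approx(np.median(diffs))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=3,
            max_size=10,
        ),
        st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
        st.integers(min_value=0, max_value=9),
    )
    def test_statistic_is_continuous_in_each_age(self, ages, delta, index):
        # Shifting one event age by delta moves the statistic by at most
        # |delta|: no discontinuities that could flip the test abruptly.
        index = index % len(ages)
        shifted = list(ages)
        shifted[index] += delta
        before = median_distance(ages)
        after = median_distance(shifted)
        assert abs(after - before) <= abs(delta) + 1e-9


class TestNullSampling:
    def test_flat_ltt_gives_uniform_ages(self, flat_ltt):
        rng = np.random.default_rng(0)
        ages = sample_ages_from_ltt(flat_ltt, 100_000, rng)
        assert ages.mean() == pytest.approx(50.0, abs=0.4)

    def test_zero_count_cells_excluded_from_support(self):
        dt = 1.0
        mids = np.arange(0, 100, dt) + dt / 2
        counts = np.where(mids < 50, 0.0, 1.0)
        ltt = LTTCurve(times=mids, counts=counts, dt=dt)
        rng = np.random.default_rng(1)
        ages = sample_ages_from_ltt(ltt, 50_000, rng)
        assert ages.min() >= 50.0

    def test_same_seed_identical_stream(self, flat_ltt):
        a = np.concatenate(list(sample_null(flat_ltt, 10, n_samples=5000, seed=3)))
        b = np.concatenate(list(sample_null(flat_ltt, 10, n_samples=5000, seed=3)))
        assert np.array_equal(a, b)
        assert a.size == 5000

    def test_p_value_equals_manual_fraction_on_tiny_run(self, flat_ltt):
        events = [30.0, 32.0, 35.0, 70.0]
        stats_stream = np.concatenate(
            list(sample_null(flat_ltt, 4, n_samples=10, seed=11))
        )
        observed = median_distance(events)
        manual = float(np.count_nonzero(stats_stream <= observed)) / 10.0
        res = clustering_p_value(events, flat_ltt, n_samples=10, seed=11)
        assert res.p_value == pytest.approx(manual)

    def test_pseudo_count_variant(self, flat_ltt):
        res = clustering_p_value(
            [60.0] * 10, flat_ltt, n_samples=1000, seed=0, pseudo_count=True
        )
        # maximal clustering: no null sample can be below 0
        assert res.observed_stat == 0.0
        assert res.p_value == pytest.approx(1.0 / 1001.0)


class TestCalibrationAndPower:
    def test_null_p_values_are_uniform(self, flat_ltt):
        # Events drawn from the null itself: p is uniform on (0, 1).
        cfg = SimulationConfig(clustered_fraction=0.0, n_events=20)
        p_values = []
        for rep in range(200):
            events = simulate_event_set(flat_ltt, cfg, seed=1000 + rep)
            res = clustering_p_value(
                events, flat_ltt, n_samples=2000, seed=rep, chunk_size=2000
            )
            p_values.append(res.p_value)
        ks = stats.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01

    def test_power_exceeds_size_for_planted_wave(self, flat_ltt):
        # Half of the events cluster at 66 +/- 5 mya: the test must reject
        # far more often than its nominal size.
        cfg = SimulationConfig(
            clustered_fraction=0.5, cluster_center=66.0, cluster_sd=5.0, n_events=20
        )
        rejections = 0
        reps = 100
        for rep in range(reps):
            events = simulate_event_set(flat_ltt, cfg, seed=2000 + rep)
            res = clustering_p_value(
                events,
                flat_ltt,
                n_samples=1000,
                seed=rep,
                kind="median_nearest_neighbor",
                chunk_size=1000,
            )
            rejections += res.p_value <= 0.05
        # One-sided binomial test against the nominal size of 5%.
        test = stats.binomtest(rejections, reps, 0.05, alternative="greater")
        assert test.pvalue < 0.01
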