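"""Generator contracts: Yule trees, age samples, Ks tables, event sets."""

import numpy as np
import pytest
from scipy import integrate, stats

from wgdwave import (
    LTTCurve,
    ParameterError,
    SimulationConfig,
    kde_mode,
    ltt_from_tree,
    simulate_event_set,
    simulate_homeolog_ages,
    simulate_ks_table,
    simulate_species_tree,
)


def _lineages_after_root(tree, t: float) -> int:
    """Independent count of lineages alive t my after the root split."""
    depths = {}
    count = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = 0.0 if parent is None else depths[parent] + node.edge.length
        if parent is None:
            continue
        start, end = depths[parent], depths[node]
        if node.is_leaf():
            end = np.inf  # tips persist to the present
        if start <= t < end:
            count += 1
    return count


class TestSpeciesTree:
    def test_minimal_tree_has_one_internal_node(self):
        tree = simulate_species_tree(0.05, 2, seed=1)
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(internal) == 1
        assert len(tree.leaf_nodes()) == 2

    def test_ltt_non_decreasing_toward_present(self):
        tree = simulate_species_tree(0.1, 50, seed=7)
        height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        ltt = ltt_from_tree(tree, window=(0.0, height * 0.999), dt=height / 500)
        # times increase into the past, so counts must be non-increasing
        assert np.all(np.diff(ltt.counts) <= 0)
        assert ltt.counts[0] == 50

    def test_mean_lineage_growth_matches_yule_expectation(self):
        # E[N(t)] = 2 * exp(rate * t) for a pure-birth process started from
        # the root split, far from the stopping boundary.
        rate, t_probe, reps = 0.1, 23.0, 400
        counts = [
            _lineages_after_root(simulate_species_tree(rate, 200, seed=s), t_probe)
            for s in range(reps)
        ]
        expected = 2.0 * np.exp(rate * t_probe)
        assert np.mean(counts) == pytest.approx(expected, rel=0.10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            simulate_species_tree(0.0, 10, seed=0)
        with pytest.raises(ParameterError):
            simulate_species_tree(0.1, 1, seed=0)

    def test_identical_seed_identical_tree(self):
        a = simulate_species_tree(0.2, 12, seed=5).as_string(schema="newick")
        b = simulate_species_tree(0.2, 12, seed=5).as_string(schema="newick")
        assert a == b


class TestHomeologAges:
    def test_zero_noise_collapses_to_true_age(self):
        cfg = SimulationConfig(anchor_sd=0.0, n_anchor_pairs=50)
        sample = simulate_homeolog_ages(cfg, "anchor", seed=0)
        assert np.all(sample.ages == cfg.true_wgd_age)

    def test_zero_contamination_equals_anchor_distribution(self):
        cfg = SimulationConfig(
            contaminant_fraction=0.0, n_anchor_pairs=500, n_peak_pairs=500
        )
        anchor = simulate_homeolog_ages(cfg, "anchor", seed=11)
        peak = simulate_homeolog_ages(cfg, "peak_based", seed=11)
        assert np.allclose(anchor.ages, peak.ages)

    def test_contaminated_mean_matches_analytic_mixture_mean(self):
        cfg = SimulationConfig(
            contaminant_fraction=0.3,
            contaminant_exponent=2.0,
            n_peak_pairs=10_000,
            anchor_sd=3.0,
        )
        sample = simulate_homeolog_ages(cfg, "peak_based", seed=2)
        # Independent oracle: numeric integration of the mixture mean.
        T, eps, a = cfg.true_wgd_age, cfg.contaminant_epsilon, 2.0
        norm, _ = integrate.quad(lambda x: (x + eps) ** -a, 0, T)
        cont_mean, _ = integrate.quad(lambda x: x * (x + eps) ** -a / norm, 0, T)
        # truncation of the Normal at 0 is negligible for 66 +/- 3
        expected = 0.7 * cfg.true_wgd_age + 0.3 * cont_mean
        se = sample.ages.std() / np.sqrt(sample.n)
        assert abs(sample.ages.mean() - expected) < 4 * se
        assert sample.ages.mean() < cfg.true_wgd_age

    def test_anchor_symmetry_and_peak_young_bias(self):
        cfg = SimulationConfig(n_anchor_pairs=10_000, n_peak_pairs=10_000)
        anchor = simulate_homeolog_ages(cfg, "anchor", seed=3)
        se = anchor.ages.std() / np.sqrt(anchor.n)
        assert abs(anchor.ages.mean() - np.median(anchor.ages)) < 3 * se
        peak = simulate_homeolog_ages(cfg, "peak_based", seed=3)
        assert np.median(peak.ages) < cfg.true_wgd_age

    def test_all_ages_non_negative(self):
        cfg = SimulationConfig(true_wgd_age=5.0, anchor_sd=10.0, n_anchor_pairs=2000)
        sample = simulate_homeolog_ages(cfg, "anchor", seed=4)
        assert np.all(sample.ages >= 0)


class TestKsTable:
    def test_no_background_means_all_labeled(self):
        cfg = SimulationConfig(n_ssd_pairs=0, n_anchor_pairs=100)
        table = simulate_ks_table(cfg, seed=0)
        assert (table["segment_id"] != "").all()

    def test_every_segment_has_at_least_three_pairs(self):
        cfg = SimulationConfig(n_anchor_pairs=301)
        table = simulate_ks_table(cfg, seed=9)
        sizes = table[table["segment_id"] != ""].groupby("segment_id").size()
        assert (sizes >= 3).all()
        assert sizes.sum() == 301

    def test_wgd_peak_detectable_as_local_mode(self):
        cfg = SimulationConfig(
            n_ssd_pairs=4000, n_anchor_pairs=4000, decoy_segment_fraction=0.0
        )
        table = simulate_ks_table(cfg, seed=1)
        peak_ks = table.loc[table["origin"] == "wgd", "ks"].to_numpy()
        assert kde_mode(peak_ks, n_grid=2**12) == pytest.approx(0.8, abs=0.1)

    def test_determinism(self):
        cfg = SimulationConfig()
        a = simulate_ks_table(cfg, seed=42)
        b = simulate_ks_table(cfg, seed=42)
        assert a.equals(b)


class TestEventSet:
    def test_pure_null_uniform_mean(self, flat_ltt):
        cfg = SimulationConfig(clustered_fraction=0.0, n_events=100_000)
        ages = simulate_event_set(flat_ltt, cfg, seed=0)
        assert ages.mean() == pytest.approx(50.0, abs=0.4)
        assert ages.min() >= 0 and ages.max() <= 100

    def test_degenerate_cluster(self, flat_ltt):
        cfg = SimulationConfig(clustered_fraction=1.0, cluster_sd=0.0, n_events=10)
        ages = simulate_event_set(flat_ltt, cfg, seed=0)
        assert np.all(ages == cfg.cluster_center)

    def test_ltt_proportional_sampling_chi_square(self):
        # Non-flat target: goodness of fit of 1e5 draws against the
        # discretized density must not be rejected at alpha = 0.01.
        dt = 1.0
        mids = np.arange(0, 100, dt) + dt / 2
        counts = 5.0 + 30.0 * np.exp(-mids / 40.0)
        ltt = LTTCurve(times=mids, counts=counts, dt=dt)
        cfg = SimulationConfig(clustered_fraction=0.0, n_events=100_000)
        ages = simulate_event_set(ltt, cfg, seed=3)
        observed, _ = np.histogram(ages, bins=np.arange(0, 101, dt))
        expected = counts / counts.sum() * ages.size
        stat, p = stats.chisquare(observed, expected)
        assert p > 0.01
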