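"""Homeolog selection: segment medians, windows, rooting, node medians."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from wgdwave import (
    DataError,
    PeakWindow,
    ParameterError,
    SimulationConfig,
    midpoint_root,
    node_median_ks,
    segment_median_ks,
    select_anchor_homeologs,
    select_peak_based_homeologs,
    simulate_ks_table,
    simulate_species_tree,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "ks", "segment_id"])


class TestSegmentMedian:
    @pytest.mark.parametrize(
        "ks_values, expected",
        [([0.5], 0.5), ([0.4, 0.6, 0.8], 0.6), ([0.4, 0.6, 0.7, 0.9], 0.65)],
    )
    def test_median_values(self, ks_values, expected):
        rows = [(f"a{i}", f"b{i}", k, "s1") for i, k in enumerate(ks_values)]
        assert segment_median_ks(_table(rows), "s1") == pytest.approx(expected)

    def test_unknown_segment(self):
        table = _table([("a", "b", 0.5, "s1")])
        with pytest.raises(DataError):
            segment_median_ks(table, "nope")

    def test_saturated_rows_excluded_from_median(self):
        rows = [("a", "b", 0.5, "s1"), ("c", "d", 0.7, "s1"), ("e", "f", 9.0, "s1")]
        assert segment_median_ks(_table(rows), "s1") == pytest.approx(0.6)


class TestAnchorSelection:
    def test_segment_median_rule_is_per_segment(self):
        # Segment median 0.95 outside [0.4, 0.9]: every pair rejected, even
        # one whose own Ks (0.5) is inside the window.
        rows = [
            ("a1", "b1", 0.5, "s1"),
            ("a2", "b2", 1.1, "s1"),
            ("a3", "b3", 0.95, "s1"),
            ("c1", "d1", 0.6, "s2"),
            ("c2", "d2", 1.2, "s2"),
            ("c3", "d3", 0.7, "s2"),
        ]
        hs = select_anchor_homeologs(_table(rows), PeakWindow(0.4, 0.9))
        # s2 median 0.7 in window: all three pairs kept, incl. Ks 1.2
        assert sorted(hs.pairs) == [("c1", "d1"), ("c2", "d2"), ("c3", "d3")]

    def test_empty_window_overlap_returns_empty(self):
        rows = [("a", "b", 0.5, "s1")]
        hs = select_anchor_homeologs(_table(rows), PeakWindow(2.0, 3.0))
        assert len(hs) == 0

    def test_row_order_invariance(self):
        cfg = SimulationConfig(n_anchor_pairs=200, n_ssd_pairs=200)
        table = simulate_ks_table(cfg, seed=5)
        window = PeakWindow(0.55, 1.1)
        base = select_anchor_homeologs(table, window)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert select_anchor_homeologs(shuffled, window).pairs == base.pairs

    def test_unlabeled_table_is_an_error(self):
        rows = [("a", "b", 0.5, "")]
        with pytest.raises(DataError):
            select_anchor_homeologs(_table(rows), PeakWindow(0.4, 0.9))

    def test_planted_wgd_purity_at_least_95_percent(self):
        # When the window brackets the planted peak, almost all accepted
        # anchors must come from the WGD component despite decoy segments.
        cfg = SimulationConfig(n_anchor_pairs=3000, n_ssd_pairs=0)
        table = simulate_ks_table(cfg, seed=17)
        hs = select_anchor_homeologs(table, PeakWindow(0.55, 1.1))
        origin = table.set_index(["gene_a", "gene_b"])["origin"]
        origins = [origin[pair] for pair in hs.pairs]
        purity = np.mean([o == "wgd" for o in origins])
        assert len(hs) > 100
        assert purity >= 0.95


class TestMidpointRooting:
    def test_two_leaf_midpoint(self):
        tree = dendropy.Tree.get(data="(A:1,B:3);", schema="newick")
        rooted = midpoint_root(tree)
        depths = {l.taxon.label: l.distance_from_root() for l in rooted.leaf_node_iter()}
        assert depths == pytest.approx({"A": 2.0, "B": 2.0})

    def test_symmetric_four_leaf_tree_roots_on_central_branch(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:1):2,(C:1,D:1):2);", schema="newick"
        )
        rooted = midpoint_root(tree)
        depths = {l.taxon.label: l.distance_from_root() for l in rooted.leaf_node_iter()}
        assert all(abs(d - 3.0) < 1e-9 for d in depths.values())

    def test_random_trees_match_brute_force_diameter(self):
        rng = np.random.default_rng(0)
        for rep in range(25):
            tree = simulate_species_tree(0.3, int(rng.integers(3, 12)), seed=rep)
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    e.length = float(e.length) * float(rng.uniform(0.2, 2.0)) + 0.01
            rooted = midpoint_root(tree)
            pdm = rooted.phylogenetic_distance_matrix()
            taxa = list(rooted.taxon_namespace)
            diameter = max(
                pdm.distance(a, b) for a, b in itertools.combinations(taxa, 2)
            )
            max_depth = max(
                l.distance_from_root() for l in rooted.leaf_node_iter()
            )
            assert abs(max_depth - diameter / 2.0) < 1e-9

    def test_path_lengths_preserved(self):
        tree = dendropy.Tree.get(
            data="((A:1.0,B:2.0):0.5,(C:0.3,D:4.0):0.9);", schema="newick"
        )
        before = tree.phylogenetic_distance_matrix()
        t_before = {t.label: t for t in tree.taxon_namespace}
        dist_before = {
            (a, b): before.distance(t_before[a], t_before[b])
            for a, b in itertools.combinations(sorted(t_before), 2)
        }
        rooted = midpoint_root(tree)
        after = rooted.phylogenetic_distance_matrix()
        t_after = {t.label: t for t in rooted.taxon_namespace}
        for (a, b), d in dist_before.items():
            assert after.distance(t_after[a], t_after[b]) == pytest.approx(d)


class TestNodeMedian:
    def _cherry(self):
        return dendropy.Tree.get(data="(a:1,b:1);", schema="newick")

    def test_cherry_returns_pair_ks(self):
        tree = self._cherry()
        assert node_median_ks(
            tree, tree.seed_node, {("a", "b"): 0.42}
        ) == pytest.approx(0.42)

    def test_cross_pairs_only(self):
        tree = dendropy.Tree.get(data="(a:2,(b:1,c:1):1);", schema="newick")
        ks = {("a", "b"): 0.5, ("a", "c"): 0.7, ("b", "c"): 0.1}
        # (b, c) is within one child subtree and must not contribute
        assert node_median_ks(tree, tree.seed_node, ks) == pytest.approx(0.6)

    def test_missing_pair_reported(self):
        tree = self._cherry()
        with pytest.raises(DataError, match="'a', 'b'"):
            node_median_ks(tree, tree.seed_node, {})

    def test_leaf_rejected(self):
        tree = self._cherry()
        leaf = tree.leaf_nodes()[0]
        with pytest.raises(ParameterError):
            node_median_ks(tree, leaf, {("a", "b"): 0.1})


class TestPeakBasedSelection:
    def test_single_qualifying_cherry_gives_that_pair(self):
        tree = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
        hs = select_peak_based_homeologs(
            [tree], {("a", "b"): 0.8}, PeakWindow(0.5, 1.0), seed=0
        )
        assert hs.pairs == [("a", "b")]

    def test_determinism(self):
        tree = dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick"
        )
        ks = {
            ("a", "b"): 0.2,
            ("c", "d"): 0.2,
            ("a", "c"): 0.8,
            ("a", "d"): 0.8,
            ("b", "c"): 0.8,
            ("b", "d"): 0.8,
        }
        window = PeakWindow(0.6, 1.0)
        a = select_peak_based_homeologs([tree], ks, window, seed=99)
        b = select_peak_based_homeologs([tree], ks, window, seed=99)
        assert a.pairs == b.pairs

    def test_one_pair_per_qualifying_node(self):
        # Root and both cherries qualify: exactly three representative pairs.
        tree = dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick"
        )
        ks = {
            ("a", "b"): 0.8,
            ("c", "d"): 0.8,
            ("a", "c"): 0.8,
            ("a", "d"): 0.8,
            ("b", "c"): 0.8,
            ("b", "d"): 0.8,
        }
        hs = select_peak_based_homeologs([tree], ks, PeakWindow(0.6, 1.0), seed=1)
        assert len(hs) == 3

    def test_representative_pair_uniformity(self):
        tree = dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick"
        )
        ks = {
            ("a", "b"): 0.2,
            ("c", "d"): 0.2,
            ("a", "c"): 0.8,
            ("a", "d"): 0.8,
            ("b", "c"): 0.8,
            ("b", "d"): 0.8,
        }
        window = PeakWindow(0.6, 1.0)
        counts = {}
        reps = 2000
        for seed in range(reps):
            hs = select_peak_based_homeologs([tree], ks, window, seed=seed)
            assert len(hs.pairs) == 1  # only the root qualifies
            counts[hs.pairs[0]] = counts.get(hs.pairs[0], 0) + 1
        freqs = np.array(list(counts.values())) / reps
        assert len(counts) == 4
        # 4 * sqrt(0.25 * 0.75 / 2000) ~ 0.039: allow ~4 sigma
        assert np.all(np.abs(freqs - 0.25) < 0.04)
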