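"""Homeolog selection from Ks age distributions.

Two selection routes, mirroring how WGD-derived duplicate pairs are
collected in practice:

* **anchor route** — duplicate pairs on collinear (syntenic) duplicated
  segments.  A whole segment is accepted iff the median Ks over its anchor
  pairs falls inside the WGD signature peak window; acceptance is
  per-segment, so every pair of an accepted segment is kept even if its
  individual Ks falls outside the window.

* **peak-based route** — for species without positional information.
  Gene-family trees are midpoint rooted; for every internal node whose
  median Ks over cross-subtree terminal pairs falls in the peak window,
  one representative pair of descendant genes is drawn uniformly at random
  (seeded).  One pair per qualifying duplication node avoids counting the
  same duplication several times through nested paralog pairs.

Ks values above a saturation cap (default 5.0) are unreliable and are
excluded from all medians, but rows are flagged rather than dropped.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError, DegenerateInputError, ParameterError

__all__ = [
    "PeakWindow",
    "HomeologSet",
    "DEFAULT_KS_SATURATION_CAP",
    "flag_saturated",
    "segment_median_ks",
    "select_anchor_homeologs",
    "midpoint_root",
    "node_median_ks",
    "select_peak_based_homeologs",
]

DEFAULT_KS_SATURATION_CAP = 5.0


@dataclasses.dataclass(frozen=True)
class PeakWindow:
    """Ks interval [ks_low, ks_high] bracketing a WGD signature peak."""

    ks_low: float
    ks_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.ks_low < self.ks_high:
            raise ParameterError(
                f"invalid peak window [{self.ks_low}, {self.ks_high}]"
            )

    def contains(self, ks: float) -> bool:
        return self.ks_low <= ks <= self.ks_high


@dataclasses.dataclass
class HomeologSet:
    """Selected homeolog pairs of one species from one selection route."""

    species: str
    source: str
    pairs: list[tuple[str, str]]
    provenance: list[str]

    def __post_init__(self) -> None:
        if self.source not in ("anchor", "peak_based"):
            raise ParameterError(f"unknown source {self.source!r}")
        if len(self.pairs) != len(self.provenance):
            raise ParameterError("pairs and provenance differ in length")
        seen = set()
        for a, b in self.pairs:
            key = tuple(sorted((a, b)))
            if key in seen:
                raise ParameterError(f"duplicate homeolog pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)


def _validate_ks_table(table: pd.DataFrame) -> None:
    for col in ("gene_a", "gene_b", "ks"):
        if col not in table.columns:
            raise DataError(f"Ks table lacks required column {col!r}")
    if (table["ks"] < 0).any():
        raise DataError("Ks values must be non-negative")
    if (table["gene_a"] == table["gene_b"]).any():
        raise DataError("self-pairs (gene_a == gene_b) are not allowed")


def flag_saturated(
    table: pd.DataFrame, cap: float = DEFAULT_KS_SATURATION_CAP
) -> pd.DataFrame:
    """Return a copy with a boolean ``saturated`` column (ks > cap)."""
    _validate_ks_table(table)
    out = table.copy()
    out["saturated"] = out["ks"] > cap
    return out


def _segment_groups(table: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    if "segment_id" not in table.columns:
        raise DataError("Ks table has no segment_id column")
    labeled = table[
        table["segment_id"].notna() & (table["segment_id"].astype(str) != "")
    ]
    if labeled.empty:
        raise DataError("Ks table has no labeled segments")
    return labeled.groupby("segment_id", sort=True)


def segment_median_ks(
    table: pd.DataFrame,
    segment_id: str,
    cap: float = DEFAULT_KS_SATURATION_CAP,
) -> float:
    """Median Ks over all anchor pairs of one duplicated segment.

    Saturated pairs (ks > cap) are excluded from the median; for an even
    number of pairs the midpoint of the two central values is returned.
    """
    _validate_ks_table(table)
    groups = _segment_groups(table)
    try:
        seg = groups.get_group(segment_id)
    except KeyError as exc:
        raise DataError(f"unknown segment {segment_id!r}") from exc
    ks = seg.loc[seg["ks"] <= cap, "ks"].to_numpy(dtype=float)
    if ks.size == 0:
        raise DataError(
            f"segment {segment_id!r} has no unsaturated Ks values"
        )
    return float(np.median(ks))


def select_anchor_homeologs(
    table: pd.DataFrame,
    window: PeakWindow,
    species: str = "unknown",
    cap: float = DEFAULT_KS_SATURATION_CAP,
) -> HomeologSet:
    """Accept whole segments whose median Ks lies inside the peak window.

    The result is invariant to the row order of the input table: segments
    are processed in sorted order and pairs in each accepted segment keep
    a deterministic (sorted) order.
    """
    _validate_ks_table(table)
    groups = _segment_groups(table)
    pairs: list[tuple[str, str]] = []
    provenance: list[str] = []
    for segment_id, seg in groups:
        ks = seg.loc[seg["ks"] <= cap, "ks"].to_numpy(dtype=float)
        if ks.size == 0:
            continue
        if window.contains(float(np.median(ks))):
            seg_pairs = sorted(
                (str(a), str(b))
                for a, b in zip(seg["gene_a"], seg["gene_b"])
            )
            pairs.extend(seg_pairs)
            provenance.extend([str(segment_id)] * len(seg_pairs))
    return HomeologSet(
        species=species, source="anchor", pairs=pairs, provenance=provenance
    )


# ---------------------------------------------------------------------------
# Gene-family trees: midpoint rooting and node medians
# ---------------------------------------------------------------------------


def _leaf_distances(tree: dendropy.Tree) -> tuple[list, dict, dict]:
    """All leaves, their root distances, and pairwise path lengths."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    labels = [leaf.taxon.label for leaf in leaves]
    if len(labels) != len(set(labels)):
        raise DataError("gene-family tree has duplicate leaf names")
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[node] = 0.0
        else:
            length = node.edge.length
            if length is None:
                raise DataError("gene-family tree has a branch without length")
            if length < 0:
                raise DataError("branch lengths must be non-negative")
            depths[node] = depths[parent] + float(length)
    return leaves, depths, {}


def _path_to_root(node: dendropy.Node) -> list[dendropy.Node]:
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def _path_between(a: dendropy.Node, b: dendropy.Node) -> list[dendropy.Node]:
    """Node path from leaf a to leaf b through their MRCA."""
    up_a = _path_to_root(a)
    up_b = _path_to_root(b)
    ancestors_a = {id(n): i for i, n in enumerate(up_a)}
    for j, n in enumerate(up_b):
        if id(n) in ancestors_a:
            i = ancestors_a[id(n)]
            return up_a[: i + 1] + list(reversed(up_b[:j]))
    raise DataError("leaves do not share an ancestor")  # pragma: no cover


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a gene-family tree at the midpoint of its longest leaf path.

    The diameter path is found by brute force over all leaf pairs; ties are
    broken toward the lexicographically smallest (leaf, leaf) label pair so
    rooting is platform independent.  Total leaf-to-leaf path lengths are
    preserved.  The input tree is not modified.
    """
    tree = tree.clone(depth=1)
    leaves, depths, _ = _leaf_distances(tree)
    if len(leaves) < 2:
        raise DegenerateInputError("midpoint rooting needs at least 2 leaves")

    best: tuple[float, str, str, dendropy.Node, dendropy.Node] | None = None
    for i, la in enumerate(leaves):
        for lb in leaves[i + 1 :]:
            path = _path_between(la, lb)
            top = min(path, key=lambda n: depths[n])
            dist = depths[la] + depths[lb] - 2 * depths[top]
            key = (-dist, la.taxon.label, lb.taxon.label)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (dist, la.taxon.label, lb.taxon.label, la, lb)
    diameter, _, _, leaf_a, leaf_b = best
    if diameter <= 0:
        raise DegenerateInputError("tree has zero total length")

    target = diameter / 2.0
    path = _path_between(leaf_a, leaf_b)
    walked = 0.0
    for prev, nxt in zip(path, path[1:]):
        if nxt.parent_node is prev:
            edge = nxt.edge
            child_end = nxt
            step = float(edge.length)
            # Walking root-ward start of edge is prev (closer to leaf_a).
            dist_at_child = walked + step
        else:
            edge = prev.edge
            child_end = prev
            step = float(edge.length)
            dist_at_child = walked
        if walked + step >= target - 1e-12:
            # Midpoint lies on this edge; split it so that the piece on the
            # child side has length |target position - child end|.
            along_from_start = target - walked
            if nxt.parent_node is prev:
                length_child_side = step - along_from_start
            else:
                length_child_side = along_from_start
            length_child_side = min(max(length_child_side, 0.0), step)
            tree.reroot_at_edge(
                edge,
                length1=step - length_child_side,
                length2=length_child_side,
                update_bipartitions=False,
            )
            tree.seed_node.edge.length = 0.0
            _recenter_root(tree, leaf_a.taxon.label, leaf_b.taxon.label)
            return tree
        walked += step
    raise DataError("midpoint not located on diameter path")  # pragma: no cover


def _recenter_root(tree: dendropy.Tree, label_a: str, label_b: str) -> None:
    """Slide the root along its two child edges so both diameter endpoints
    sit at equal depth (library rerooting conventions and suppressed
    degree-2 nodes can leave the split slightly on the wrong side)."""
    root = tree.seed_node
    children = root.child_nodes()
    if len(children) != 2:
        return
    depths: dict[dendropy.Node, float] = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depths[node] = depths[node.parent_node] + float(node.edge.length or 0.0)
    by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    da = depths[by_label[label_a]]
    db = depths[by_label[label_b]]
    delta = (da - db) / 2.0
    if abs(delta) < 1e-12:
        return
    # Move the root toward the deeper endpoint's side by delta.
    side_a = next(c for c in children if _subtends(c, by_label[label_a]))
    side_b = next(c for c in children if c is not side_a)
    if side_a.edge.length - delta < -1e-9 or side_b.edge.length + delta < -1e-9:
        raise DataError("cannot recenter midpoint root on the split edge")
    side_a.edge.length = max(side_a.edge.length - delta, 0.0)
    side_b.edge.length = max(side_b.edge.length + delta, 0.0)


def _subtends(node: dendropy.Node, target: dendropy.Node) -> bool:
    current = target
    while current is not None:
        if current is node:
            return True
        current = current.parent_node
    return False


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def node_median_ks(
    tree: dendropy.Tree,
    node: dendropy.Node,
    pair_ks: Mapping[tuple[str, str], float],
    cap: float = DEFAULT_KS_SATURATION_CAP,
) -> float:
    """Median Ks over terminal pairs spanning the children of a node.

    Only pairs with one terminal in each child subtree are used: pairs
    within a single child subtree measure younger duplications and would
    bias the node's age.  A missing Ks value raises a ``DataError`` naming
    the offending pair.
    """
    if node.is_leaf():
        raise ParameterError("node_median_ks requires an internal node")
    child_leaf_sets = [
        sorted(leaf.taxon.label for leaf in child.leaf_iter())
        for child in node.child_nodes()
    ]
    values = []
    for i, left in enumerate(child_leaf_sets):
        for right in child_leaf_sets[i + 1 :]:
            for a in left:
                for b in right:
                    key = _pair_key(a, b)
                    if key not in pair_ks:
                        raise DataError(f"missing Ks value for pair {key}")
                    values.append(float(pair_ks[key]))
    usable = [v for v in values if v <= cap]
    if not usable:
        raise DataError("all cross-subtree pairs of the node are saturated")
    return float(np.median(usable))


def _cross_pairs(node: dendropy.Node) -> list[tuple[str, str]]:
    child_leaf_sets = [
        sorted(leaf.taxon.label for leaf in child.leaf_iter())
        for child in node.child_nodes()
    ]
    pairs = []
    for i, left in enumerate(child_leaf_sets):
        for right in child_leaf_sets[i + 1 :]:
            for a in left:
                for b in right:
                    pairs.append(_pair_key(a, b))
    return sorted(set(pairs))


def select_peak_based_homeologs(
    trees: Sequence[dendropy.Tree],
    pair_ks: Mapping[tuple[str, str], float],
    window: PeakWindow,
    seed: int | None = None,
    species: str = "unknown",
    cap: float = DEFAULT_KS_SATURATION_CAP,
) -> HomeologSet:
    """One representative pair per duplication node inside the peak window.

    Every tree is midpoint rooted first.  For each internal node whose
    cross-subtree median Ks lies in the window, one cross-subtree terminal
    pair is chosen uniformly at random; the candidate list is sorted
    lexicographically before the seeded draw, so identical inputs and seed
    give identical selections on any platform.  Families with no
    qualifying node contribute nothing.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    provenance: list[str] = []
    chosen: set[tuple[str, str]] = set()
    for t_index, tree in enumerate(trees):
        rooted = midpoint_root(tree)
        for n_index, node in enumerate(rooted.preorder_internal_node_iter()):
            try:
                median = node_median_ks(rooted, node, pair_ks, cap=cap)
            except DataError:
                raise
            if not window.contains(median):
                continue
            candidates = _cross_pairs(node)
            pick = candidates[int(rng.integers(0, len(candidates)))]
            if pick in chosen:
                # The same gene pair can span two nested qualifying nodes
                # only in pathological trees; re-draw deterministically by
                # scanning candidates in order.
                alternatives = [c for c in candidates if c not in chosen]
                if not alternatives:
                    continue
                pick = alternatives[0]
            chosen.add(pick)
            pairs.append(pick)
            provenance.append(f"tree{t_index}:node{n_index}")
    return HomeologSet(
        species=species, source="peak_based", pairs=pairs, provenance=provenance
    )
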