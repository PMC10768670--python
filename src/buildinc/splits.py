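"""Rooted-split semantics: extraction from trees, display, and conflict.

A rooted split ``sigma1 |* sigma2`` asserts that the taxa in the include
group ``sigma1`` (the "cluster") share a common ancestor that is not an
ancestor of any taxon in the exclude group ``sigma2``; the root lies on the
exclude side.  Every internal branch of a rooted tree induces one such
split: the leaves below the branch against the remaining leaves of that
tree.  Because input trees usually cover only part of the full taxon set,
``sigma1 ∪ sigma2`` is in general a proper subset of the universe.

Taxon labels are interned to dense non-negative integer ids once per
problem (:class:`TaxonIndex`); all split sets are sets of ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Iterator, List, Optional, Tuple

import dendropy

__all__ = [
    "TaxonIndex",
    "RootedSplit",
    "ClusterIndex",
    "leaf_labels",
    "splits_of_tree",
    "displays",
    "conflicts_with_tree",
]


class TaxonIndex:
    """Bijective mapping between tip labels and dense integer ids.

    The mapping is fixed at problem load: the first time a label is seen it
    receives the next free id, and ids are stable for the lifetime of a
    run.
    """

    def __init__(self) -> None:
        self._id_of: dict = {}
        self._labels: List[str] = []

    def intern(self, label: str) -> int:
        i = self._id_of.get(label)
        if i is None:
            i = len(self._labels)
            self._id_of[label] = i
            self._labels.append(label)
        return i

    def id_of(self, label: str) -> int:
        return self._id_of[label]

    def label_of(self, taxon_id: int) -> str:
        return self._labels[taxon_id]

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: str) -> bool:
        return label in self._id_of

    def ids(self) -> range:
        return range(len(self._labels))

    @classmethod
    def from_trees(cls, trees: Iterable[dendropy.Tree]) -> "TaxonIndex":
        """Intern every tip label across *trees*, in first-appearance order."""
        index = cls()
        for tree in trees:
            for label in leaf_labels(tree):
                index.intern(label)
        return index


def leaf_labels(tree: dendropy.Tree) -> Iterator[str]:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise ValueError("tree contains an unlabeled leaf")
        yield leaf.taxon.label


@dataclass(frozen=True)
class RootedSplit:
    """An include group against an exclude group, root on the exclude side.

    Invariants: the groups are disjoint, ``|include| >= 2`` and
    ``|exclude| >= 1``.  ``provenance`` optionally records
    ``(source_tree_index, source_edge_index)``.
    """

    include: FrozenSet[int]
    exclude: FrozenSet[int]
    provenance: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.include) < 2:
            raise ValueError("rooted split needs at least two include taxa")
        if len(self.exclude) < 1:
            raise ValueError("rooted split needs a non-empty exclude group")
        if self.include & self.exclude:
            raise ValueError("include and exclude groups overlap")

    def restricted(self, universe: FrozenSet[int]) -> Optional["RootedSplit"]:
        """Restriction to *universe*, or None if it degenerates to a trivial
        split (fewer than two include taxa, or an empty exclude group)."""
        inc = self.include & universe
        exc = self.exclude & universe
        if len(inc) < 2 or not exc:
            return None
        return RootedSplit(inc, exc, self.provenance)

    def key(self) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
        return (tuple(sorted(self.include)), tuple(sorted(self.exclude)))

    def __repr__(self) -> str:  # compact, e.g. {0,1}|*{2}
        inc = ",".join(map(str, sorted(self.include)))
        exc = ",".join(map(str, sorted(self.exclude)))
        return "{%s}|*{%s}" % (inc, exc)


class ClusterIndex:
    """Precomputed leaf clusters of a rooted tree, for display/conflict tests.

    Holds one frozenset of taxon ids per node, the tree's full leaf id set,
    and supports the MRCA descent used by the conflict predicate.  All sets
    use the tree's *own* leaf universe; restriction to a sub-universe is by
    set intersection on the caller's side.
    """

    def __init__(self, tree: dendropy.Tree, index: TaxonIndex) -> None:
        self.tree = tree
        self.index = index
        self._cluster: dict = {}
        seen = set()
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon is not None else None
                if label is None:
                    raise ValueError("tree contains an unlabeled leaf")
                if label in seen:
                    raise ValueError("duplicate tip label %r in tree" % label)
                seen.add(label)
                cl = frozenset((index.intern(label),))
            else:
                cl = frozenset().union(*(self._cluster[c] for c in node.child_nodes()))
            self._cluster[node] = cl
        self.leaf_ids: FrozenSet[int] = self._cluster[tree.seed_node]

    def cluster(self, node) -> FrozenSet[int]:
        return self._cluster[node]

    def clusters(self) -> Iterator[FrozenSet[int]]:
        return iter(self._cluster.values())

    def mrca(self, taxa: FrozenSet[int]):
        """Deepest node whose cluster contains *taxa* (taxa must be leaves)."""
        node = self.tree.seed_node
        while True:
            for child in node.child_nodes():
                if taxa <= self._cluster[child]:
                    node = child
                    break
            else:
                return node

    def child_clusters(self, node) -> List[FrozenSet[int]]:
        return [self._cluster[c] for c in node.child_nodes()]


def splits_of_tree(
    tree: dendropy.Tree,
    index: TaxonIndex,
    tree_index: Optional[int] = None,
    cindex: Optional[ClusterIndex] = None,
) -> List[RootedSplit]:
    """One rooted split per internal edge, in preorder over edges.

    An internal edge is one whose child node is neither a leaf nor the
    root.  Splits that would violate the rooted-split invariants (include
    group smaller than two, or empty exclude group) are omitted.
    """
    ci = cindex if cindex is not None else ClusterIndex(tree, index)
    universe = ci.leaf_ids
    out: List[RootedSplit] = []
    edge_i = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        include = ci.cluster(node)
        exclude = universe - include
        if len(include) >= 2 and exclude:
            prov = (tree_index, edge_i) if tree_index is not None else None
            out.append(RootedSplit(include, exclude, prov))
        edge_i += 1
    return out


def displays(
    tree: dendropy.Tree,
    split: RootedSplit,
    index: TaxonIndex,
    cindex: Optional[ClusterIndex] = None,
) -> bool:
    """True iff some node's cluster contains the include group and avoids
    the exclude group.  The split's taxa must lie within the tree."""
    ci = cindex if cindex is not None else ClusterIndex(tree, index)
    if not (split.include | split.exclude) <= ci.leaf_ids:
        raise ValueError("split mentions taxa outside the tree's leaf set")
    for cl in ci.clusters():
        if split.include <= cl and not (cl & split.exclude):
            return True
    return False


def conflicts_with_tree(
    split: RootedSplit,
    tree: dendropy.Tree,
    index: TaxonIndex,
    cindex: Optional[ClusterIndex] = None,
) -> bool:
    """True iff the split, restricted to the tree's leaves, cannot be
    displayed by any refinement of the tree.

    The split is first restricted to the tree's leaf set; if the restricted
    include group has fewer than two taxa or the restricted exclude group
    is empty there is nothing to conflict with.  Otherwise let v be the
    MRCA of the restricted include group: the split conflicts iff some
    child cluster of v intersects both the restricted include and the
    restricted exclude group (such a cluster can be neither kept together
    under the split's branch nor excluded from it, under any refinement).
    """
    ci = cindex if cindex is not None else ClusterIndex(tree, index)
    inc = split.include & ci.leaf_ids
    exc = split.exclude & ci.leaf_ids
    if len(inc) < 2 or not exc:
        return False
    v = ci.mrca(inc)
    for cl in ci.child_clusters(v):
        if (cl & inc) and (cl & exc):
            return True
    return False
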