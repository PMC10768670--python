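"""Shared test utilities: tiny parsers and independent brute-force oracles.

The enumeration oracle decides split compatibility by enumerating every
rooted binary tree on the taxon set ((2n-3)!! trees) and asking whether
any of them displays all splits; it shares no code with the solver.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import FrozenSet, Iterator, List, Sequence, Set, Tuple

import dendropy

from buildinc.splits import RootedSplit, TaxonIndex


def tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick if newick.endswith(";") else newick + ";",
        schema="newick",
        rooting="force-rooted",
        preserve_underscores=True,
    )


def index_of(*labels: str) -> TaxonIndex:
    ix = TaxonIndex()
    for lab in labels:
        ix.intern(lab)
    return ix


def split(ix: TaxonIndex, spec: str, provenance=None) -> RootedSplit:
    """Split from a compact 'A B | C D' spec using interned labels."""
    inc, exc = spec.split("|")
    return RootedSplit(
        frozenset(ix.intern(x) for x in inc.split()),
        frozenset(ix.intern(x) for x in exc.split()),
        provenance,
    )


# ---------------------------------------------------------------------------
# Enumeration oracle over all rooted binary trees.
# ---------------------------------------------------------------------------


def _enum_cluster_sets(taxa: FrozenSet[int]) -> Iterator[FrozenSet[FrozenSet[int]]]:
    """Cluster sets (including leaves and root) of every rooted binary tree."""
    if len(taxa) == 1:
        yield frozenset((taxa,))
        return
    anchor = min(taxa)
    rest = sorted(taxa - {anchor})
    for r in range(len(rest)):
        for left_rest in itertools.combinations(rest, r):
            left = frozenset(left_rest) | {anchor}
            right = taxa - left
            for cl in _enum_cluster_sets(left):
                for cr in _enum_cluster_sets(right):
                    yield cl | cr | {taxa}


@lru_cache(maxsize=8)
def all_binary_cluster_sets(n: int) -> Tuple[FrozenSet[FrozenSet[int]], ...]:
    return tuple(_enum_cluster_sets(frozenset(range(n))))


def set_displays(clusters: FrozenSet[FrozenSet[int]], sp: RootedSplit) -> bool:
    return any(sp.include <= c and not (c & sp.exclude) for c in clusters)


def compatible_bruteforce(n: int, splits: Sequence[RootedSplit]) -> bool:
    """True iff some rooted binary tree on n taxa displays every split."""
    return any(
        all(set_displays(clusters, sp) for sp in splits)
        for clusters in all_binary_cluster_sets(n)
    )


def cluster_set_of_tree(t: dendropy.Tree, ix: TaxonIndex) -> Set[FrozenSet[int]]:
    from buildinc.splits import ClusterIndex

    return set(ClusterIndex(t, ix).clusters())
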