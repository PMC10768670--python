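"""Synthetic subproblem generation: model tree, noisy inputs, taxonomy.

A replicate draws a pure-birth (Yule) model tree, derives each
phylogenetic input by subsampling tips (each kept independently with the
tip-inclusion probability; redrawn while fewer than two survive) and then
applying a fixed number of edge-contract-refine (ECR) moves to mimic
estimation noise, and finally emits a taxonomy: the full-leaf model tree
with the same number of ECR moves followed by independent collapsing of
internal edges, mimicking the unresolved character of real taxonomies.
The taxonomy is complete (never subsampled) and is emitted last.

An ECR move contracts one uniformly chosen internal edge and re-refines
the resulting polytomy by moving a uniformly chosen proper subset (size at
least two, and different from the contracted node's former children — the
move must actually change the topology) of its children under a new child
node.  On a binary tree this swaps exactly one cluster for a conflicting
one, so each move leaves one input-tree split in conflict with the model
and one model split in conflict with the input: at two moves per input the
symmetric conflicting-split count is about four.

A single seeded random stream is consumed in a fixed order (model tree,
inputs in order, taxonomy), so a replicate is byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional

import dendropy

from .splits import ClusterIndex, TaxonIndex, conflicts_with_tree, splits_of_tree

__all__ = [
    "SimParams",
    "simulate_yule",
    "subsample_tree",
    "ecr_move",
    "collapse_edges",
    "generate_subproblem",
    "conflicting_split_count",
]


@dataclass
class SimParams:
    """Simulation protocol parameters.

    Defaults are the study conditions used throughout: 20 inputs, tip
    inclusion probability 0.5, two ECR moves per tree, taxonomy edge
    collapse probability 0.75.
    """

    n_leaves: int
    n_trees: int = 20
    tip_prob: float = 0.5
    n_ecr: int = 2
    collapse_prob: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("need at least three leaves")
        if not 0 < self.tip_prob <= 1:
            raise ValueError("tip_prob must be in (0, 1]")
        if not 0 <= self.collapse_prob <= 1:
            raise ValueError("collapse_prob must be in [0, 1]")
        if self.n_trees < 1 or self.n_ecr < 0:
            raise ValueError("n_trees must be >= 1 and n_ecr >= 0")


def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )


def _copy(tree: dendropy.Tree) -> dendropy.Tree:
    return _parse(tree.as_string(schema="newick", suppress_rooting=True))


def simulate_yule(n: int, rng: random.Random) -> dendropy.Tree:
    """Yule topology on *n* leaves labelled t1..tn.

    Going backward in time, two uniformly chosen lineages join at each
    step; branch lengths are irrelevant to split compatibility and are
    omitted.
    """
    if n < 2:
        raise ValueError("need at least two leaves")
    lineages = ["t%d" % (i + 1) for i in range(n)]
    while len(lineages) > 1:
        i, j = rng.sample(range(len(lineages)), 2)
        if i > j:
            i, j = j, i
        joined = "(%s,%s)" % (lineages[i], lineages[j])
        lineages[i] = joined
        del lineages[j]
    return _parse(lineages[0] + ";")


def subsample_tree(tree: dendropy.Tree, p: float, rng: random.Random) -> dendropy.Tree:
    """Keep each tip independently with probability *p*; restrict the tree
    to the kept tips with degree-two nodes suppressed.  Fresh coin flips
    are drawn until at least two tips survive (a 0- or 1-tip tree carries
    no splits and would be unusable)."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    while True:
        kept = [lab for lab in labels if rng.random() < p]
        if len(kept) >= 2:
            break
    if len(kept) == len(labels):
        return _copy(tree)
    sub = tree.extract_tree_with_taxa_labels(labels=kept)
    sub.is_rooted = True
    return sub


def _internal_edge_heads(tree: dendropy.Tree) -> List:
    """Nodes that head an internal edge (internal, non-root child)."""
    return [
        nd
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node and not nd.is_leaf()
    ]


def _contract(node) -> None:
    parent = node.parent_node
    for child in list(node.child_nodes()):
        node.remove_child(child)
        parent.add_child(child)
    parent.remove_child(node)


def ecr_move(tree: dendropy.Tree, rng: random.Random) -> dendropy.Tree:
    """One edge-contract-refine move; returns a modified copy.

    A uniformly chosen internal edge is contracted, then a proper subset
    (size >= 2, not equal to the contracted node's former children) of the
    polytomous node's children, chosen uniformly among such subsets, is
    regrouped under a new child node.  The leaf set is unchanged.  A tree
    with no internal edge is returned unchanged.
    """
    tree = _copy(tree)
    heads = _internal_edge_heads(tree)
    if not heads:
        return tree
    victim = heads[rng.randrange(len(heads))]
    parent = victim.parent_node
    former = set(victim.child_nodes())
    _contract(victim)
    children = list(parent.child_nodes())
    k = len(children)
    assert k >= 3
    while True:
        subset = [ch for ch in children if rng.random() < 0.5]
        if 2 <= len(subset) <= k - 1 and set(subset) != former:
            break
    group = parent.new_child()
    for ch in subset:
        parent.remove_child(ch)
        group.add_child(ch)
    return tree


def collapse_edges(tree: dendropy.Tree, p: float, rng: random.Random) -> dendropy.Tree:
    """Contract each internal edge independently with probability *p*;
    returns a modified copy.  Leaves are untouched."""
    tree = _copy(tree)
    for node in _internal_edge_heads(tree):
        if rng.random() < p:
            _contract(node)
    return tree


def generate_subproblem(params: SimParams) -> List[dendropy.Tree]:
    """One replicate: the noisy inputs followed by the collapsed taxonomy.

    Fully reproducible from ``params.seed``; the model tree itself is not
    returned (use :func:`simulate_yule` with the same first stream draw to
    recover it, or :func:`generate_subproblem_with_model`).
    """
    return generate_subproblem_with_model(params)[0]


def generate_subproblem_with_model(params: SimParams):
    """As :func:`generate_subproblem`, also returning the model tree."""
    rng = random.Random(params.seed)
    model = simulate_yule(params.n_leaves, rng)
    out: List[dendropy.Tree] = []
    for _ in range(params.n_trees):
        t = subsample_tree(model, params.tip_prob, rng)
        for _ in range(params.n_ecr):
            t = ecr_move(t, rng)
        out.append(t)
    taxonomy = _copy(model)
    for _ in range(params.n_ecr):
        taxonomy = ecr_move(taxonomy, rng)
    taxonomy = collapse_edges(taxonomy, params.collapse_prob, rng)
    out.append(taxonomy)
    return out, model


def conflicting_split_count(
    tree: dendropy.Tree,
    reference: dendropy.Tree,
    index: Optional[TaxonIndex] = None,
) -> int:
    """Symmetric conflicting-split count between a tree and a reference.

    The reference is first restricted to the tree's leaf set (so that each
    disagreement is counted once, not once per reference edge collapsing
    onto it); the count is then the tree's splits that conflict with the
    restricted reference plus the restricted reference's splits that
    conflict with the tree.  For an input derived from the reference by
    subsampling and ECR moves, each move contributes one conflict on each
    side.
    """
    if index is None:
        index = TaxonIndex.from_trees([reference, tree])
    tree_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref_leaves = {leaf.taxon.label for leaf in reference.leaf_node_iter()}
    if tree_leaves != ref_leaves:
        reference = reference.extract_tree_with_taxa_labels(labels=tree_leaves)
        reference.is_rooted = True
    ci_tree = ClusterIndex(tree, index)
    ci_ref = ClusterIndex(reference, index)
    n = 0
    for sp in splits_of_tree(tree, index, cindex=ci_tree):
        if conflicts_with_tree(sp, reference, index, cindex=ci_ref):
            n += 1
    for sp in splits_of_tree(reference, index, cindex=ci_ref):
        if conflicts_with_tree(sp, tree, index, cindex=ci_tree):
            n += 1
    return n
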