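"""Greedy supertree synthesis over an ordered list of input trees.

The synthesis walks the input trees in the order given (the comprehensive
taxonomy tree last), extracts each tree's rooted splits in preorder, and
accepts a split iff it is jointly compatible with all previously accepted
splits.  Compatibility checks can run from scratch (plain BUILD) or
incrementally, with or without rollback; splits can be attempted one at a
time or batch-added with recursive bisection back-off; and an oracle can
pre-screen a tree's splits against the current synthesis tree so that
batches are unlikely to contain doomed splits.  All configurations accept
the same splits in the same order — only the number of compatibility
checks (and the work per check) differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import dendropy

from . import build_core
from .build_core import WORK, BuildOutcome, Solution, build, solution_to_tree
from .build_inc import buildinc
from .splits import ClusterIndex, RootedSplit, TaxonIndex, conflicts_with_tree, splits_of_tree

__all__ = ["SolverOptions", "SupertreeResult", "solve_supertree", "batch_add", "oracle_partition"]


@dataclass
class SolverOptions:
    """Which optimizations the solver uses.

    ``rollback`` requires ``incremental``.  ``oracle_skip`` drops
    oracle-flagged splits instead of attempting them individually; the
    default attempts them (at their original position), which keeps the
    accepted sequence provably identical to the oracle-free run.
    ``seed`` is reserved for callers; the solver itself is deterministic.
    """

    incremental: bool = True
    rollback: bool = True
    batch: bool = True
    oracle: bool = True
    oracle_skip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rollback and not self.incremental:
            raise ValueError("rollback requires the incremental solver")
        if self.oracle_skip and not self.oracle:
            raise ValueError("oracle_skip requires the oracle")


@dataclass
class SupertreeResult:
    tree: dendropy.Tree
    index: TaxonIndex
    accepted: List[RootedSplit]
    rejected: List[RootedSplit]
    decisions: List[Tuple[RootedSplit, bool, int]]  # (split, accepted, cumulative build calls)
    splits_considered: int
    splits_dropped: int
    build_calls: int
    merge_taxon_ops: int
    merge_ops: int


class _GreedyState:
    """Current accepted set plus the solution it came from."""

    def __init__(self, universe, options: SolverOptions):
        self.universe = frozenset(universe)
        self.options = options
        self.accepted: List[RootedSplit] = []
        self.rejected: List[RootedSplit] = []
        self.decisions: List[Tuple[RootedSplit, bool, int]] = []
        self.build_calls = 0
        outcome = build(self.universe, [])
        assert outcome.success
        self.solution: Solution = outcome.solution

    def attempt(self, group: Sequence[RootedSplit]) -> bool:
        """One top-level compatibility check for *group* as a whole."""
        self.build_calls += 1
        if self.options.incremental:
            ok = buildinc(self.solution, group, use_rollback=self.options.rollback)
            if ok:
                self.accepted.extend(group)
            elif not self.options.rollback:
                # the solution was trashed; rebuild it from the accepted set
                outcome = build(self.universe, self.accepted)
                assert outcome.success, "accepted set must stay compatible"
                self.solution = outcome.solution
            return ok
        outcome = build(self.universe, list(self.accepted) + list(group))
        if outcome.success:
            self.solution = outcome.solution
            self.accepted.extend(group)
        return outcome.success

    def add_one(self, sp: RootedSplit) -> bool:
        ok = self.attempt([sp])
        if not ok:
            self.rejected.append(sp)
        self.decisions.append((sp, ok, self.build_calls))
        return ok

    def add_group(self, group: Sequence[RootedSplit]) -> None:
        if self.options.batch:
            batch_add(self, group)
        else:
            for sp in group:
                self.add_one(sp)


def batch_add(state: _GreedyState, group: Sequence[RootedSplit]) -> List[RootedSplit]:
    """Batch-add with recursive bisection back-off.

    Try the whole group in one compatibility check; on failure split into
    the first ceil(n/2) splits and the remainder and recurse; a failing
    singleton is rejected.  The accepted sublist is identical to what
    one-at-a-time addition would accept.
    """
    group = list(group)
    if not group:
        return []
    if len(group) == 1:
        return [group[0]] if state.add_one(group[0]) else []
    if state.attempt(group):
        state.decisions.extend((sp, True, state.build_calls) for sp in group)
        return group
    half = math.ceil(len(group) / 2)
    return batch_add(state, group[:half]) + batch_add(state, group[half:])


def oracle_partition(
    splits: Sequence[RootedSplit],
    current_tree: Optional[dendropy.Tree],
    index: TaxonIndex,
) -> Tuple[List[RootedSplit], List[RootedSplit]]:
    """Partition a tree's splits into (clean, flagged) against the current
    synthesis tree.  With no current tree everything is clean.  Flagged
    splits conflict with the current tree under the MRCA-child test; they
    are overwhelmingly (though not provably) doomed, so keeping them out
    of batches lets large batches succeed."""
    if current_tree is None:
        return list(splits), []
    ci = ClusterIndex(current_tree, index)
    clean: List[RootedSplit] = []
    flagged: List[RootedSplit] = []
    for sp in splits:
        if conflicts_with_tree(sp, current_tree, index, cindex=ci):
            flagged.append(sp)
        else:
            clean.append(sp)
    return clean, flagged


def solve_supertree(
    trees: Sequence[dendropy.Tree],
    options: Optional[SolverOptions] = None,
    index: Optional[TaxonIndex] = None,
) -> SupertreeResult:
    """Synthesize a supertree from an ordered tree list (taxonomy last).

    The taxon universe is the union of all tip labels.  Returns the final
    tree together with the ordered accept/reject log and the counters
    (splits considered, top-level compatibility checks, component-merge
    work).
    """
    if not trees:
        raise ValueError("no input trees")
    options = options if options is not None else SolverOptions()
    if index is None:
        index = TaxonIndex.from_trees(trees)

    work_before = WORK.snapshot()
    state = _GreedyState(range(len(index)), options)
    considered = 0
    dropped = 0

    for ti, tree in enumerate(trees):
        splits = splits_of_tree(tree, index, tree_index=ti)
        if not splits:
            continue
        if options.oracle:
            current = solution_to_tree(state.solution, index)
            clean, flagged = oracle_partition(splits, current, index)
            flagged_ids = {id(sp) for sp in flagged}
            # Walk the tree's splits in their original order, batching
            # maximal runs of clean splits and attempting flagged ones
            # individually in place (or dropping them with oracle_skip).
            run: List[RootedSplit] = []
            for sp in splits:
                if id(sp) in flagged_ids:
                    state.add_group(run)
                    considered += len(run)
                    run = []
                    if options.oracle_skip:
                        dropped += 1
                    else:
                        state.add_one(sp)
                        considered += 1
                else:
                    run.append(sp)
            state.add_group(run)
            considered += len(run)
        else:
            state.add_group(splits)
            considered += len(splits)

    taxon_ops, merges = (a - b for a, b in zip(WORK.snapshot(), work_before))
    return SupertreeResult(
        tree=solution_to_tree(state.solution, index),
        index=index,
        accepted=state.accepted,
        rejected=state.rejected,
        decisions=state.decisions,
        splits_considered=considered,
        splits_dropped=dropped,
        build_calls=state.build_calls,
        merge_taxon_ops=taxon_ops,
        merge_ops=merges,
    )
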