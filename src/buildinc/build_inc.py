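"""Incremental BUILD: add splits to an existing solution, with rollback.

Adding splits to a solved instance can only merge cluster-graph
components, never break them, so an existing solution tree can be updated
in place instead of recomputed.  Components that absorb nothing keep their
child solutions untouched.  Components that absorb an original non-trivial
component retain the subsumed solutions and pass them one level down,
where a subsumed component often re-emerges intact and its old solution is
reused verbatim.  A passed-down solution whose top-level splits become
implied at the receiving level is *punctured*: its splits and children are
dispersed and the stale object dropped.

Because the update mutates the structure in place, a failed addition must
be undone.  Every mutation of a pre-existing level is journaled
(:class:`RollbackInfo`, one entry per level, with one
:class:`MergeRollbackInfo` per component merger) and the journal is
replayed in reverse on failure, restoring the exact previous state.
Levels created during the failing call need no journal (they are simply
discarded): a level is journaled only if its visit counter shows it
predates the call.  Merge records are skipped entirely for levels that had
no components, where clearing the component list is enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .build_core import (
    Component,
    Solution,
    assign_to_components,
    check_failure,
    create_blank_solution,
    merge_components,
    remove_irrelevant_splits,
)
from .splits import RootedSplit

__all__ = [
    "MergeRollbackInfo",
    "RollbackInfo",
    "RollbackJournal",
    "buildinc",
    "buildinc_a",
    "classify_components",
    "rollback_all",
    "rollback_one",
]


#: Allocation counter for merge records; lets tests assert that plain
#: from-scratch builds (and blank levels generally) allocate none.
MERGE_RECORDS_ALLOCATED = 0


@dataclass
class MergeRollbackInfo:
    """Undo record for one component merger.

    ``component2 is None`` marks absorption of a trivial component, in
    which case ``taxon`` is the absorbed taxon.  ``orig_solution`` /
    ``orig_solution2`` are the pre-merge child solutions of the two
    components (restored from here rather than from the components'
    retained-original lists, which a deeper recursion level may already
    have consumed by the time failure strikes).  ``splice_point`` is the
    length of component1's taxon list before the merge; everything past it
    is returned to component2 on undo.
    """

    component1: Component
    component2: Optional[Component]
    taxon: Optional[int]
    orig_solution: Optional[Solution]
    splice_point: int
    orig_solution2: Optional[Solution] = None

    def __post_init__(self) -> None:
        global MERGE_RECORDS_ALLOCATED
        MERGE_RECORDS_ALLOCATED += 1


@dataclass
class RollbackInfo:
    """Undo record for one pre-existing solution level.

    ``orig_components`` is the component list captured after new components
    were added but before empty ones were dropped: its prefix of length
    ``n_orig_components`` is exactly the original list.  Merge records (and
    the snapshot) are kept only when the level had components to begin
    with; otherwise clearing the list outright restores it.
    """

    solution: Solution
    n_orig_implied_splits: int
    n_orig_components: int
    orig_components: Optional[List[Component]] = None
    merges: List[MergeRollbackInfo] = field(default_factory=list)


class RollbackJournal:
    """Ordered mutation journal; replaying it in reverse undoes the call."""

    def __init__(self) -> None:
        self.entries: List[RollbackInfo] = []

    def __len__(self) -> int:
        return len(self.entries)


def buildinc(S: Solution, delta: Sequence[RootedSplit], use_rollback: bool = True) -> bool:
    """Try to add the splits *delta* to the solved instance *S*, in place.

    Returns True and leaves ``S`` incorporating the new splits if they are
    compatible with the splits already present.  On failure with
    ``use_rollback`` the journal is replayed and ``S`` is restored exactly;
    on failure without it ``S`` is left invalid and the caller must rebuild
    from scratch (the journal-free configuration exists to measure what
    rollback buys).
    """
    for sp in delta:
        if not sp.include <= S.tset:
            raise ValueError("split include group %r not within the taxon set" % (sp,))
    journal = RollbackJournal() if use_rollback else None
    ok, top = buildinc_a(S, list(delta), [], journal)
    assert top is S, "the top-level solution is never replaced"
    if not ok and journal is not None:
        rollback_all(journal)
    return ok


def buildinc_a(
    S: Solution,
    delta: List[RootedSplit],
    originals: List[Solution],
    journal: Optional[RollbackJournal],
) -> Tuple[bool, Solution]:
    """One level of the incremental recursion.

    Precondition (checked): if *originals* is non-empty, ``S`` holds no
    splits; every original's taxa lie within ``S``'s and the originals'
    taxon sets are pairwise disjoint.  If an original covers all of ``S``'s
    taxa it replaces ``S`` outright (reuse) and the list is emptied.
    Returns the success flag and the level's final solution object (which
    differs from the argument exactly in the reuse case).
    """
    if not delta and not originals:
        return True, S

    if originals:
        assert not S.implied and not S.components, (
            "a level receiving originals must hold no splits")
        seen: set = set()
        for orig in originals:
            assert orig.tset <= S.tset, "original outside the level's taxon set"
            assert not (orig.tset & seen), "originals overlap"
            seen |= orig.tset
            if len(orig.taxa) == len(S.taxa):
                S = orig
                originals = []
                break

    preexisting = S.visits > 0
    S.visits += 1
    rb: Optional[RollbackInfo] = None
    if journal is not None and preexisting:
        rb = RollbackInfo(S, len(S.implied), len(S.components))
        journal.entries.append(rb)

    remove_irrelevant_splits(S, delta, originals)
    record_merges = rb is not None and rb.n_orig_components > 0
    merge_components(S, delta, originals, record=record_merges, rollback=rb)
    if check_failure(S):
        return False, S
    assign_to_components(S, delta, originals)

    for c in S.components:
        if not c.pending and not c.originals:
            continue  # untouched subtree
        child = c.solution if c.solution is not None else create_blank_solution(c.taxa)
        sub_delta, c.pending = c.pending, []
        sub_orig, c.originals = c.originals, []
        ok, child = buildinc_a(child, sub_delta, sub_orig, journal)
        c.solution = child
        if not ok:
            return False, S
    return True, S


def classify_components(
    before: Sequence[Component], after: Sequence[Component]
) -> Dict[int, str]:
    """Label one level's post-merge components new/unmodified/modified.

    Keyed by ``id(component)``.  *Unmodified*: present before the merge and
    untouched (child solution retained).  *Modified*: absorbed at least one
    original non-trivial component (solution cleared, subsumed solutions
    retained).  *New*: composed entirely of previously-trivial taxa.
    Call between the merge and assignment steps — assignment appends
    passed-down originals, which are not subsumed components.
    """
    labels: Dict[int, str] = {}
    before_ids = {id(c) for c in before}
    for c in after:
        if c.solution is not None:
            assert id(c) in before_ids
            labels[id(c)] = "unmodified"
        elif c.originals:
            labels[id(c)] = "modified"
        else:
            labels[id(c)] = "new"
    return labels


def rollback_all(journal: RollbackJournal) -> None:
    """Undo a failed incremental addition by reverse journal replay."""
    for rb in reversed(journal.entries):
        rollback_one(rb)


def rollback_one(rb: RollbackInfo) -> None:
    S = rb.solution
    del S.implied[rb.n_orig_implied_splits :]
    if rb.n_orig_components == 0:
        S.components = []
        for t in S.taxa:
            S.comp_of[t] = None
        return
    for m in reversed(rb.merges):
        _undo_merge(S, m)
    if rb.orig_components is not None:
        S.components = rb.orig_components[: rb.n_orig_components]
    # Transient per-call fields were empty before the call; deeper levels
    # may have consumed or partially filled them, so clear outright.
    for c in S.components:
        c.pending.clear()
        c.originals.clear()


def _undo_merge(S: Solution, m: MergeRollbackInfo) -> None:
    c1 = m.component1
    if m.component2 is None:
        t = c1.taxa.pop()
        assert t == m.taxon, "rollback out of order"
        S.comp_of[t] = None
        c1.solution = m.orig_solution
    else:
        c2 = m.component2
        returned = c1.taxa[m.splice_point :]
        del c1.taxa[m.splice_point :]
        c2.taxa = returned
        for t in returned:
            S.comp_of[t] = c2
        c1.solution = m.orig_solution
        c2.solution = m.orig_solution2
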