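"""The non-incremental BUILD algorithm over rooted splits.

BUILD decides whether a set of rooted splits is jointly compatible by a
recursive cluster-graph argument: at each level, taxa are partitioned into
the connected components of the graph that links every pair of taxa
co-occurring in some relevant split's include group.  A single component
spanning all taxa signals incompatibility; otherwise each non-trivial
component becomes a subproblem one level down.

The work is stored in a tree of :class:`Solution` objects (one per
recursion level), each holding its taxon set, the splits *implied* at that
level (those whose exclude group no longer intersects the level's taxa —
they are satisfied by the branch leading to the level), its non-trivial
:class:`Component` objects, and a taxon -> component map in which ``None``
marks a trivial (single-taxon) component.  The incremental algorithm in
:mod:`buildinc.build_inc` reuses these level operations and this structure.

Connected components are maintained directly (smaller component spliced
into larger); the edges of the cluster graph are never materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import dendropy

from .splits import RootedSplit, TaxonIndex

__all__ = [
    "Solution",
    "Component",
    "BuildOutcome",
    "WorkCounters",
    "WORK",
    "create_blank_solution",
    "build",
    "remove_irrelevant_splits",
    "merge_components",
    "check_failure",
    "assign_to_components",
    "solution_to_tree",
    "canonical_form",
]


class WorkCounters:
    """Counts the elementary operations of component maintenance.

    ``taxon_ops`` is incremented once per taxon examined or re-mapped while
    connecting include groups; ``merges`` once per component merger or
    trivial absorption.  These counters are the work measure used by the
    scaling diagnostics (wall time is hardware-bound; operation counts are
    not)."""

    __slots__ = ("taxon_ops", "merges")

    def __init__(self) -> None:
        self.reset()

    def reset(self) -> None:
        self.taxon_ops = 0
        self.merges = 0

    def snapshot(self) -> tuple:
        return (self.taxon_ops, self.merges)


#: Global work counters (reset by callers that want a measurement window).
WORK = WorkCounters()


class Component:
    """One non-trivial connected component at a recursion level.

    ``taxa`` is the component's ordered taxon list (merges splice the
    smaller list onto the larger); ``solution`` is the child Solution, or
    None when it has not been computed (or was invalidated by a merge);
    ``pending`` holds splits assigned to this component and not yet pushed
    down; ``originals`` holds retained original Solutions whose taxa lie
    inside this component, to be offered to the child level for reuse.
    """

    __slots__ = ("taxa", "solution", "pending", "originals", "order")

    def __init__(self, order: int = 0) -> None:
        self.taxa: List[int] = []
        self.solution: Optional["Solution"] = None
        self.pending: List[RootedSplit] = []
        self.originals: List["Solution"] = []
        self.order = order

    def __repr__(self) -> str:
        return "<Component %s>" % sorted(self.taxa)


class Solution:
    """State of one recursion level of BUILD.

    Fields mirror the level record: ``taxa`` (ordered, ascending id),
    ``implied`` (append-only list of splits satisfied by the branch leading
    here), ``components`` (non-trivial components only), ``comp_of``
    (taxon -> Component, None = trivial), and ``visits``, a counter of how
    many incremental passes have entered this level (used to decide whether
    the level predates the current top-level call and so needs journaling).
    """

    __slots__ = ("taxa", "tset", "implied", "components", "comp_of", "visits",
                 "_next_order")

    def __init__(self, taxa: Iterable[int]) -> None:
        self.taxa: List[int] = sorted(taxa)
        if not self.taxa:
            raise ValueError("a solution needs at least one taxon")
        self.tset: FrozenSet[int] = frozenset(self.taxa)
        if len(self.tset) != len(self.taxa):
            raise ValueError("duplicate taxa in solution taxon set")
        self.implied: List[RootedSplit] = []
        self.components: List[Component] = []
        self.comp_of: Dict[int, Optional[Component]] = {t: None for t in self.taxa}
        self.visits = 0
        self._next_order = 0

    def new_component(self) -> Component:
        c = Component(order=self._next_order)
        self._next_order += 1
        self.components.append(c)
        return c

    # -- integrity -------------------------------------------------------

    def validate(self, complete: bool = False) -> None:
        """Assert the structural invariants, recursively.

        With ``complete=True`` additionally require that every component
        has a child solution over exactly its taxa and that all transient
        fields (pending splits, retained originals) are empty, i.e. the
        state a finished run must leave behind.
        """
        assert set(self.comp_of) == self.tset
        seen: set = set()
        for c in self.components:
            assert len(c.taxa) >= 2, "stored component must be non-trivial"
            ctset = set(c.taxa)
            assert len(ctset) == len(c.taxa)
            assert not (ctset & seen), "components overlap"
            seen |= ctset
            assert ctset <= self.tset
            for t in c.taxa:
                assert self.comp_of[t] is c
            for orig in c.originals:
                assert orig.tset <= ctset
            for sp in c.pending:
                assert sp.include <= ctset
            if complete:
                assert not c.pending and not c.originals
                assert c.solution is not None
            if c.solution is not None:
                assert c.solution.tset == frozenset(ctset)
                c.solution.validate(complete=complete)
        for t, c in self.comp_of.items():
            assert c is None or c in self.components
        for sp in self.implied:
            assert sp.include <= self.tset
            assert not (sp.exclude & self.tset)

    def all_implied_splits(self) -> List[RootedSplit]:
        """Every split stored in the solution tree (depth-first)."""
        out = list(self.implied)
        for c in self.components:
            if c.solution is not None:
                out.extend(c.solution.all_implied_splits())
        return out


@dataclass
class BuildOutcome:
    success: bool
    solution: Solution


def create_blank_solution(taxa: Iterable[int]) -> Solution:
    """Fresh level state over *taxa*: no splits, every taxon trivial."""
    return Solution(taxa)


# ---------------------------------------------------------------------------
# The per-level operations shared by the plain and incremental recursions.
# ---------------------------------------------------------------------------


def remove_irrelevant_splits(
    S: Solution,
    pending: List[RootedSplit],
    originals: List[Solution],
) -> None:
    """Move splits that are irrelevant at this level into ``S.implied``.

    A split (whose include group is contained in ``S.taxa``) is relevant
    iff its exclude group intersects ``S.taxa``.  Irrelevant pending splits
    move to ``S.implied``.  For each retained original solution, only its
    own top-level implied splits can meet the criterion; if any do, they
    move to ``S.implied`` and the original is *punctured*: it is dropped
    from *originals*, its remaining top-level splits join *pending*, and
    its child solutions join *originals*.  Punctured solutions are never
    mutated — their contents are copied out and the stale object dropped,
    which keeps rollback of a later failure trivial.
    """
    kept = [sp for sp in pending if sp.exclude & S.tset]
    if len(kept) != len(pending):
        S.implied.extend(sp for sp in pending if not (sp.exclude & S.tset))
        pending[:] = kept

    if originals:
        kept_orig: List[Solution] = []
        for orig in originals:
            lifted = [sp for sp in orig.implied if not (sp.exclude & S.tset)]
            if not lifted:
                kept_orig.append(orig)
                continue
            # puncture: disperse the original without mutating it
            S.implied.extend(lifted)
            pending.extend(sp for sp in orig.implied if sp.exclude & S.tset)
            for c in orig.components:
                if c.solution is None:
                    raise AssertionError("punctured solution has an unsolved component")
                kept_orig.append(c.solution)
        originals[:] = kept_orig


def merge_components(
    S: Solution,
    pending: Sequence[RootedSplit],
    originals: Sequence[Solution],
    record: bool = False,
    rollback=None,
) -> list:
    """Refine ``S``'s components to the connected components of the cluster
    graph for (existing components ∪ pending splits ∪ originals).

    Each pending split connects its include group; each original solution
    connects its whole taxon set (its splits connect exactly those taxa, so
    the splits themselves need not be examined).  Mergers splice the
    smaller taxon list into the larger (ties keep the component created
    earlier).  A brand-new component object is created only when all merged
    parts were trivial.  Merge records are returned iff *record* is true;
    if *rollback* (a RollbackInfo) is given, the records and the component
    list snapshot (taken after new components are added but before empty
    ones are dropped) are stored on it as well.
    """
    recs: Optional[list] = [] if record else None
    for sp in pending:
        _connect(S, sp.include, recs)
    for orig in originals:
        _connect(S, orig.taxa, recs)

    if rollback is not None and recs is not None:
        rollback.merges = recs
        rollback.orig_components = list(S.components)

    if any(not c.taxa for c in S.components):
        S.components = [c for c in S.components if c.taxa]
    return recs if recs is not None else []


def _connect(S: Solution, taxa: Iterable[int], recs: Optional[list]) -> None:
    """Place all of *taxa* into one connected component."""
    target: Optional[Component] = None
    lone: Optional[int] = None  # a trivial taxon waiting for a partner
    for t in taxa:
        WORK.taxon_ops += 1
        c = S.comp_of[t]
        if c is None:
            if target is not None:
                _absorb_trivial(S, target, t, recs)
            elif lone is None:
                lone = t
            else:
                target = S.new_component()
                _absorb_trivial(S, target, lone, recs)
                _absorb_trivial(S, target, t, recs)
                lone = None
        else:
            if target is None:
                target = c
            elif c is not target:
                target = _merge_pair(S, target, c, recs)
            if lone is not None:
                _absorb_trivial(S, target, lone, recs)
                lone = None


def _absorb_trivial(S: Solution, c: Component, t: int, recs: Optional[list]) -> None:
    if recs is not None:
        from .build_inc import MergeRollbackInfo

        recs.append(
            MergeRollbackInfo(
                component1=c,
                component2=None,
                taxon=t,
                orig_solution=c.solution,
                splice_point=len(c.taxa),
            )
        )
    if c.solution is not None:
        c.originals.append(c.solution)
        c.solution = None
    c.taxa.append(t)
    S.comp_of[t] = c
    WORK.merges += 1


def _merge_pair(S: Solution, a: Component, b: Component, recs: Optional[list]) -> Component:
    """Merge two non-trivial components; returns the surviving one."""
    if len(b.taxa) > len(a.taxa) or (len(b.taxa) == len(a.taxa) and b.order < a.order):
        a, b = b, a
    c1, c2 = a, b
    if recs is not None:
        from .build_inc import MergeRollbackInfo

        recs.append(
            MergeRollbackInfo(
                component1=c1,
                component2=c2,
                taxon=None,
                orig_solution=c1.solution,
                orig_solution2=c2.solution,
                splice_point=len(c1.taxa),
            )
        )
    if c1.solution is not None:
        c1.originals.append(c1.solution)
        c1.solution = None
    if c2.solution is not None:
        c1.originals.append(c2.solution)
        c2.solution = None
    if c2.originals:
        c1.originals.extend(c2.originals)
        c2.originals = []
    for t in c2.taxa:
        S.comp_of[t] = c1
        WORK.taxon_ops += 1
    c1.taxa.extend(c2.taxa)
    c2.taxa = []
    WORK.merges += 1
    return c1


def check_failure(S: Solution) -> bool:
    """True iff the level's single component spans all its taxa."""
    return len(S.components) == 1 and len(S.components[0].taxa) == len(S.taxa)


def assign_to_components(
    S: Solution,
    pending: List[RootedSplit],
    originals: List[Solution],
) -> None:
    """Distribute pending splits and original solutions to their components.

    Every include group lies inside one component by construction of the
    cluster graph; assignment looks up the component of the group's first
    taxon.  Original solutions go to the component of any of their taxa;
    such a component can never hold a live child solution (a level that
    receives originals had no splits, so its components are all fresh).
    Both input lists are consumed.
    """
    for sp in pending:
        c = S.comp_of[next(iter(sp.include))]
        if c is None or not (sp.include <= set(c.taxa)):
            raise AssertionError("split include group spans components")
        c.pending.append(sp)
    for orig in originals:
        c = S.comp_of[orig.taxa[0]]
        if c is None:
            raise AssertionError("original solution landed in a trivial component")
        if c.solution is not None:
            raise AssertionError("original assigned to a component with a live solution")
        c.originals.append(orig)
    pending.clear()
    originals.clear()


# ---------------------------------------------------------------------------
# Plain (from-scratch) BUILD.
# ---------------------------------------------------------------------------


def build(taxa: Iterable[int], sigma: Sequence[RootedSplit]) -> BuildOutcome:
    """Decide joint compatibility of *sigma* over *taxa*; on success the
    returned solution tree displays every input split, and each split is
    recorded at exactly one level (the branch that implies it)."""
    S = create_blank_solution(taxa)
    for sp in sigma:
        if not sp.include <= S.tset:
            raise ValueError("split include group %r not within the taxon set" % (sp,))
    ok = _build_a(S, list(sigma))
    return BuildOutcome(ok, S)


def _build_a(S: Solution, pending: List[RootedSplit]) -> bool:
    S.visits += 1
    remove_irrelevant_splits(S, pending, [])
    merge_components(S, pending, [])
    if check_failure(S):
        return False
    assign_to_components(S, pending, [])
    for c in S.components:
        if c.solution is None:
            c.solution = create_blank_solution(c.taxa)
        sub = c.pending
        c.pending = []
        if not _build_a(c.solution, sub):
            return False
    return True


# ---------------------------------------------------------------------------
# Extracting results.
# ---------------------------------------------------------------------------


def solution_to_tree(S: Solution, index: TaxonIndex) -> dendropy.Tree:
    """The rooted tree encoded by a completed solution.

    One tree node per solution level; one child subtree per non-trivial
    component and one leaf child per trivial taxon, ordered by smallest
    contained taxon id.
    """
    tree = dendropy.Tree()
    tree.is_rooted = True
    tns = tree.taxon_namespace
    _emit(S, tree.seed_node, tns, index)
    return tree


def _emit(S: Solution, node, tns, index: TaxonIndex) -> None:
    if len(S.taxa) == 1:
        node.taxon = tns.require_taxon(label=index.label_of(S.taxa[0]))
        return
    children: List[tuple] = []  # (min taxon id, payload)
    for t in S.taxa:
        if S.comp_of[t] is None:
            children.append((t, t))
    for c in S.components:
        if c.solution is None:
            raise AssertionError("incomplete solution: component without a child solution")
        if c.pending:
            raise AssertionError("incomplete solution: component with pending splits")
        children.append((min(c.taxa), c))
    children.sort(key=lambda pair: pair[0])
    for _, payload in children:
        child = node.new_child()
        if isinstance(payload, int):
            child.taxon = tns.require_taxon(label=index.label_of(payload))
        else:
            _emit(payload.solution, child, tns, index)


def canonical_form(S: Solution) -> str:
    """Deterministic text rendering of a solution tree, for equality checks.

    Taxa ascending; implied splits sorted by (include, exclude); components
    by smallest taxon id.  Transient fields (pending splits, retained
    originals) are included so that an incompletely-restored state cannot
    masquerade as the original.
    """
    parts = ["T=%s" % S.taxa]
    parts.append("I=[%s]" % ";".join(repr(sp) for sp in sorted(S.implied, key=RootedSplit.key)))
    comps = sorted(S.components, key=lambda c: min(c.taxa))
    rendered = []
    for c in comps:
        sub = canonical_form(c.solution) if c.solution is not None else "?"
        extra = ""
        if c.pending or c.originals:
            extra = " pending=%d originals=%d" % (len(c.pending), len(c.originals))
        rendered.append("{%s -> %s%s}" % (sorted(c.taxa), sub, extra))
    parts.append("C=[%s]" % ";".join(rendered))
    return "Solution(%s)" % ", ".join(parts)
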