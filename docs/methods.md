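# Methods

## Rooted splits and compatibility

A rooted split σ = σ₁|•σ₂ on taxon set 𝒯 has disjoint include group σ₁
(|σ₁| ≥ 2) and exclude group σ₂ (|σ₂| ≥ 1); the root lies on the exclude
side, and σ₁ ∪ σ₂ may be a proper subset of 𝒯. A tree *displays* σ if
some node's leaf cluster contains σ₁ and avoids σ₂. Splits whose
restriction to a relevant leaf set degenerates (include below two taxa,
empty exclude) are dropped: they imply no rooted triplets and are
vacuously satisfiable.

Joint compatibility is decided by BUILD. At each recursion level over
taxon set T with relevant splits Σ, taxa are partitioned into connected
components of the cluster graph (an edge between every pair of taxa
inside some include group); a split is *relevant* iff its exclude group
intersects T, and irrelevant splits are recorded as *implied* at that
level — they are satisfied by the branch leading to it. One component
spanning all of T is the failure condition; otherwise each non-trivial
component recurses. The solver never materializes graph edges: it keeps,
per level, an ordered taxon array, the implied-split list, the list of
non-trivial components, and a taxon→component map in which a null entry
denotes a trivial (singleton) component. Mergers splice the smaller
component's taxon list into the larger (ties keep the earlier-created
object) and rewrite only the smaller side's map entries.

The recursion's output structure is canonical: the partition at each
level depends only on the split set, so an incrementally grown solution
and a from-scratch build of the same accepted set are identical up to
ordering. The package normalizes ordering everywhere (taxa ascending,
components by insertion, children of an emitted tree node by smallest
contained taxon id), making runs bit-reproducible.

## Incremental addition and rollback

Adding splits can only merge components, never divide them, so
`buildinc(S, ΔΣ)` updates the solved structure in place. Components
untouched by the new splits keep their child solutions. A component that
absorbs original non-trivial components retains the subsumed solutions
and passes them down; when a subsumed component re-emerges at a deeper
level with the same taxon set, its old solution is plugged back in
verbatim (reuse). A passed-down solution that loses one of its top-level
implied splits to a higher level stops being internally connected and is
*punctured*: its lifted splits go to the receiving level, its remaining
top-level splits rejoin the pending set, and its child solutions join the
passed-down set. Punctured objects are never mutated — their contents are
copied out — which is what makes their rollback free.

Three invariants govern the passed-down set O at every level (asserted at
entry): a level receiving a non-empty O holds no splits; every original's
taxa lie within the level's; originals are pairwise disjoint.

A failed addition must leave the structure exactly as it was. Every
mutation of a *pre-existing* level (one whose visit counter is positive
at entry — levels created during the failing call are simply discarded)
appends a journal entry holding: the prior implied-split count (implied
splits are append-only, so truncation restores them), the prior component
count, a snapshot of the component list taken after new components are
added but before emptied ones are dropped, and one merge record per
component merger. A merge record stores the two component objects (or the
absorbed taxon, for trivial absorptions), the splice offset into the
surviving taxon list, and both components' prior child solutions. Undo
walks merge records in reverse: split the taxon list at the splice
offset, re-point the taxon map, and restore both child-solution fields
from the record. Solutions are restored from the record fields rather
than by popping the component's retained-originals list because a deeper
recursion level may already have consumed that list when failure strikes
below; since all per-call transient fields (pending splits, retained
originals) are empty between calls, rollback simply clears them.
Transient components created by merging two trivial taxa and emptied by a
later merger survive (Python references in the merge records keep them
alive) so their taxa can pass through them during undo. Journals are
skipped entirely for fresh levels, and merge records are never allocated
for levels that had no components — in particular a from-scratch build
allocates none, so the incremental machinery adds no overhead there
(asserted via an allocation counter).

The journal-free mode (`rollback=False`) reproduces the configuration in
which a failed addition forces a from-scratch rebuild of the accepted
set; it exists so the value of rollback itself can be measured.

## The synthesis pipeline

The greedy loop extracts each tree's splits in preorder and accepts a
split iff the accepted set plus that split is compatible. Batching
attempts a whole group in one check and on failure bisects (first ⌈n/2⌉,
then the rest; a failing singleton is rejected) — decisions are provably
identical to one-at-a-time addition. The oracle screens a tree's splits
against the current synthesis tree with the MRCA-child conflict test and
keeps flagged splits out of batches.

Two deliberate choices here:

* **Flagged splits are attempted individually at their original position**
  (maximal clean runs are batched between them), not after the clean
  batch. The conflict test is exact for a split on a tree's full leaf
  universe but *heuristic* against the partial knowledge in the accepted
  set: with accepted {ab|•c} over {a,b,c,d} the synthesis tree is
  ((a,b),c,d) and ad|•b is flagged, yet {ab|•c, ad|•b} is displayed by
  (((a,d),b),c). In-position attempts make the accepted sequence
  invariant across every optimization configuration by construction;
  reordering could not guarantee that.
* **`oracle_skip` mode** drops flagged splits outright (cheaper, as a
  production synthesis would). Because the test is heuristic, this is
  lossy: on small noisy subproblems a few acceptable splits are
  discarded and the accepted set changes. The tests document this
  divergence rather than pretending the heuristic is exact.

Counters: `build_calls` counts top-level compatibility checks (one per
whole-group or single-split attempt); `merge_taxon_ops`/`merge_ops`
count elementary component-maintenance operations and serve as the
hardware-independent work measure for scaling comparisons.

## Simulation protocol

A replicate draws a Yule model tree (backward uniform joins — on four
leaves the balanced shape has probability 1/3), then emits a fixed number
of inputs and one taxonomy:

| parameter | default | meaning |
|---|---|---|
| `n_leaves` | — | leaves in the model tree |
| `n_trees` | 20 | phylogenetic inputs per replicate |
| `tip_prob` | 0.5 | independent tip-retention probability per input |
| `n_ecr` | 2 | ECR moves per input (and on the taxonomy) |
| `collapse_prob` | 0.75 | independent contraction probability per taxonomy edge |

Inputs are tip-subsampled (fresh coin flips until at least two tips
survive — a one-tip tree carries no splits, so the redraw threshold is
two rather than zero) and then perturbed by ECR moves. The taxonomy is
complete, receives the same number of ECR moves, and is then collapsed.
One seeded stream is consumed in fixed order, so replicates are
byte-reproducible.

An ECR move contracts a uniformly chosen internal edge and regroups a
uniformly chosen proper subset (size ≥ 2) of the resulting polytomy's
children under a new node. The subset equal to the contracted node's
former children is excluded: without that exclusion one third of moves on
binary trees are identities and the calibration below undershoots. On a
binary tree each move therefore swaps exactly one cluster for a
conflicting one, so an input with two moves disagrees with the model on
about four splits, counted symmetrically: input splits conflicting with
the model restricted to the input's leaves, plus restricted-model splits
conflicting with the input (restricting first, so chains of model edges
collapsing onto one input edge are counted once). The acceptance run at
the full protocol (500 taxa, 20 inputs, 15 replicates) measures ≈ 4.0.

What the simulator does not emulate: curator-ranked heterogeneous tree
quality, *incertae sedis* placement and the partial taxonomy splits it
induces, non-Yule shape imbalance, and branch lengths. Passing tests
therefore certify algorithmic correctness and scaling behaviour on
realistic split structure, not biological fidelity of any particular
synthesis.

## Measurement scales

Problem sizes were chosen so the whole verification runs in minutes of
pure Python: the enumeration cross-check uses ≤ 6 taxa (945 rooted binary
trees); ladder invariance uses 200 subproblems of 6–12 taxa with 5
inputs; rollback identity uses ≥ 1000 failed additions on 4–10-taxon
multi-level solutions; the scaling trend uses 5-input problems at
50–200 taxa for the from-scratch solver and 50–400 for the incremental
one (the from-scratch solver's work grows near-cubically, which is
exactly why its largest size is capped; the directional comparison only
needs overlapping ranges). Log-log slopes are least-squares fits of work
against taxon count; the incremental solver's slope stays below 2 and
below the naive slope.

## Known limitations

* Split deletion is unsupported; increments only add splits.
* The conflict analysis handles partial splits only by restriction, and
  as noted is heuristic against partial accepted knowledge.
* The per-level algorithms are the quadratic variants; the asymptotically
  faster per-level machinery from the dynamic-connectivity literature is
  intentionally out of scope.
* Subproblem decomposition, tree ranking/curation, and taxon placement
  are upstream concerns; this package solves a given subproblem file.
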