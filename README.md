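# buildinc

Greedy rooted supertree synthesis with an incrementalized BUILD algorithm.

## The problem

Projects that summarize published phylogenies — most prominently the Open
Tree of Life synthesis — build a supertree by walking an ordered list of
input trees (curator-ranked phylogenies first, the comprehensive taxonomy
tree last) and accepting each internal branch's grouping iff it is
compatible with everything accepted so far. Each branch of a rooted input
tree induces a *rooted split* σ = σ₁|•σ₂: the taxa in the include group σ₁
share an ancestor excluding every taxon in σ₂, with the root on the
exclude side (σ₁ ∪ σ₂ is usually a strict subset of the full taxon set
𝒯, because input trees overlap only partially). Joint compatibility of a
split set Σ is decided by Aho's BUILD algorithm: at each recursion level,
link every pair of taxa that co-occur in a relevant split's include group
and split the taxa into the connected components of this cluster graph; a
single spanning component means incompatibility, otherwise recurse into
each component. A synthesis run asks this question thousands of times,
each time with one more split — which is exactly the workload this package
optimizes.

## What is implemented

* **`buildinc.splits`** — taxon interning, rooted splits, split
  extraction from trees, and the display/conflict predicates (the
  conflict test: σ conflicts with tree *U* iff some child cluster of the
  MRCA of σ₁ in *U* intersects both σ₁ and σ₂ after restriction to *U*'s
  leaves).
* **`buildinc.build_core`** — BUILD over rooted splits, storing its work
  in a tree of Solution/Component records (taxon lists, implied splits,
  non-trivial components, taxon→component map); connected components are
  maintained by smaller-into-larger splicing without materializing the
  cluster graph.
* **`buildinc.build_inc`** — the incremental algorithm: `buildinc(S, ΔΣ)`
  adds splits to a solved instance in place, reusing untouched component
  solutions, passing subsumed solutions down for verbatim reuse,
  puncturing the ones that lose splits to higher levels — and journaling
  every mutation of pre-existing state so a failed addition rolls back to
  the exact prior state.
* **`buildinc.pipeline`** — the greedy synthesis loop with the
  optimization ladder: batching (whole-group attempts with recursive
  bisection back-off) and an oracle pre-filter (screen a tree's splits
  against the current synthesis tree so batches rarely contain doomed
  splits). All configurations accept identical split sequences; only the
  number of compatibility checks differs.
* **`buildinc.simulate`** — synthetic subproblems: Yule model tree,
  tip-subsampled inputs perturbed by edge-contract-refine (ECR) moves,
  and a collapsed complete taxonomy.
* **`buildinc.treeio` / `buildinc.cli`** — newick subproblem files and
  the `buildinc` command (`solve`, `simulate`, `check`, `bench`).

## Worked example

```
$ buildinc simulate --taxa 30 --trees 6 --seed 4 -o sub.tre
wrote 7 trees to sub.tre
$ buildinc solve sub.tre -o super.nwk
considered=95 accepted=77 rejected=18 dropped=0 build_calls=54
$ buildinc bench sub.tre
batch  oracle  incremental  rollback  build_calls  merge_ops  accepted  seconds
0      0       0            0         95           8446       77        0.024
1      1       0            0         54           5042       77        0.020
0      0       1            0         95           2326       77        0.009
1      1       1            0         54           2326       77        0.012
0      0       1            1         95           279        77        0.004
1      1       1            1         54           279        77        0.006
```

The simulated subproblem has 95 splits across six noisy inputs plus the
taxonomy; 77 are mutually compatible and become the supertree's branches,
18 conflict with earlier-accepted groupings and are rejected. Every row
of the optimization ladder accepts the same 77 splits; batching+oracle
cuts the 95 compatibility checks to 54, and the incremental solver with
rollback cuts the component-merge work from 8 446 elementary operations
to 279.

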