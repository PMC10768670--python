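"""Subproblem file format and canonical newick writing.

A subproblem is a newline-separated list of rooted newick trees, one per
line, phylogenetic inputs first and the comprehensive taxonomy tree last.
Branch lengths are ignored on input and omitted on output; labels with
whitespace or newick punctuation are single-quoted.  Written trees use a
canonical child order (sorted by smallest descendant label) so output is
independent of construction order.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Sequence, Tuple

import dendropy

from .splits import TaxonIndex, leaf_labels

__all__ = [
    "read_subproblem",
    "write_tree",
    "write_subproblem",
    "tree_to_newick",
]

_SAFE_LABEL = re.compile(r"^[^\s()\[\]{}:;,'\"]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'%s'" % label.replace("'", "''")


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Canonical newick: children sorted by smallest descendant label,
    labels only, terminated by a semicolon."""

    def render(node) -> Tuple[str, str]:  # (min descendant label, newick)
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            if label is None:
                raise ValueError("tree contains an unlabeled leaf")
            return label, _quote(label)
        parts = sorted(render(c) for c in node.child_nodes())
        return parts[0][0], "(%s)" % ",".join(p[1] for p in parts)

    return render(tree.seed_node)[1] + ";"


def _parse_line(line: str, lineno: int) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=line,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ValueError("line %d: cannot parse newick (%s)" % (lineno, exc)) from exc
    seen = set()
    for label in leaf_labels(tree):
        if label in seen:
            raise ValueError("line %d: duplicate tip label %r" % (lineno, label))
        seen.add(label)
    return tree


def read_subproblem(path) -> Tuple[List[dendropy.Tree], TaxonIndex]:
    """Read an ordered tree list; labels are interned into one shared id
    space across trees, in first-appearance order."""
    trees: List[dendropy.Tree] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            trees.append(_parse_line(line, lineno))
    if not trees:
        raise ValueError("%s: no trees found" % path)
    return trees, TaxonIndex.from_trees(trees)


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def write_subproblem(trees: Sequence[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree_to_newick(tree) + "\n")
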