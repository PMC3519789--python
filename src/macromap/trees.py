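"""Leaf-labeled trees with supports, bipartition algebra, and consensus.

Trees are unrooted gene trees (polytomies allowed) whose internal edges
carry bootstrap supports on a 0-100 scale.  Leaves are classified by a
label-prefix table into taxon classes: the focal gymnosperm whose genes
are mapped (default prefix ``Pg``), other gymnosperms (``Pt``), and the
angiosperm outgroups (``AT``, ``Os``) that anchor the
gymnosperm-angiosperm split.

Internally a tree is stored rooted at an arbitrary node; the unrooted
object it represents is recovered through its set of *bipartitions*
(splits): each internal edge cuts the leaves into two sets, normalised
here as the side not containing a fixed reference leaf (the
lexicographically smallest).  Split sets are the common currency of the
consensus operations:

* majority-rule consensus — exactly the splits present in more than half
  of the input trees (these are always mutually compatible), annotated
  with their percentage frequency;
* strict consensus — exactly the splits present in every input tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

#: default leaf-label prefix -> taxon class table
DEFAULT_PREFIX_CLASSES: dict[str, str] = {
    "Pg": "focal_gymno",
    "Pt": "other_gymno",
    "AT": "angiosperm",
    "Os": "angiosperm",
}

FOCAL = "focal_gymno"
ANGIOSPERM = "angiosperm"


class TreeError(ValueError):
    """Malformed tree input or an operation on incompatible trees."""


@dataclass(eq=False)
class Node:
    """A rooted-view tree node; ``support`` belongs to the edge above it."""

    label: str | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def copy(self) -> "Node":
        return Node(self.label, self.support, [c.copy() for c in self.children])


@dataclass
class SupportTree:
    """An unrooted, leaf-labeled tree with per-edge supports and leaf classes."""

    root: Node
    classes: dict[str, str]  # leaf label -> taxon class

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self.root.leaves())

    def leaves_of_class(self, cls: str) -> list[str]:
        return sorted(l for l in self.leaf_labels if self.classes[l] == cls)

    # -- bipartitions ---------------------------------------------------
    def splits(self) -> dict[frozenset[str], float | None]:
        """Non-trivial bipartitions with their supports.

        Each split is normalised as the leaf side *not* containing the
        reference leaf (the smallest label); single-leaf sides and the
        full set are excluded.  If the same edge is seen twice (a degree-2
        root), the supports are reconciled by taking the maximum of the
        non-None values.
        """
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        n = len(all_leaves)
        out: dict[frozenset[str], float | None] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaves())
            if ref in side:
                side = all_leaves - side
            if not 2 <= len(side) <= n - 2:
                continue
            if side in out:
                prev = out[side]
                vals = [v for v in (prev, node.support) if v is not None]
                out[side] = max(vals) if vals else None
            else:
                out[side] = node.support
        return out

    def copy(self) -> "SupportTree":
        return SupportTree(self.root.copy(), dict(self.classes))

    def collapse_low_support(self, min_support: float) -> "SupportTree":
        """Collapse internal edges with support below ``min_support``.

        Edges with no recorded support are kept (treated as resolved).
        """
        t = self.copy()

        def rec(node: Node) -> None:
            new_children: list[Node] = []
            for c in node.children:
                rec(c)
                if (not c.is_leaf and c.support is not None
                        and c.support < min_support):
                    new_children.extend(c.children)
                else:
                    new_children.append(c)
            node.children = new_children

        rec(t.root)
        return t

    def newick(self) -> str:
        return _to_newick(self.root) + ";"


# ---------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------

def classify_leaf(label: str, prefixes: dict[str, str]) -> str:
    for pre in sorted(prefixes, key=len, reverse=True):
        if label.startswith(pre):
            return prefixes[pre]
    raise TreeError(f"leaf label {label!r} matches no class prefix {sorted(prefixes)}")


def _from_dendropy(dnode, classes: dict[str, str], prefixes: dict[str, str]) -> Node:
    if dnode.is_leaf():
        if dnode.taxon is None or not dnode.taxon.label:
            raise TreeError("leaf without a label")
        label = dnode.taxon.label.replace(" ", "_")
        classes[label] = classify_leaf(label, prefixes)
        return Node(label=label)
    support = None
    if dnode.label is not None:
        try:
            support = float(dnode.label)
        except ValueError as exc:
            raise TreeError(f"internal label {dnode.label!r} is not a support value") from exc
    return Node(
        support=support,
        children=[_from_dendropy(c, classes, prefixes) for c in dnode.child_nodes()],
    )


def read_tree_set(
    source: str | Path,
    prefixes: dict[str, str] | None = None,
) -> list[SupportTree]:
    """Read one or more Newick trees (supports as internal node labels).

    ``source`` may be a path or a Newick string.  Leaf taxon classes are
    assigned from the longest matching label prefix; an unclassifiable
    leaf raises :class:`TreeError`.
    """
    prefixes = prefixes if prefixes is not None else DEFAULT_PREFIX_CLASSES
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and not source.strip().startswith("(")):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tl = dendropy.TreeList.get(
            file=io.StringIO(text), schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise TreeError(f"Newick parse error: {exc}") from exc
    out = []
    for t in tl:
        classes: dict[str, str] = {}
        root = _from_dendropy(t.seed_node, classes, prefixes)
        tree = SupportTree(root, classes)
        if len(tree.leaf_labels) != len(root.leaves()):
            raise TreeError("duplicate leaf labels in tree")
        out.append(tree)
    return out


def write_tree_set(trees: Sequence[SupportTree], path: str | Path) -> None:
    Path(path).write_text("\n".join(t.newick() for t in trees) + "\n")


def _to_newick(node: Node) -> str:
    if node.is_leaf:
        return node.label
    inner = ",".join(_to_newick(c) for c in node.children)
    sup = ""
    if node.support is not None:
        sup = f"{node.support:g}"
    return f"({inner}){sup}"


# ---------------------------------------------------------------------
# Building a tree from a compatible split set
# ---------------------------------------------------------------------

def tree_from_splits(
    leaves: frozenset[str],
    splits: dict[frozenset[str], float | None],
    classes: dict[str, str],
) -> SupportTree:
    """Assemble the unique unrooted tree containing exactly ``splits``.

    Splits must be normalised away from the reference leaf (smallest
    label) and pairwise compatible; with that normalisation each split
    is a clade of the tree rooted at the reference leaf, so the tree is
    built by nesting clades by containment.
    """
    ref = min(leaves)
    ordered = sorted(splits, key=len, reverse=True)
    # verify nesting (compatibility): any two splits are disjoint or nested
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if a & b and not (b <= a):
                raise TreeError("incompatible splits")
    top = Node()  # represents the node adjacent to the reference leaf
    node_of: dict[frozenset[str], Node] = {}

    def parent_of(s: frozenset[str]) -> Node:
        best = None
        for cand in ordered:
            if s < cand and (best is None or len(cand) < len(best)):
                best = cand
        return node_of[best] if best is not None else top

    for s in ordered:
        node_of[s] = Node(support=splits[s])
    for s in ordered:
        parent_of(s).children.append(node_of[s])
    for leaf in sorted(leaves - {ref}):
        parent_of(frozenset([leaf])).children.append(Node(label=leaf))
    root = Node(children=[Node(label=ref), top])
    return SupportTree(root, {l: classes[l] for l in leaves})


# ---------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------

def _check_same_leaves(trees: Sequence[SupportTree]) -> frozenset[str]:
    if not trees:
        raise TreeError("no input trees")
    leaves = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leaves:
            raise TreeError("input trees have different leaf sets")
    return leaves


def majority_rule_consensus(trees: Sequence[SupportTree]) -> SupportTree:
    """Strict-majority consensus: splits in > 50% of inputs, with % support."""
    leaves = _check_same_leaves(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    half = len(trees) / 2.0
    kept = {s: 100.0 * c / len(trees) for s, c in counts.items() if c > half}
    return tree_from_splits(leaves, kept, trees[0].classes)


def strict_consensus(t1: SupportTree, t2: SupportTree) -> SupportTree:
    """Splits common to both trees; supports carried as the minimum."""
    leaves = _check_same_leaves([t1, t2])
    s1, s2 = t1.splits(), t2.splits()
    kept: dict[frozenset[str], float | None] = {}
    for s in set(s1) & set(s2):
        vals = [v for v in (s1[s], s2[s]) if v is not None]
        kept[s] = min(vals) if vals else None
    return tree_from_splits(leaves, kept, t1.classes)
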