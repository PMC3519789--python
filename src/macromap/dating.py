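"""Dating gene duplications against the gymnosperm-angiosperm (GA) split.

Each gene family contributes one tree per reconstruction method (e.g. a
neighbour-joining and a parsimony bootstrap consensus).  For a pair of
focal-taxon genes (a, b) on one tree the age of their duplication is
read off the topology after collapsing weakly supported edges:

* **recent** (postdating the GA split) — the smallest clade containing
  both genes, in the tree rooted on an angiosperm leaf, contains no
  angiosperm sequence: the duplication happened inside the gymnosperm
  lineage;
* **ancient** (predating the GA split) — angiosperm sequences intervene
  between the two genes: either the MRCA is binary (the split of its two
  children is resolved and angiosperms necessarily separate the genes)
  or an angiosperm lies inside one of the two children holding the
  genes;
* **undetermined** — the MRCA is a multifurcation whose angiosperm
  leaves all sit in children holding neither gene: the polytomy leaves
  the order of duplication and GA split unresolved.

Across the two per-method trees, a pair whose labels differ is
**incongruent** and excluded from the age tallies.

The rooting convention (lexicographically smallest angiosperm leaf) is
deterministic; for pairs whose label is driven by an angiosperm-free
clade the label is invariant to which angiosperm roots the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .map import GeneticMap
from .tags import ClassifiedPair
from .trees import ANGIOSPERM, FOCAL, SupportTree, TreeError

RECENT = "recent"
ANCIENT = "ancient"
UNDETERMINED = "undetermined"
INCONGRUENT = "incongruent"


def _rooted_clades(
    tree: SupportTree, root_leaf: str, min_support: float
) -> tuple[frozenset[str], list[frozenset[str]]]:
    """Clades of the tree rooted on ``root_leaf``, after support collapse.

    Splits with support below ``min_support`` are dropped (edges without
    a recorded support are kept).  Returns (all leaves except the root
    leaf, clades as frozensets).
    """
    leaves = tree.leaf_labels
    clades = []
    for side, sup in tree.splits().items():
        if sup is not None and sup < min_support:
            continue
        clade = leaves - side if root_leaf in side else side
        clades.append(frozenset(clade))
    return frozenset(leaves - {root_leaf}), clades


def classify_pair_age(
    tree: SupportTree,
    a: str,
    b: str,
    min_support: float = 50.0,
) -> str:
    """Age label for the duplication separating focal genes ``a`` and ``b``.

    Raises
    ------
    TreeError
        If the tree carries no angiosperm leaf (the family is not
        anchored to the GA reference) or a gene is missing.
    """
    leaves = tree.leaf_labels
    if a not in leaves or b not in leaves:
        raise TreeError(f"gene {a!r} or {b!r} absent from tree")
    angios = tree.leaves_of_class(ANGIOSPERM)
    if not angios:
        raise TreeError("family not anchored to GA reference (no angiosperm leaf)")
    root_leaf = angios[0]
    top, clades = _rooted_clades(tree, root_leaf, min_support)

    # MRCA clade: smallest clade containing both genes
    containing = [c for c in clades if a in c and b in c]
    mrca = min(containing, key=len) if containing else top
    angio_set = set(angios)
    if not (mrca & angio_set):
        return RECENT

    # children of the MRCA: maximal proper sub-clades plus uncovered leaves
    proper = [c for c in clades if c < mrca]
    maximal = [c for c in proper if not any(c < d for d in proper)]
    covered = set().union(*maximal) if maximal else set()
    children = maximal + [frozenset([l]) for l in mrca - covered]
    c_a = next(c for c in children if a in c)
    c_b = next(c for c in children if b in c)
    if len(children) == 2:
        return ANCIENT
    if (c_a | c_b) & angio_set:
        return ANCIENT
    return UNDETERMINED


@dataclass(frozen=True)
class PairAgeCall:
    """Final age call for one within-family mapped gene pair."""

    family_id: str
    gene_a: str
    gene_b: str
    label: str
    label_a_tree: str  # label on the first (e.g. NJ) tree
    label_b_tree: str  # label on the second (e.g. MP) tree
    chrom_a: str | None = None
    pos_a: float | None = None
    chrom_b: str | None = None
    pos_b: float | None = None

    @property
    def congruent(self) -> bool:
        return self.label != INCONGRUENT


@dataclass
class AgeTally:
    total: int
    incongruent: int
    ancient: int
    recent: int
    undetermined: int

    @property
    def congruent(self) -> int:
        return self.total - self.incongruent

    def percentages(self) -> dict[str, float]:
        """Percentages of the congruent pairs, printed to one decimal."""
        c = self.congruent
        if c == 0:
            return {ANCIENT: float("nan"), RECENT: float("nan"),
                    UNDETERMINED: float("nan")}
        return {
            ANCIENT: round(100.0 * self.ancient / c, 1),
            RECENT: round(100.0 * self.recent / c, 1),
            UNDETERMINED: round(100.0 * self.undetermined / c, 1),
        }

    @property
    def ancient_recent_ratio(self) -> float:
        return self.ancient / self.recent if self.recent else float("inf")


def tally_calls(calls: Sequence[PairAgeCall]) -> AgeTally:
    labels = [c.label for c in calls]
    return AgeTally(
        total=len(labels),
        incongruent=labels.count(INCONGRUENT),
        ancient=labels.count(ANCIENT),
        recent=labels.count(RECENT),
        undetermined=labels.count(UNDETERMINED),
    )


def classify_family(
    family_id: str,
    tree_a: SupportTree,
    tree_b: SupportTree,
    genes: Sequence[str],
    min_support: float = 50.0,
    locus_of: dict[str, tuple[str, float]] | None = None,
) -> list[PairAgeCall]:
    """Classify all C(k, 2) pairs of mapped focal genes of one family.

    Each pair is labelled on both trees; the final label is the shared
    one, or ``incongruent`` when the trees disagree (including when a
    gene is missing from one tree).
    """
    calls = []
    for a, b in combinations(sorted(genes), 2):
        try:
            la = classify_pair_age(tree_a, a, b, min_support)
        except TreeError:
            la = "absent"
        try:
            lb = classify_pair_age(tree_b, a, b, min_support)
        except TreeError:
            lb = "absent"
        label = la if (la == lb and la != "absent") else INCONGRUENT
        loc_a = locus_of.get(a) if locus_of else None
        loc_b = locus_of.get(b) if locus_of else None
        calls.append(PairAgeCall(
            family_id, a, b, label, la, lb,
            chrom_a=loc_a[0] if loc_a else None,
            pos_a=loc_a[1] if loc_a else None,
            chrom_b=loc_b[0] if loc_b else None,
            pos_b=loc_b[1] if loc_b else None,
        ))
    return calls


def classify_families(
    nj_trees: dict[str, SupportTree],
    mp_trees: dict[str, SupportTree],
    gmap: GeneticMap,
    min_support: float = 50.0,
) -> tuple[list[PairAgeCall], AgeTally]:
    """Classify every within-family mapped gene pair across a family set.

    For each family present in both tree sets, the mapped focal genes
    are the loci of that family on the map whose gene ids appear as
    focal leaves in both trees; families contributing fewer than two such
    genes are skipped.
    """
    locus_of: dict[str, tuple[str, float]] = {}
    for l in gmap.loci:
        locus_of[l.gene_id] = (l.chromosome, l.position)
    calls: list[PairAgeCall] = []
    for fam in sorted(set(nj_trees) & set(mp_trees)):
        nj, mp = nj_trees[fam], mp_trees[fam]
        mapped = [
            l.gene_id for l in gmap.by_family().get(fam, [])
            if l.gene_id in nj.leaf_labels or l.gene_id in mp.leaf_labels
        ]
        if len(mapped) < 2:
            continue
        calls.extend(classify_family(fam, nj, mp, mapped, min_support, locus_of))
    return calls, tally_calls(calls)


def calls_to_classified_pairs(calls: Sequence[PairAgeCall]) -> list[ClassifiedPair]:
    """Convert congruent age calls with positions to classified pairs."""
    out = []
    for c in calls:
        if c.label == INCONGRUENT or c.chrom_a is None or c.chrom_b is None:
            continue
        out.append(ClassifiedPair(
            c.family_id, c.gene_a, c.gene_b,
            c.chrom_a, c.pos_a, c.chrom_b, c.pos_b, c.label,
        ))
    return out
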