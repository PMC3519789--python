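"""Seeded generators for every input the pipeline consumes.

The generators emulate a gene-dense conifer-style genetic map (12
linkage groups, uniform background gene placement with optional
gene-rich windows), per-family gene-tree pairs with a known duplication
history relative to the gymnosperm-angiosperm (GA) split, cross-map hit
tables with a known orthology, and tissue expression profiles.  Every
generator is a pure function of its :class:`ScenarioConfig` (including
the seed) and returns the matching :class:`GroundTruth`, which is
sufficient to score the downstream analyses without re-deriving truth.

Paper-derived defaults (translocation probabilities 0.919 ancient /
0.425 recent, same-chromosome distance means 47.0 / 4.3 cM, an 8:1
ancient:recent event ratio) are *generator parameters* describing the
emulated study conditions, not assertions about any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .map import GeneLocus, GeneticMap
from .synteny import HitRecord
from .trees import ANGIOSPERM, FOCAL, DEFAULT_PREFIX_CLASSES, Node, SupportTree

#: default linkage-group lengths (cM) of a 12-chromosome conifer-style map
DEFAULT_LENGTHS: dict[str, float] = {
    "1": 180.6, "2": 185.3, "3": 172.6, "4": 168.3, "5": 167.1, "6": 180.3,
    "7": 204.5, "8": 157.4, "9": 145.8, "10": 120.4, "11": 171.2, "12": 131.7,
}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic scenario; defaults emulate the study map."""

    seed: int = 0
    lengths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LENGTHS))
    genes_per_chromosome: int = 150
    # gene-rich regions: (chromosome, center cM, width cM, enrichment factor)
    grr_regions: list[tuple[str, float, float, float]] = field(default_factory=list)
    # families
    n_families: int = 157
    mean_family_size: float = 3.4          # sizes ~ 2 + Poisson(mean - 2)
    n_tandem_families: int = 0             # planted single-chromosome arrays
    tandem_family_sizes: tuple[int, int] = (2, 4)
    n_coloc_groups: int = 0                # planted zero-recombinant groups
    coloc_group_sizes: tuple[int, int] = (2, 3)
    # duplication history
    fraction_ancient: float = 8.0 / 9.0
    p_transloc_ancient: float = 0.919
    p_transloc_recent: float = 0.425
    mean_dist_ancient: float = 47.0        # cM, same-chromosome ancient pairs
    sd_dist_ancient: float = 15.0          # small enough that truncation at the
                                           # chromosome ends leaves the realized
                                           # mean at the nominal value
    mean_dist_recent: float = 4.3          # cM, same-chromosome recent pairs
    p_pine_leaf: float = 0.5               # other-gymnosperm leaf per lineage
    p_angiosperm_loss: float = 0.0
    # tree noise
    p_nni: float = 0.0
    p_collapse: float = 0.0
    # map pair
    n_shared_genes: int = 150
    n_translocations: int = 0
    n_inversions: int = 0
    position_jitter: float = 0.0           # cM, sd of map-B position noise; any
                                           # jitter can swap close gene orders,
                                           # so the identity scenario keeps 0
    ortholog_identity: tuple[float, float] = (92.0, 3.0)  # mean, sd
    decoy_identity: tuple[float, float] = (70.0, 78.0)    # uniform range
    decoy_rate: float = 0.3                # decoy hits per gene per direction
    # expression
    n_tissues: int = 8

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Recorded truth for a generated scenario (JSON-serialisable)."""

    grr_regions: list[tuple[str, float, float, float]] = field(default_factory=list)
    tandem_families: list[str] = field(default_factory=list)
    coloc_groups: list[list[str]] = field(default_factory=list)
    family_chromosomes: dict[str, int] = field(default_factory=dict)
    # per gene pair (sorted gene-id tuple joined by '|')
    pair_age: dict[str, str] = field(default_factory=dict)
    pair_translocated: dict[str, bool] = field(default_factory=dict)
    pair_distance: dict[str, float] = field(default_factory=dict)
    # map pair
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    homoeology: dict[str, str] = field(default_factory=dict)
    translocated_genes: list[str] = field(default_factory=list)
    coexpressed_groups: list[list[str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @staticmethod
    def pair_key(a: str, b: str) -> str:
        return "|".join(sorted((a, b)))


# ---------------------------------------------------------------------
# Map generator
# ---------------------------------------------------------------------

def simulate_map(cfg: ScenarioConfig) -> tuple[GeneticMap, GroundTruth]:
    """Uniform-background map with optional gene-rich windows and families.

    Background genes are uniform per chromosome.  Each GRR spec
    ``(chromosome, center, width, enrichment)`` adds extra genes inside
    its window so the local density is ``enrichment`` times the
    background (enrichment must be >= 1).  Planted tandem families are
    contiguous same-chromosome clusters within 1 cM; planted
    co-localizing groups are exact position ties of unrelated genes;
    remaining families are dispersed uniformly.
    """
    rng = cfg.rng(1)
    truth = GroundTruth(grr_regions=list(cfg.grr_regions))
    loci: list[GeneLocus] = []
    counter = 0

    def add(chrom: str, pos: float, family: str | None = None) -> GeneLocus:
        nonlocal counter
        counter += 1
        gid = f"G{counter:05d}"
        l = GeneLocus(f"L{counter:05d}", gid, chrom, float(pos), family)
        loci.append(l)
        return l

    for chrom, L in cfg.lengths.items():
        for pos in rng.uniform(0, L, size=cfg.genes_per_chromosome):
            add(chrom, pos)
    for chrom, center, width, enrich in cfg.grr_regions:
        if enrich < 1:
            raise ValueError("GRR enrichment must be >= 1")
        L = cfg.lengths[chrom]
        lo = max(0.0, center - width / 2)
        hi = min(L, center + width / 2)
        n_extra = round(cfg.genes_per_chromosome * (hi - lo) / L * (enrich - 1))
        for pos in rng.uniform(lo, hi, size=n_extra):
            add(chrom, pos)

    chroms = list(cfg.lengths)
    for t in range(cfg.n_tandem_families):
        fam = f"TF{t + 1:03d}"
        chrom = chroms[rng.integers(len(chroms))]
        L = cfg.lengths[chrom]
        size = int(rng.integers(cfg.tandem_family_sizes[0], cfg.tandem_family_sizes[1] + 1))
        anchor = rng.uniform(0, L - 1.0)
        pos = anchor
        for _ in range(size):
            add(chrom, min(pos, L), fam)
            pos += rng.uniform(0.05, 0.9 / max(size - 1, 1))
        truth.tandem_families.append(fam)
        truth.family_chromosomes[fam] = 1

    n_dispersed = cfg.n_families - cfg.n_tandem_families
    for d in range(max(n_dispersed, 0)):
        fam = f"DF{d + 1:03d}"
        size = 2 + int(rng.poisson(max(cfg.mean_family_size - 2, 0)))
        occupied = set()
        for _ in range(size):
            chrom = chroms[rng.integers(len(chroms))]
            add(chrom, rng.uniform(0, cfg.lengths[chrom]), fam)
            occupied.add(chrom)
        truth.family_chromosomes[fam] = len(occupied)

    for g in range(cfg.n_coloc_groups):
        size = int(rng.integers(cfg.coloc_group_sizes[0], cfg.coloc_group_sizes[1] + 1))
        chrom = chroms[rng.integers(len(chroms))]
        pos = rng.uniform(0, cfg.lengths[chrom])
        members = [add(chrom, pos) for _ in range(size)]
        truth.coloc_groups.append([m.gene_id for m in members])

    return GeneticMap(lengths=dict(cfg.lengths), loci=loci), truth


# ---------------------------------------------------------------------
# Family trees with a known duplication history
# ---------------------------------------------------------------------

def _random_binary(rng: np.random.Generator, tips: list[Node]) -> Node:
    """Random binary tree over the given tip subtrees (random joins)."""
    nodes = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    return nodes[0]


def _apply_noise(root: Node, rng: np.random.Generator, p_nni: float,
                 p_collapse: float) -> Node:
    """Independent NNI / edge-collapse noise; supports 100 on kept edges."""
    root = root.copy()

    def internal_children(node: Node) -> list[tuple[Node, Node]]:
        out = []
        for c in node.children:
            if not c.is_leaf:
                out.append((node, c))
                out.extend(internal_children(c))
        return out

    # NNI moves: swap a child of an internal edge's lower node with one
    # of its siblings
    for parent, child in internal_children(root):
        if rng.random() < p_nni and len(parent.children) >= 2 and child.children:
            sibs = [c for c in parent.children if c is not child]
            if not sibs:
                continue
            s = sibs[int(rng.integers(len(sibs)))]
            x = child.children[int(rng.integers(len(child.children)))]
            parent.children[parent.children.index(s)] = x
            child.children[child.children.index(x)] = s
    # collapses
    def collapse(node: Node) -> None:
        kept = []
        for c in node.children:
            collapse(c)
            if not c.is_leaf and rng.random() < p_collapse:
                kept.extend(c.children)
            else:
                kept.append(c)
        node.children = kept

    collapse(root)
    for n in root.walk():
        if not n.is_leaf and n is not root:
            n.support = 100.0
    return root


def _place_gene(rng: np.random.Generator, cfg: ScenarioConfig,
                ref: tuple[str, float] | None, p_transloc: float,
                mean_dist: float, sd_dist: float | None) -> tuple[str, float]:
    """Place one gene relative to a reference locus (or uniformly)."""
    chroms = list(cfg.lengths)
    if ref is None or rng.random() < p_transloc:
        others = [c for c in chroms if ref is None or c != ref[0]]
        chrom = others[int(rng.integers(len(others)))]
        return chrom, float(rng.uniform(0, cfg.lengths[chrom]))
    chrom, p0 = ref
    L = cfg.lengths[chrom]
    for _ in range(1000):
        if sd_dist is None:
            d = float(rng.exponential(mean_dist))
        else:
            d = float(rng.normal(mean_dist, sd_dist))
        if not 0 < d < L:
            continue
        sides = [s for s in (+1, -1) if 0 <= p0 + s * d <= L]
        if sides:
            s = sides[int(rng.integers(len(sides)))]
            return chrom, p0 + s * d
    raise RuntimeError("could not place gene within chromosome bounds")


def simulate_family_trees(
    cfg: ScenarioConfig,
) -> tuple[dict[str, SupportTree], dict[str, SupportTree], GeneticMap, GroundTruth]:
    """Per-family NJ-like and MP-like trees, mapped genes, and truth.

    Each family's history: a binomial number of its duplication events
    predate the GA split, giving a set of pre-GA lineages; genes within
    a lineage descend from post-GA (recent) duplications, genes in
    different lineages from pre-GA (ancient) ones.  Every pre-GA lineage
    carries a sibling angiosperm cherry (two lineages, e.g. a eudicot
    and a monocot representative); optional other-gymnosperm leaves are
    neutral to the classification.  Focal genes are placed on a map:
    within a lineage the next gene either translocates (probability
    ``p_transloc_recent``) or sits at an Exp(``mean_dist_recent``) offset
    from the previous one; the first gene of each further lineage either
    translocates (``p_transloc_ancient``) from the family's first locus
    or sits at a Normal(``mean_dist_ancient``, sd) offset.  The two tree
    copies receive independent NNI/collapse noise; retained internal
    edges carry support 100.
    """
    rng = cfg.rng(2)
    nj: dict[str, SupportTree] = {}
    mp: dict[str, SupportTree] = {}
    truth = GroundTruth()
    loci: list[GeneLocus] = []
    locus_n = 0

    for f in range(1, cfg.n_families + 1):
        fam = f"F{f:03d}"
        k = 2 + int(rng.poisson(max(cfg.mean_family_size - 2, 0)))
        n_ancient = int(rng.binomial(k - 1, cfg.fraction_ancient))
        n_lineages = n_ancient + 1
        # random surjective assignment of genes to lineages
        while True:
            assign = rng.integers(n_lineages, size=k)
            if len(np.unique(assign)) == n_lineages:
                break
        gene_ids = [f"Pg{f}g{i + 1}" for i in range(k)]

        # --- map placement and pair truth
        pos: dict[str, tuple[str, float]] = {}
        anchor: tuple[str, float] | None = None
        for lin in range(n_lineages):
            genes = [g for g, a in zip(gene_ids, assign) if a == lin]
            first = _place_gene(rng, cfg, anchor, cfg.p_transloc_ancient,
                                cfg.mean_dist_ancient, cfg.sd_dist_ancient) \
                if anchor is not None else _place_gene(rng, cfg, None, 1.0, 0.0, None)
            pos[genes[0]] = first
            if anchor is None:
                anchor = first
            prev = first
            for g in genes[1:]:
                prev = _place_gene(rng, cfg, prev, cfg.p_transloc_recent,
                                   cfg.mean_dist_recent, None)
                pos[g] = prev
        for i in range(k):
            for j in range(i + 1, k):
                key = GroundTruth.pair_key(gene_ids[i], gene_ids[j])
                age = "recent" if assign[i] == assign[j] else "ancient"
                truth.pair_age[key] = age
                ca, pa = pos[gene_ids[i]]
                cb, pb = pos[gene_ids[j]]
                truth.pair_translocated[key] = ca != cb
                if ca == cb:
                    truth.pair_distance[key] = abs(pa - pb)
        for g in gene_ids:
            locus_n += 1
            c, p = pos[g]
            loci.append(GeneLocus(f"PL{locus_n:05d}", g, c, p, fam))

        # --- true topology
        classes: dict[str, str] = {}
        lineage_subtrees = []
        keep_angio = rng.random(n_lineages) >= cfg.p_angiosperm_loss
        if not keep_angio.any():
            keep_angio[0] = True
        for lin in range(n_lineages):
            genes = [g for g, a in zip(gene_ids, assign) if a == lin]
            tips = [Node(label=g) for g in genes]
            for g in genes:
                classes[g] = FOCAL
            if rng.random() < cfg.p_pine_leaf:
                label = f"Pt{f}_{lin + 1}"
                classes[label] = "other_gymno"
                tips.append(Node(label=label))
            gym = _random_binary(rng, tips)
            if keep_angio[lin]:
                at, os_ = f"AT{f}_{lin + 1}", f"Os{f}_{lin + 1}"
                classes[at] = classes[os_] = ANGIOSPERM
                angio = Node(children=[Node(label=at), Node(label=os_)])
                lineage_subtrees.append(Node(children=[gym, angio]))
            else:
                lineage_subtrees.append(gym)
        true_root = (_random_binary(rng, lineage_subtrees)
                     if len(lineage_subtrees) > 1 else lineage_subtrees[0])
        for n in true_root.walk():
            if not n.is_leaf and n is not true_root:
                n.support = 100.0

        nj[fam] = SupportTree(
            _apply_noise(true_root, rng, cfg.p_nni, cfg.p_collapse), dict(classes))
        mp[fam] = SupportTree(
            _apply_noise(true_root, rng, cfg.p_nni, cfg.p_collapse), dict(classes))

    gmap = GeneticMap(lengths=dict(cfg.lengths), loci=loci)
    return nj, mp, gmap, truth


# ---------------------------------------------------------------------
# Map pair with hit tables
# ---------------------------------------------------------------------

def simulate_map_pair(
    cfg: ScenarioConfig,
) -> tuple[GeneticMap, GeneticMap, list[HitRecord], list[HitRecord], GroundTruth]:
    """Two maps related by renaming, jitter, and configured rearrangements.

    Map B is map A with chromosomes relabelled (``B<k>``), gene ids
    prefixed, positions jittered by Normal(0, ``position_jitter``), then
    ``n_translocations`` random single-gene moves to another chromosome
    and ``n_inversions`` random segment inversions.  Hit tables in both
    directions contain the true ortholog at Normal ``ortholog_identity``
    (truncated to [70, 100]) plus uniform low-identity decoys; bit score
    is a deterministic, monotone function of identity.
    """
    rng = cfg.rng(3)
    truth = GroundTruth()
    chroms = list(cfg.lengths)
    loci_a: list[GeneLocus] = []
    loci_b: list[GeneLocus] = []
    b_name = {c: f"B{i + 1}" for i, c in enumerate(chroms)}
    truth.homoeology = dict(b_name)

    for i in range(cfg.n_shared_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        p = float(rng.uniform(0, cfg.lengths[chrom]))
        ga, gb = f"a{i + 1:04d}", f"b{i + 1:04d}"
        loci_a.append(GeneLocus(f"LA{i + 1:04d}", ga, chrom, p))
        pb = float(np.clip(p + rng.normal(0, cfg.position_jitter), 0,
                           cfg.lengths[chrom]))
        loci_b.append(GeneLocus(f"LB{i + 1:04d}", gb, b_name[chrom], pb))
        truth.ortholog_pairs.append((ga, gb))

    lengths_b = {b_name[c]: L for c, L in cfg.lengths.items()}

    moved = rng.choice(len(loci_b), size=min(cfg.n_translocations, len(loci_b)),
                       replace=False)
    for idx in moved:
        l = loci_b[idx]
        others = [c for c in lengths_b if c != l.chromosome]
        new_c = others[int(rng.integers(len(others)))]
        loci_b[idx] = GeneLocus(l.locus_id, l.gene_id, new_c,
                                float(rng.uniform(0, lengths_b[new_c])))
        truth.translocated_genes.append(l.gene_id)

    for _ in range(cfg.n_inversions):
        chrom = list(lengths_b)[int(rng.integers(len(lengths_b)))]
        L = lengths_b[chrom]
        a, b = sorted(rng.uniform(0, L, size=2))
        for idx, l in enumerate(loci_b):
            if l.chromosome == chrom and a <= l.position <= b:
                loci_b[idx] = GeneLocus(l.locus_id, l.gene_id, chrom,
                                        a + b - l.position)

    map_a = GeneticMap(lengths=dict(cfg.lengths), loci=loci_a)
    map_b = GeneticMap(lengths=lengths_b, loci=loci_b)

    def score(identity: float) -> float:
        return round(10.0 * identity, 1)

    mu, sd = cfg.ortholog_identity
    ab: list[HitRecord] = []
    ba: list[HitRecord] = []
    genes_b = [l.gene_id for l in loci_b]
    genes_a = [l.gene_id for l in loci_a]
    for ga, gb in truth.ortholog_pairs:
        # identities carry BLAST-style 3-decimal precision
        ident = round(float(np.clip(rng.normal(mu, sd), 70.0, 100.0)), 3)
        ab.append(HitRecord(ga, gb, ident, score(ident)))
        ba.append(HitRecord(gb, ga, ident, score(ident)))
        lo, hi = cfg.decoy_identity
        if rng.random() < cfg.decoy_rate:
            decoy = genes_b[int(rng.integers(len(genes_b)))]
            if decoy != gb:
                di = round(float(rng.uniform(lo, hi)), 3)
                ab.append(HitRecord(ga, decoy, di, score(di)))
        if rng.random() < cfg.decoy_rate:
            decoy = genes_a[int(rng.integers(len(genes_a)))]
            if decoy != ga:
                di = round(float(rng.uniform(lo, hi)), 3)
                ba.append(HitRecord(gb, decoy, di, score(di)))
    return map_a, map_b, ab, ba, truth


# ---------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------

def simulate_expression(
    cfg: ScenarioConfig,
    coexpressed_groups: list[list[str]],
    independent_genes: list[str] = (),
):
    """Gene x tissue expression with planted co-regulated groups.

    Genes within a planted group share one latent tissue profile plus
    small independent noise; all other genes get independent profiles.
    Returns an :class:`~macromap.annotate.ExpressionMatrix`.
    """
    import pandas as pd

    from .annotate import ExpressionMatrix

    rng = cfg.rng(4)
    tissues = [f"tissue{i + 1}" for i in range(cfg.n_tissues)]
    rows = {}
    truth_groups = []
    for group in coexpressed_groups:
        latent = rng.normal(0, 2.0, size=cfg.n_tissues)
        for g in group:
            rows[g] = latent + rng.normal(0, 0.1, size=cfg.n_tissues)
        truth_groups.append(list(group))
    for g in independent_genes:
        rows[g] = rng.normal(0, 2.0, size=cfg.n_tissues)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    return ExpressionMatrix(df), truth_groups
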