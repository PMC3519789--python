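"""Cross-map homology, synteny, collinearity, and conserved segments.

Homologous gene pairs between two genetic maps are resolved from
BLAST-style tabular hit tables by reciprocal best hit (RBH) above an
identity threshold.  Chromosome homoeology is assigned by plurality of
links; a link is *syntenic* when it connects a homoeologous chromosome
pair and *collinear* when it belongs to a longest order-preserving
(nondecreasing) subsequence of the syntenic links of that pair.
Conserved segments are maximal runs of consecutive collinear links with
bounded gaps on both maps, and their spans yield per-map coverage.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .map import GeneticMap

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "bitscore"]


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    identity: float  # percent, 0..100
    score: float


def load_hits(path: str | Path) -> list[HitRecord]:
    """Read a BLAST outfmt-6 style subset: qseqid sseqid pident bitscore.

    Accepts files with or without a header line.
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    header = 0 if str(first.iloc[0, 0]) == "qseqid" else None
    df = pd.read_csv(path, sep="\t", header=header, names=HIT_COLUMNS,
                     dtype={0: str, 1: str})
    return [
        HitRecord(q, s, float(i), float(b))
        for q, s, i, b in zip(df.qseqid, df.sseqid, df.pident, df.bitscore)
    ]


def write_hits(hits: list[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(h.query, h.subject, h.identity, h.score) for h in hits],
        columns=HIT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def _best_hits(hits: list[HitRecord], min_identity: float) -> dict[str, str]:
    """Best subject per query among hits at or above the identity floor.

    Ordering key: score desc, identity desc, subject id asc — fully
    deterministic.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.identity < min_identity:
            continue
        cur = best.get(h.query)
        if cur is None or (h.score, h.identity, _neg(h.subject)) > (
            cur.score, cur.identity, _neg(cur.subject)
        ):
            best[h.query] = h
    return {q: h.subject for q, h in best.items()}


class _neg(str):
    """Reverses lexical comparison so 'smaller id wins' fits a max key."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def reciprocal_best_hits(
    ab: list[HitRecord],
    ba: list[HitRecord],
    min_identity: float = 80.0,
) -> list[tuple[str, str]]:
    """Gene pairs (a, b) that are each other's best hit above the threshold."""
    fwd = _best_hits(ab, min_identity)
    rev = _best_hits(ba, min_identity)
    pairs = [(a, b) for a, b in fwd.items() if rev.get(b) == a]
    return sorted(pairs)


@dataclass
class SyntenyLink:
    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: float
    chrom_b: str
    pos_b: float
    syntenic: bool = False
    collinear: bool = False


@dataclass
class SyntenyResult:
    links: list[SyntenyLink]
    homoeology: dict[str, str]  # chromosome of A -> homoeologous chromosome of B
    pct_syntenic: float | None

    def syntenic_links(self) -> list[SyntenyLink]:
        return [l for l in self.links if l.syntenic]


def synteny_links(
    map_a: GeneticMap,
    map_b: GeneticMap,
    pairs: list[tuple[str, str]],
) -> SyntenyResult:
    """Assign homoeologous chromosome pairs and flag syntenic links.

    For each chromosome of map A, the homoeologous chromosome of map B
    is the one receiving the plurality of its links (ties broken by the
    chromosome's total link count, then label order).  A link is
    syntenic iff it connects a homoeologous pair.  Links sharing a gene
    on the same chromosome pair are collapsed to one.
    """
    gene_a = {l.gene_id: l for l in map_a.loci}
    gene_b = {l.gene_id: l for l in map_b.loci}
    links: list[SyntenyLink] = []
    seen: set[tuple[str, str, str]] = set()
    for a, b in pairs:
        if a not in gene_a or b not in gene_b:
            raise KeyError(f"pair ({a}, {b}) not present on both maps")
        la, lb = gene_a[a], gene_b[b]
        # collapse many-to-one matches on one chromosome pair to one link
        key_a = ("a", a, lb.chromosome)
        key_b = ("b", b, la.chromosome)
        if key_a in seen or key_b in seen:
            continue
        seen.add(key_a)
        seen.add(key_b)
        links.append(SyntenyLink(a, b, la.chromosome, la.position,
                                 lb.chromosome, lb.position))
    if not links:
        return SyntenyResult([], {}, None)

    tally: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    totals: dict[str, int] = defaultdict(int)
    for l in links:
        tally[l.chrom_a][l.chrom_b] += 1
        totals[l.chrom_b] += 1
    homoeology = {
        ca: max(sub, key=lambda cb: (sub[cb], totals[cb], _neg(cb)))
        for ca, sub in tally.items()
    }
    n_syn = 0
    for l in links:
        l.syntenic = homoeology.get(l.chrom_a) == l.chrom_b
        n_syn += l.syntenic
    return SyntenyResult(links, dict(homoeology), 100.0 * n_syn / len(links))


def _lnds_indices(values: list[float]) -> list[int]:
    """Indices of one longest nondecreasing subsequence (patience sorting)."""
    tails: list[float] = []
    tails_idx: list[int] = []
    prev = [-1] * len(values)
    for i, v in enumerate(values):
        j = bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def collinearity(
    links: list[SyntenyLink],
    allow_reversed: bool = True,
) -> tuple[list[SyntenyLink], float | None]:
    """Collinear subset of syntenic links on one chromosome pair.

    Links sorted by map-A position (ties by map-B position); the
    collinear subset is a longest nondecreasing subsequence of the map-B
    positions, so coordinate ties never break collinearity.  With
    ``allow_reversed`` the better of the forward and reversed map-B
    orientations is taken (a whole-chromosome inversion conserves local
    order).  Flags the chosen links in place and returns (subset,
    percent collinear).
    """
    if not links:
        return [], None
    fwd_sorted = sorted(links, key=lambda l: (l.pos_a, l.pos_b))
    fwd = _lnds_indices([l.pos_b for l in fwd_sorted])
    best_sorted, best = fwd_sorted, fwd
    if allow_reversed:
        rev_sorted = sorted(links, key=lambda l: (l.pos_a, -l.pos_b))
        rev = _lnds_indices([-l.pos_b for l in rev_sorted])
        if len(rev) > len(fwd):
            best_sorted, best = rev_sorted, rev
    subset = [best_sorted[i] for i in best]
    for l in subset:
        l.collinear = True
    return subset, 100.0 * len(subset) / len(links)


def collinearity_by_pair(
    result: SyntenyResult, allow_reversed: bool = True
) -> tuple[list[SyntenyLink], float | None]:
    """Collinearity over all homoeologous chromosome pairs of a synteny result."""
    groups: dict[tuple[str, str], list[SyntenyLink]] = defaultdict(list)
    for l in result.syntenic_links():
        groups[(l.chrom_a, l.chrom_b)].append(l)
    collinear: list[SyntenyLink] = []
    total = 0
    for key in sorted(groups):
        subset, _ = collinearity(groups[key], allow_reversed)
        collinear.extend(subset)
        total += len(groups[key])
    pct = 100.0 * len(collinear) / total if total else None
    return collinear, pct


@dataclass
class ConservedSegment:
    chrom_a: str
    chrom_b: str
    start_a: float
    end_a: float
    start_b: float
    end_b: float
    links: list[SyntenyLink]

    @property
    def span_a(self) -> float:
        return self.end_a - self.start_a

    @property
    def span_b(self) -> float:
        return self.end_b - self.start_b


def conserved_segments(
    collinear: list[SyntenyLink],
    map_a: GeneticMap,
    map_b: GeneticMap,
    max_gap: float = 20.0,
) -> tuple[list[ConservedSegment], float, float]:
    """Conserved segments and per-map coverage from collinear links.

    Segments are maximal runs of consecutive collinear links (ordered by
    map-A position) whose inter-link gaps are <= ``max_gap`` cM on both
    maps.  Single-link runs yield degenerate zero-span segments.
    Coverage = sum of segment spans / total map length, per map, as a
    percentage.
    """
    groups: dict[tuple[str, str], list[SyntenyLink]] = defaultdict(list)
    for l in collinear:
        groups[(l.chrom_a, l.chrom_b)].append(l)
    segments: list[ConservedSegment] = []
    for (ca, cb), ls in sorted(groups.items()):
        ls = sorted(ls, key=lambda l: (l.pos_a, l.pos_b))
        run = [ls[0]]
        for l in ls[1:]:
            if (l.pos_a - run[-1].pos_a <= max_gap
                    and abs(l.pos_b - run[-1].pos_b) <= max_gap):
                run.append(l)
            else:
                segments.append(_segment(ca, cb, run))
                run = [l]
        segments.append(_segment(ca, cb, run))
    cov_a = 100.0 * sum(s.span_a for s in segments) / map_a.total_length
    cov_b = 100.0 * sum(s.span_b for s in segments) / map_b.total_length
    return segments, cov_a, cov_b


def _segment(ca: str, cb: str, run: list[SyntenyLink]) -> ConservedSegment:
    pa = [l.pos_a for l in run]
    pb = [l.pos_b for l in run]
    return ConservedSegment(ca, cb, min(pa), max(pa), min(pb), max(pb), list(run))
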