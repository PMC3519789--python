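"""Genetic-map data model and I/O.

A :class:`GeneticMap` is an ordered collection of linkage groups
("chromosomes", labelled strings) with declared cM lengths, carrying
:class:`GeneLocus` records.  Positions are 0-based centiMorgan floats on
the half-open interval ``[0, length)``; ties in position are allowed and
meaningful (zero-recombinant loci).  Maps round-trip through a simple TSV
with columns ``locus_id, gene_id, chromosome, position_cM, family_id,
species``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["locus_id", "gene_id", "chromosome", "position_cM", "family_id", "species"]

#: sentinel used in TSV for an absent family
_NA = "."


class MapError(ValueError):
    """Malformed or inconsistent genetic-map input."""


@dataclass(frozen=True)
class GeneLocus:
    """A single mapped gene locus.

    Parameters
    ----------
    locus_id
        Unique locus identifier within a map.
    gene_id
        Identifier of the gene the locus represents (several loci may
        tag the same gene across maps).
    chromosome
        Linkage-group label (string).
    position
        Map position in cM, ``0 <= position <= length(chromosome)``.
    family_id
        Gene-family label, or ``None`` for singletons/unassigned.
    species
        Source tag, e.g. ``"focal"`` for loci mapped directly and a
        donor-taxon tag for loci transferred from another map.
    """

    locus_id: str
    gene_id: str
    chromosome: str
    position: float
    family_id: str | None = None
    species: str = "focal"


@dataclass
class GeneticMap:
    """A gene linkage map: chromosomes with lengths and positioned loci."""

    lengths: dict[str, float]
    loci: list[GeneLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- introspection -------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths.values()))

    def __len__(self) -> int:
        return len(self.loci)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.lengths == other.lengths and self.loci == other.loci

    def loci_on(self, chromosome: str) -> list[GeneLocus]:
        """Loci on one chromosome, sorted by position (ties by locus id)."""
        found = [l for l in self.loci if l.chromosome == chromosome]
        return sorted(found, key=lambda l: (l.position, l.locus_id))

    def positions(self, chromosome: str) -> list[float]:
        return [l.position for l in self.loci_on(chromosome)]

    def counts(self) -> dict[str, int]:
        """Number of mapped loci per chromosome."""
        out = {c: 0 for c in self.lengths}
        for l in self.loci:
            out[l.chromosome] += 1
        return out

    def by_family(self) -> dict[str, list[GeneLocus]]:
        """Loci grouped by family id (unassigned loci skipped)."""
        fams: dict[str, list[GeneLocus]] = {}
        for l in self.loci:
            if l.family_id is not None:
                fams.setdefault(l.family_id, []).append(l)
        return fams

    def locus(self, locus_id: str) -> GeneLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        for c, length in self.lengths.items():
            if not length > 0:
                raise MapError(f"chromosome {c!r} has non-positive length {length}")
        seen: set[str] = set()
        for l in self.loci:
            if l.chromosome not in self.lengths:
                raise MapError(f"locus {l.locus_id}: unknown chromosome {l.chromosome!r}")
            if not 0 <= l.position <= self.lengths[l.chromosome]:
                raise MapError(
                    f"locus {l.locus_id}: position {l.position} outside "
                    f"[0, {self.lengths[l.chromosome]}] on chromosome {l.chromosome}"
                )
            if l.locus_id in seen:
                raise MapError(f"duplicate locus id {l.locus_id!r}")
            seen.add(l.locus_id)


# ---------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------

def load_map(path: str | Path, lengths: dict[str, float] | None = None) -> GeneticMap:
    """Read a genetic map from TSV.

    The file must carry the header ``locus_id gene_id chromosome
    position_cM family_id species``.  Chromosome lengths are taken from
    ``lengths`` when given; otherwise each chromosome's length defaults
    to the maximum observed position (a degenerate but self-consistent
    choice for quick inspection).

    Raises
    ------
    MapError
        On a missing column, an unparseable position (the offending line
        is named), a duplicate locus id, or a position above the declared
        chromosome length.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise MapError(f"{path}: missing column(s) {missing}")
    loci = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            pos = float(row.position_cM)
        except ValueError as exc:
            raise MapError(f"{path}: line {i}: bad position {row.position_cM!r}") from exc
        fam = None if row.family_id in ("", _NA) else row.family_id
        loci.append(
            GeneLocus(row.locus_id, row.gene_id, row.chromosome, pos, fam,
                      row.species or "focal")
        )
    if lengths is None:
        lengths = {}
        for l in loci:
            lengths[l.chromosome] = max(lengths.get(l.chromosome, 0.0), l.position)
        lengths = {c: (v if v > 0 else 1.0) for c, v in lengths.items()}
    return GeneticMap(lengths=dict(lengths), loci=loci)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write a map to the TSV dialect read by :func:`load_map`."""
    rows = [
        (l.locus_id, l.gene_id, l.chromosome, repr(l.position),
         l.family_id if l.family_id is not None else _NA, l.species)
        for l in gmap.loci
    ]
    pd.DataFrame(rows, columns=MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def write_lengths(gmap: GeneticMap, path: str | Path) -> None:
    pd.DataFrame(
        {"chromosome": list(gmap.lengths), "length_cM": list(gmap.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def load_lengths(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return dict(zip(df["chromosome"], df["length_cM"].astype(float)))


# ---------------------------------------------------------------------
# Composite-map locus transfer
# ---------------------------------------------------------------------

def transfer_donor_loci(
    reference: GeneticMap,
    donor: GeneticMap,
    anchors: Iterable[str] | None = None,
) -> GeneticMap:
    """Transfer donor-only loci onto a reference map by anchor midpoints.

    Anchor loci are genes mapped on both maps (shared ``gene_id``; the
    set may be restricted with ``anchors``).  A donor locus absent from
    the reference is placed at the midpoint of the cM interval between
    its two flanking anchors *on the reference map*; its flanking anchors
    are the nearest anchors below and above it in donor coordinates.  A
    donor locus lying exactly on an anchor position takes that anchor's
    reference position.  Donor loci outside the anchor span are skipped
    with a logged warning — extrapolation beyond the aligned interval is
    not defined.

    Raises
    ------
    MapError
        If a donor chromosome's anchors are not order-consistent with
        the reference (an inverted interval), or has fewer than 2 anchors
        while carrying transferable loci.
    """
    ref_by_gene = {l.gene_id: l for l in reference.loci}
    donor_genes = {l.gene_id for l in donor.loci}
    anchor_ids = donor_genes & set(ref_by_gene)
    if anchors is not None:
        anchor_ids &= set(anchors)

    new_loci = list(reference.loci)
    existing_ids = {l.locus_id for l in reference.loci}
    n_transferred = 0
    for chrom in donor.chromosomes:
        chrom_loci = donor.loci_on(chrom)
        chrom_anchors = [l for l in chrom_loci if l.gene_id in anchor_ids]
        to_transfer = [
            l for l in chrom_loci
            if l.gene_id not in anchor_ids and l.gene_id not in ref_by_gene
        ]
        if not to_transfer:
            continue
        if len(chrom_anchors) < 2:
            raise MapError(
                f"donor chromosome {chrom!r}: fewer than 2 anchors for "
                f"{len(to_transfer)} transferable loci"
            )
        # order consistency: reference positions must be monotone along
        # the donor ordering and stay on one reference chromosome
        ref_anchor = [ref_by_gene[a.gene_id] for a in chrom_anchors]
        ref_chroms = {a.chromosome for a in ref_anchor}
        if len(ref_chroms) != 1:
            raise MapError(
                f"donor chromosome {chrom!r}: anchors map to several reference "
                f"chromosomes {sorted(ref_chroms)}"
            )
        ref_pos = [a.position for a in ref_anchor]
        increasing = all(ref_pos[i] <= ref_pos[i + 1] for i in range(len(ref_pos) - 1))
        decreasing = all(ref_pos[i] >= ref_pos[i + 1] for i in range(len(ref_pos) - 1))
        if not (increasing or decreasing):
            raise MapError(f"donor chromosome {chrom!r}: anchor order conflict with reference")

        donor_pos = [a.position for a in chrom_anchors]
        for locus in to_transfer:
            if locus.position < donor_pos[0] or locus.position > donor_pos[-1]:
                logger.warning(
                    "donor locus %s at %.2f cM outside anchor span [%.2f, %.2f] on %s; skipped",
                    locus.locus_id, locus.position, donor_pos[0], donor_pos[-1], chrom,
                )
                continue
            # flanking anchors in donor coordinates
            hi = next(i for i, p in enumerate(donor_pos) if p >= locus.position)
            if donor_pos[hi] == locus.position:
                new_pos = ref_pos[hi]
            else:
                lo = hi - 1
                new_pos = 0.5 * (ref_pos[lo] + ref_pos[hi])
            locus_id = locus.locus_id
            if locus_id in existing_ids:
                locus_id = f"{locus_id}:transferred"
            placed = replace(
                locus,
                locus_id=locus_id,
                chromosome=ref_anchor[0].chromosome,
                position=float(new_pos),
            )
            new_loci.append(placed)
            existing_ids.add(locus_id)
            n_transferred += 1
    logger.info("transferred %d donor loci onto reference map", n_transferred)
    return GeneticMap(lengths=dict(reference.lengths), loci=new_loci)


# ---------------------------------------------------------------------
# Co-localization
# ---------------------------------------------------------------------

@dataclass
class ColocGroup:
    """A maximal group of >= 2 loci within ``epsilon`` cM of each other."""

    chromosome: str
    loci: list[GeneLocus]
    relation: str = "unrelated"  # same-family | functionally-related | unrelated

    @property
    def positions(self) -> list[float]:
        return [l.position for l in self.loci]


def colocalized_groups(
    gmap: GeneticMap,
    epsilon: float = 0.0,
    terms: "dict[str, set[str]] | None" = None,
) -> list[ColocGroup]:
    """Maximal groups of loci whose pairwise cM differences are <= epsilon.

    With the default ``epsilon = 0`` groups are exact position ties —
    the zero-recombinant clusters of a mapping population — and form a
    partition of the tied loci.  With ``epsilon > 0`` maximal windows
    may overlap; every reported group is non-extendable.

    When a ``terms`` table (gene id -> set of term labels) is supplied,
    each group is annotated ``same-family`` (all members share a family
    id), ``functionally-related`` (not same-family but all members share
    at least one term), or ``unrelated``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    groups: list[ColocGroup] = []
    for chrom in gmap.chromosomes:
        loci = gmap.loci_on(chrom)
        n = len(loci)
        prev_end = -1
        for i in range(n):
            j = i
            while j + 1 < n and loci[j + 1].position - loci[i].position <= epsilon:
                j += 1
            if j > i and j > prev_end:  # size >= 2, not nested in previous window
                members = loci[i : j + 1]
                groups.append(ColocGroup(chrom, members, _relation(members, terms)))
                prev_end = j
    return groups


def _relation(members: Sequence[GeneLocus], terms: dict[str, set[str]] | None) -> str:
    fams = {l.family_id for l in members}
    if None not in fams and len(fams) == 1:
        return "same-family"
    if terms is not None:
        shared = None
        for l in members:
            t = terms.get(l.gene_id, set())
            shared = set(t) if shared is None else shared & t
        if shared:
            return "functionally-related"
    return "unrelated"
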