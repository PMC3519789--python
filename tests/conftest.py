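import pytest

from macromap.map import GeneLocus, GeneticMap


@pytest.fixture
def toy_map() -> GeneticMap:
    """Three loci on one 100 cM chromosome, two of them tied in position."""
    return GeneticMap(
        lengths={"1": 100.0},
        loci=[
            GeneLocus("L1", "g1", "1", 12.3, "famA"),
            GeneLocus("L2", "g2", "1", 12.3, "famA"),
            GeneLocus("L3", "g3", "1", 40.0),
        ],
    )


def make_map(positions_by_chrom: dict[str, list[float]],
             lengths: dict[str, float],
             families: dict[str, str] | None = None) -> GeneticMap:
    """Build a map from per-chromosome position lists; families by locus id."""
    loci = []
    i = 0
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            i += 1
            lid = f"L{i:04d}"
            fam = (families or {}).get(lid)
            loci.append(GeneLocus(lid, f"g{i:04d}", chrom, p, fam))
    return GeneticMap(lengths=lengths, loci=loci)
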