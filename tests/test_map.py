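"""Map model: TSV round trip, validation, locus transfer, co-localization."""

import numpy as np
import pytest

from macromap.map import (GeneLocus, GeneticMap, MapError, colocalized_groups,
                          load_map, transfer_donor_loci, write_map)
from macromap.simulate import ScenarioConfig, simulate_map


def random_map(seed: int, n: int = 50) -> GeneticMap:
    rng = np.random.default_rng(seed)
    lengths = {str(c): 100.0 + 10.0 * c for c in range(1, 5)}
    chroms = list(lengths)
    loci = [
        GeneLocus(
            f"L{i:03d}", f"g{i:03d}",
            chroms[rng.integers(len(chroms))],
            float(rng.uniform(0, 100)),
            f"fam{rng.integers(5)}" if rng.random() < 0.5 else None,
        )
        for i in range(n)
    ]
    return GeneticMap(lengths=lengths, loci=loci)


class TestRoundTrip:
    def test_toy_tsv_loads_three_loci(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text(
            "locus_id\tgene_id\tchromosome\tposition_cM\tfamily_id\tspecies\n"
            "L1\tg1\t1\t10.0\tfamA\tfocal\n"
            "L2\tg2\t1\t20.5\t.\tfocal\n"
            "L3\tg3\t1\t99.0\t.\tfocal\n"
        )
        gmap = load_map(p, lengths={"1": 100.0})
        assert len(gmap) == 3
        assert gmap.counts() == {"1": 3}
        assert gmap.locus("L1").family_id == "famA"
        assert gmap.locus("L2").family_id is None

    def test_write_then_load_is_identity(self, tmp_path):
        gmap = random_map(seed=1)
        p = tmp_path / "m.tsv"
        write_map(gmap, p)
        assert load_map(p, lengths=gmap.lengths) == gmap

    def test_position_beyond_length_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "locus_id\tgene_id\tchromosome\tposition_cM\tfamily_id\tspecies\n"
            "L1\tg1\t1\t120.0\t.\tfocal\n"
        )
        with pytest.raises(MapError, match="outside"):
            load_map(p, lengths={"1": 100.0})

    def test_malformed_position_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "locus_id\tgene_id\tchromosome\tposition_cM\tfamily_id\tspecies\n"
            "L1\tg1\t1\t10.0\t.\tfocal\n"
            "L2\tg2\t1\tnot-a-number\t.\tfocal\n"
        )
        with pytest.raises(MapError, match="line 3"):
            load_map(p, lengths={"1": 100.0})

    def test_duplicate_locus_id_rejected(self):
        with pytest.raises(MapError, match="duplicate"):
            GeneticMap(
                lengths={"1": 100.0},
                loci=[GeneLocus("L1", "a", "1", 1.0), GeneLocus("L1", "b", "1", 2.0)],
            )


class TestTransfer:
    @staticmethod
    def _maps(donor_pos, anchor_ref=(10.0, 20.0), anchor_donor=(5.0, 9.0)):
        ref = GeneticMap(
            lengths={"1": 100.0},
            loci=[GeneLocus("R1", "anc1", "1", anchor_ref[0]),
                  GeneLocus("R2", "anc2", "1", anchor_ref[1])],
        )
        donor = GeneticMap(
            lengths={"d1": 50.0},
            loci=[GeneLocus("D1", "anc1", "d1", anchor_donor[0], species="donor"),
                  GeneLocus("D2", "anc2", "d1", anchor_donor[1], species="donor"),
                  GeneLocus("D3", "new1", "d1", donor_pos, species="donor")],
        )
        return ref, donor

    def test_midpoint_placement(self):
        ref, donor = self._maps(donor_pos=7.0)
        merged = transfer_donor_loci(ref, donor)
        placed = merged.locus("D3")
        assert placed.position == 15.0
        assert placed.chromosome == "1"
        assert placed.species == "donor"

    def test_locus_on_anchor_takes_anchor_position(self):
        ref, donor = self._maps(donor_pos=5.0)
        merged = transfer_donor_loci(ref, donor)
        assert merged.locus("D3").position == 10.0

    def test_reference_loci_unchanged_and_inside_interval(self):
        ref, donor = self._maps(donor_pos=8.5)
        merged = transfer_donor_loci(ref, donor)
        for l in ref.loci:
            assert merged.locus(l.locus_id) == l
        placed = merged.locus("D3")
        assert 10.0 <= placed.position <= 20.0

    def test_outside_span_skipped_with_warning(self, caplog):
        ref, donor = self._maps(donor_pos=40.0)
        with caplog.at_level("WARNING", logger="macromap.map"):
            merged = transfer_donor_loci(ref, donor)
        assert len(merged) == len(ref)
        assert "outside anchor span" in caplog.text

    def test_anchor_order_conflict_raises(self):
        ref = GeneticMap(
            lengths={"1": 100.0},
            loci=[GeneLocus("R1", "anc1", "1", 10.0),
                  GeneLocus("R2", "anc2", "1", 30.0),
                  GeneLocus("R3", "anc3", "1", 20.0)],
        )
        donor = GeneticMap(
            lengths={"d1": 50.0},
            loci=[GeneLocus("D1", "anc1", "d1", 5.0),
                  GeneLocus("D2", "anc2", "d1", 10.0),
                  GeneLocus("D3", "anc3", "d1", 15.0),
                  GeneLocus("D4", "new1", "d1", 7.0)],
        )
        with pytest.raises(MapError, match="order conflict"):
            transfer_donor_loci(ref, donor)

    def test_simulated_donor_loci_all_transferred(self):
        """58 donor-only loci inside anchor spans all transfer (count oracle)."""
        rng = np.random.default_rng(7)
        lengths = {"1": 120.0}
        ref_loci = [GeneLocus(f"R{i}", f"anc{i}", "1", float(p))
                    for i, p in enumerate(np.linspace(0, 120, 30))]
        donor_loci = [GeneLocus(f"DA{i}", f"anc{i}", "d1", float(p), species="donor")
                      for i, p in enumerate(np.linspace(0, 60, 30))]
        extra = rng.uniform(0.5, 59.5, size=58)
        donor_loci += [GeneLocus(f"DN{i}", f"new{i}", "d1", float(p), species="donor")
                       for i, p in enumerate(extra)]
        ref = GeneticMap(lengths=lengths, loci=ref_loci)
        donor = GeneticMap(lengths={"d1": 60.0}, loci=donor_loci)
        merged = transfer_donor_loci(ref, donor)
        assert len(merged) - len(ref) == 58
        assert sum(l.species == "donor" for l in merged.loci) == 58


class TestColocalization:
    def test_exact_tie_forms_one_group(self, toy_map):
        groups = colocalized_groups(toy_map, epsilon=0.0)
        assert len(groups) == 1
        assert [l.locus_id for l in groups[0].loci] == ["L1", "L2"]
        assert groups[0].relation == "same-family"

    def test_distinct_positions_give_no_groups(self):
        gmap = GeneticMap(
            lengths={"1": 100.0},
            loci=[GeneLocus(f"L{i}", f"g{i}", "1", float(10 * i)) for i in range(1, 5)],
        )
        assert colocalized_groups(gmap, epsilon=0.0) == []

    def test_groups_are_disjoint_partition_at_epsilon_zero(self):
        gmap = GeneticMap(
            lengths={"1": 100.0},
            loci=[GeneLocus(f"L{i}", f"g{i}", "1", p)
                  for i, p in enumerate([5.0, 5.0, 5.0, 9.0, 9.0, 50.0])],
        )
        groups = colocalized_groups(gmap)
        sizes = sorted(len(g.loci) for g in groups)
        assert sizes == [2, 3]
        seen = [l.locus_id for g in groups for l in g.loci]
        assert len(seen) == len(set(seen))

    def test_generator_planted_groups_recovered(self):
        cfg = ScenarioConfig(seed=42, genes_per_chromosome=100, n_families=0,
                             n_coloc_groups=32)
        gmap, truth = simulate_map(cfg)
        assert len(truth.coloc_groups) == 32
        groups = colocalized_groups(gmap, epsilon=0.0)
        assert len(groups) == 32
        got = {frozenset(l.gene_id for l in g.loci) for g in groups}
        want = {frozenset(g) for g in truth.coloc_groups}
        assert got == want

    def test_functional_relation_annotation(self):
        gmap = GeneticMap(
            lengths={"1": 100.0},
            loci=[GeneLocus("L1", "g1", "1", 7.0, "famA"),
                  GeneLocus("L2", "g2", "1", 7.0, "famB")],
        )
        terms = {"g1": {"metabolism"}, "g2": {"metabolism", "transport"}}
        (g,) = colocalized_groups(gmap, terms=terms)
        assert g.relation == "functionally-related"
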