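"""RBH resolution, synteny assignment, collinearity, conserved segments."""

from itertools import combinations

import numpy as np
import pytest

from macromap.map import GeneLocus, GeneticMap
from macromap.simulate import ScenarioConfig, simulate_map_pair
from macromap.synteny import (HitRecord, SyntenyLink, collinearity,
                              collinearity_by_pair, conserved_segments,
                              reciprocal_best_hits, synteny_links)


def hit(q, s, ident, score=None):
    return HitRecord(q, s, ident, score if score is not None else ident * 10)


class TestRBH:
    def test_mutual_best_pair_kept(self):
        assert reciprocal_best_hits([hit("a", "b", 95)], [hit("b", "a", 95)]) \
            == [("a", "b")]

    def test_broken_reciprocity_dropped(self):
        ab = [hit("a", "b", 95)]
        ba = [hit("b", "a2", 96), hit("b", "a", 95)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_identity_threshold_filters(self):
        ab, ba = [hit("a", "b", 79.0)], [hit("b", "a", 79.0)]
        assert reciprocal_best_hits(ab, ba, min_identity=80.0) == []
        assert reciprocal_best_hits(ab, ba, min_identity=70.0) == [("a", "b")]

    def test_symmetric_in_direction_inputs(self):
        rng = np.random.default_rng(0)
        ab, ba = [], []
        for i in range(30):
            ident = float(rng.uniform(75, 99))
            ab.append(hit(f"a{i}", f"b{i}", ident))
            ba.append(hit(f"b{i}", f"a{i}", ident))
            if rng.random() < 0.5:
                ab.append(hit(f"a{i}", f"b{(i + 3) % 30}", ident - 5))
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert {(a, b) for a, b in fwd} == {(a, b) for b, a in rev}

    def test_raising_threshold_never_adds_pairs(self):
        rng = np.random.default_rng(1)
        ab = [hit(f"a{i}", f"b{i}", float(rng.uniform(70, 100))) for i in range(40)]
        ba = [hit(h.subject, h.query, h.identity) for h in ab]
        sizes = [len(reciprocal_best_hits(ab, ba, m)) for m in (70, 80, 90, 95)]
        assert sizes == sorted(sizes, reverse=True)

    def test_deterministic_tie_break_by_subject_id(self):
        ab = [hit("a", "b2", 90.0, 900.0), hit("a", "b1", 90.0, 900.0)]
        ba = [hit("b1", "a", 90.0, 900.0), hit("b2", "a", 90.0, 900.0)]
        assert reciprocal_best_hits(ab, ba) == [("a", "b1")]


def two_maps(chrom_b_of, pos_b=None):
    """Maps with genes g1..gN on chromosome 1 of A at 10*i cM."""
    n = len(chrom_b_of)
    loci_a = [GeneLocus(f"LA{i}", f"a{i}", "1", 10.0 * i) for i in range(1, n + 1)]
    loci_b = [
        GeneLocus(f"LB{i}", f"b{i}", chrom_b_of[i - 1],
                  (pos_b[i - 1] if pos_b else 10.0 * i))
        for i in range(1, n + 1)
    ]
    chroms_b = sorted({c for c in chrom_b_of})
    map_a = GeneticMap(lengths={"1": 10.0 * n + 10}, loci=loci_a)
    map_b = GeneticMap(lengths={c: 10.0 * n + 10 for c in chroms_b}, loci=loci_b)
    pairs = [(f"a{i}", f"b{i}") for i in range(1, n + 1)]
    return map_a, map_b, pairs


class TestSyntenyLinks:
    def test_unanimous_links_fully_syntenic(self):
        map_a, map_b, pairs = two_maps(["3"] * 5)
        res = synteny_links(map_a, map_b, pairs)
        assert res.homoeology == {"1": "3"}
        assert res.pct_syntenic == 100.0

    def test_minority_link_not_syntenic(self):
        map_a, map_b, pairs = two_maps(["3"] * 9 + ["5"])
        res = synteny_links(map_a, map_b, pairs)
        assert res.homoeology == {"1": "3"}
        assert res.pct_syntenic == pytest.approx(90.0)
        assert sum(not l.syntenic for l in res.links) == 1

    def test_no_links_reports_absent_percentage(self):
        map_a, map_b, _ = two_maps(["3"])
        res = synteny_links(map_a, map_b, [])
        assert res.links == [] and res.homoeology == {}
        assert res.pct_syntenic is None


class TestCollinearity:
    @staticmethod
    def links(b_ranks):
        return [SyntenyLink(f"a{i}", f"b{i}", "1", float(i), "B1", float(r),
                            syntenic=True)
                for i, r in enumerate(b_ranks)]

    @staticmethod
    def brute_force_lnds(values):
        best = 0
        for r in range(len(values), 0, -1):
            for idx in combinations(range(len(values)), r):
                sub = [values[i] for i in idx]
                if all(x <= y for x, y in zip(sub, sub[1:])):
                    return r
        return best

    def test_known_rank_pattern(self):
        subset, pct = collinearity(self.links([1, 2, 5, 3, 4]), allow_reversed=False)
        assert len(subset) == 4 and pct == pytest.approx(80.0)

    def test_monotone_links_fully_collinear(self):
        _, pct = collinearity(self.links([1, 2, 3, 4, 5]))
        assert pct == 100.0

    def test_reversed_order_with_orientation_flag(self):
        ranks = [5, 4, 3, 2, 1]
        _, pct_fwd = collinearity(self.links(ranks), allow_reversed=False)
        _, pct_rev = collinearity(self.links(ranks), allow_reversed=True)
        assert pct_fwd == pytest.approx(20.0)
        assert pct_rev == 100.0

    def test_position_ties_treated_as_compatible(self):
        _, pct = collinearity(self.links([1, 2, 2, 2, 3]))
        assert pct == 100.0

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_exhaustive_search(self, n):
        rng = np.random.default_rng(n)
        for _ in range(15):
            ranks = list(rng.permutation(n) + 1.0)
            subset, _ = collinearity(self.links(ranks), allow_reversed=False)
            assert len(subset) == self.brute_force_lnds(ranks)


class TestConservedSegments:
    def test_coverage_arithmetic(self):
        links = [SyntenyLink(f"a{i}", f"b{i}", "1", 10.0 + 10 * i, "B1",
                             10.0 + 10 * i, True, True) for i in range(5)]
        map_a = GeneticMap(lengths={"1": 100.0}, loci=[])
        map_b = GeneticMap(lengths={"B1": 100.0}, loci=[])
        segs, cov_a, cov_b = conserved_segments(links, map_a, map_b)
        assert len(segs) == 1 and segs[0].span_a == pytest.approx(40.0)
        assert cov_a == pytest.approx(40.0) and cov_b == pytest.approx(40.0)

    def test_gap_above_cap_splits_segments(self):
        links = [SyntenyLink("a1", "b1", "1", 10.0, "B1", 10.0, True, True),
                 SyntenyLink("a2", "b2", "1", 60.0, "B1", 60.0, True, True)]
        map_a = GeneticMap(lengths={"1": 100.0}, loci=[])
        map_b = GeneticMap(lengths={"B1": 100.0}, loci=[])
        segs, cov_a, _ = conserved_segments(links, map_a, map_b, max_gap=20.0)
        assert len(segs) == 2
        assert all(s.span_a == 0.0 for s in segs)
        assert cov_a == 0.0


class TestGeneratorScenarios:
    def test_zero_rearrangements_fully_syntenic_and_collinear(self):
        cfg = ScenarioConfig(seed=17, n_shared_genes=150)
        map_a, map_b, ab, ba, _ = simulate_map_pair(cfg)
        pairs = reciprocal_best_hits(ab, ba, 80.0)
        assert len(pairs) == 150
        res = synteny_links(map_a, map_b, pairs)
        _, pct_col = collinearity_by_pair(res)
        assert res.pct_syntenic == 100.0
        assert pct_col == 100.0

    def test_decoys_below_threshold_never_in_rbh(self):
        cfg = ScenarioConfig(seed=19, n_shared_genes=100, decoy_rate=1.0,
                             decoy_identity=(70.0, 75.0))
        _, _, ab, ba, truth = simulate_map_pair(cfg)
        pairs = reciprocal_best_hits(ab, ba, 80.0)
        assert set(pairs) == set(map(tuple, truth.ortholog_pairs))

    def test_five_translocations_lower_synteny_as_constructed(self):
        fracs = []
        for seed in range(50):
            cfg = ScenarioConfig(seed=seed, n_shared_genes=150, n_translocations=5)
            map_a, map_b, ab, ba, _ = simulate_map_pair(cfg)
            res = synteny_links(map_a, map_b, reciprocal_best_hits(ab, ba))
            fracs.append(res.pct_syntenic / 100.0)
        mean = float(np.mean(fracs))
        p = 145 / 150
        sigma = float(np.sqrt(p * (1 - p) / 150 / len(fracs)))
        assert abs(mean - p) <= 3 * sigma + 0.005

    def test_synteny_decreases_with_translocation_count(self):
        means = []
        for t in range(0, 6):
            vals = []
            for seed in range(25):
                cfg = ScenarioConfig(seed=1000 + seed, n_shared_genes=150,
                                     n_translocations=t)
                map_a, map_b, ab, ba, _ = simulate_map_pair(cfg)
                res = synteny_links(map_a, map_b, reciprocal_best_hits(ab, ba))
                vals.append(res.pct_syntenic)
            means.append(float(np.mean(vals)))
        assert all(x > y for x, y in zip(means, means[1:]))
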