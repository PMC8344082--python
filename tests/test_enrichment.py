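"""Hypergeometric testing, Holm correction, kappa grouping, GMT I/O."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppinet.enrichment import (
    EnrichmentResult,
    TermAnnotation,
    enrich,
    group_terms,
    holm_adjust,
    hypergeom_pvalue,
    kappa_pairwise,
    read_gmt,
    write_gmt,
)


def exact_tail(overlap, query, term, universe, upper=True):
    """Exhaustive-enumeration oracle: sum hypergeometric point masses exactly."""
    total = math.comb(universe, query)
    lo = max(0, query + term - universe)
    hi = min(query, term)
    ks = range(overlap, hi + 1) if upper else range(lo, overlap + 1)
    mass = sum(
        Fraction(math.comb(term, k) * math.comb(universe - term, query - k), total)
        for k in ks
    )
    return float(mass)


class TestHypergeom:
    def test_full_overlap_upper_tail(self):
        # C(5,5)C(5,0)/C(10,5) = 1/252
        assert hypergeom_pvalue(5, 5, 5, 10, "upper") == pytest.approx(1 / 252)

    def test_zero_overlap_lower_tail_by_symmetry(self):
        assert hypergeom_pvalue(0, 5, 5, 10, "lower") == pytest.approx(1 / 252)

    def test_certain_event_all_sidedness(self):
        for sided in ("upper", "lower", "two"):
            assert hypergeom_pvalue(5, 5, 5, 5, sided) == 1.0

    def test_two_sided_doubles_smaller_tail(self):
        upper = hypergeom_pvalue(4, 5, 5, 20, "upper")
        assert hypergeom_pvalue(4, 5, 5, 20, "two") == pytest.approx(2 * upper)

    def test_matches_enumeration_oracle_small_universes(self):
        for universe in range(1, 16):
            for term in range(universe + 1):
                for query in range(universe + 1):
                    lo = max(0, query + term - universe)
                    for overlap in range(lo, min(query, term) + 1):
                        for sided, upper in (("upper", True), ("lower", False)):
                            expect = exact_tail(overlap, query, term, universe, upper)
                            got = hypergeom_pvalue(overlap, query, term, universe, sided)
                            assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize(
        "args",
        [(6, 5, 5, 10), (-1, 5, 5, 10), (0, 11, 5, 10), (0, 5, 5, 9)],
    )
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_pvalue(*args, "upper")


class TestHolm:
    def test_two_element_hand_example(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_three_element_hand_example(self):
        # step-down: 0.01*3=0.03; 0.02*2=0.04; 0.03*1=0.03 raised to 0.04
        assert holm_adjust([0.03, 0.02, 0.01]) == pytest.approx([0.04, 0.04, 0.03])

    def test_single_p_of_one_unchanged(self):
        assert holm_adjust([1.0]) == [1.0]

    def test_empty(self):
        assert holm_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_bounded_by_raw_and_bonferroni(self, pvals):
        adj = holm_adjust(pvals)
        m = len(pvals)
        for raw, a in zip(pvals, adj):
            assert a >= raw - 1e-15
            assert a <= min(1.0, raw * m) + 1e-12


def term(tid, genes):
    return TermAnnotation(tid, tid.lower(), frozenset(genes))


class TestKappa:
    universe = {"G1", "G2", "G3", "G4", "G5", "G6"}

    def test_identical_terms(self):
        terms = [term("A", {"G1", "G2"}), term("B", {"G1", "G2"})]
        k = kappa_pairwise(terms, self.universe)
        assert k[0, 1] == pytest.approx(1.0)

    def test_partial_overlap_hand_value(self):
        terms = [term("A", {"G1", "G2", "G3"}), term("B", {"G2", "G3", "G4"})]
        k = kappa_pairwise(terms, self.universe)
        # 2x2 table: both=2, only-A=1, only-B=1, neither=2 -> (2/3-1/2)/(1/2)
        assert k[0, 1] == pytest.approx(1 / 3)

    def test_complementary_terms(self):
        terms = [term("A", {"G1", "G2", "G3"}), term("B", {"G4", "G5", "G6"})]
        k = kappa_pairwise(terms, self.universe)
        assert k[0, 1] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(20)]
        terms = [
            term(f"T{i}", rng.choice(genes, size=rng.integers(2, 10), replace=False))
            for i in range(8)
        ]
        k = kappa_pairwise(terms, genes)
        assert np.allclose(k, k.T)
        assert np.allclose(np.diag(k), 1.0)
        assert np.all(k >= -1 - 1e-12) and np.all(k <= 1 + 1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            kappa_pairwise([term("A", {"G1"})], set())


def results_for(terms, padj):
    return [
        EnrichmentResult(t.term_id, 0, p, p, "enriched")
        for t, p in zip(terms, padj)
    ]


class TestGroupTerms:
    def test_identical_terms_grouped_disjoint_dropped(self):
        universe = {f"G{i}" for i in range(8)}
        terms = [
            term("A", {"G1", "G2", "G3"}),
            term("B", {"G1", "G2", "G3"}),
            term("C", {"G5", "G6"}),
        ]
        k = kappa_pairwise(terms, universe)
        res = results_for(terms, [0.01, 0.02, 0.03])
        groups = group_terms(k, terms, res, threshold=0.5, fusion=False)
        assert len(groups) == 1
        assert groups[0].members == {"A", "B"}
        assert groups[0].leading_term == "A"

    def test_chain_merges_to_single_group(self):
        # Kappa chain A~B, B~C above threshold, A~C below: one merged group.
        terms = [term(t, {t}) for t in ("A", "B", "C")]
        k = np.array([[1.0, 0.6, 0.1], [0.6, 1.0, 0.6], [0.1, 0.6, 1.0]])
        res = results_for(terms, [0.01, 0.02, 0.03])
        groups = group_terms(k, terms, res, threshold=0.5, fusion=False)
        assert len(groups) == 1
        assert groups[0].members == {"A", "B", "C"}

    def test_empty_input(self):
        assert group_terms(np.zeros((0, 0)), [], [], threshold=0.5) == []

    def test_fusion_keeps_one_representative_of_identical_gene_sets(self):
        universe = {f"G{i}" for i in range(6)}
        terms = [
            term("A", {"G1", "G2", "G3"}),
            term("B", {"G1", "G2", "G3"}),
            term("C", {"G1", "G2", "G4"}),
        ]
        k = kappa_pairwise(terms, universe)
        res = results_for(terms, [0.05, 0.01, 0.02])
        # kappa(B, C) = 1/3 by hand; threshold below that so the pair groups
        groups = group_terms(k, terms, res, threshold=0.3, fusion=True)
        # B wins the fusion (lower adjusted p); A never appears.
        members = set().union(*(g.members for g in groups))
        assert "A" not in members
        assert "B" in members

    def test_independent_of_term_order(self):
        universe = {f"G{i}" for i in range(10)}
        rng = np.random.default_rng(1)
        terms = [
            term(f"T{i}", rng.choice(sorted(universe), size=4, replace=False))
            for i in range(6)
        ]
        res = results_for(terms, np.linspace(0.01, 0.06, 6))
        k = kappa_pairwise(terms, universe)
        groups_fwd = group_terms(k, terms, res, threshold=0.3)
        rev = terms[::-1]
        k_rev = kappa_pairwise(rev, universe)
        groups_rev = group_terms(k_rev, rev, res[::-1], threshold=0.3)
        assert {g.members for g in groups_fwd} == {g.members for g in groups_rev}


class TestEnrichAndGmt:
    def test_enrich_flags_planted_term(self):
        universe = [f"G{i}" for i in range(50)]
        query = set(universe[:10])
        terms = [
            term("HIT", universe[:10]),
            term("BG1", universe[20:35]),
            term("BG2", universe[30:45]),
        ]
        res = enrich(query, terms, universe=universe)
        by_id = {r.term_id: r for r in res}
        # single most-extreme configuration: two-sided p = 2/C(50,10)
        assert by_id["HIT"].p_raw == pytest.approx(2 / math.comb(50, 10))
        assert by_id["HIT"].direction == "enriched"
        assert by_id["HIT"].p_adjusted <= 0.05
        assert by_id["BG1"].p_adjusted > 0.05

    def test_gmt_round_trip(self, tmp_path):
        terms = [term("T1", {"A", "B"}), term("T2", {"C"})]
        path = tmp_path / "sets.gmt"
        write_gmt(terms, path)
        back = read_gmt(path)
        assert back == terms

    def test_gmt_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("T1\tx\tA\nT1\ty\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)
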