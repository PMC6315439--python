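"""Over-representation statistics against enumeration oracles."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from prometa import (
    GeneSetCollection,
    bh_adjust,
    binomial_upper_tail,
    ease_score,
    enrich,
    hypergeom_upper_tail,
    merge_redundant_terms,
    read_gmt,
)
from prometa.enrichment import EnrichmentRecord


def hypergeom_oracle(k, K, n, N):
    """P(overlap >= k) by exhaustive enumeration of n-draws from N."""
    population = range(N)
    term = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def binomial_oracle(k, n, q):
    """P(successes >= k) by summing the pmf exactly (Fractions of q powers)."""
    return sum(math.comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1))


class TestHypergeomTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_small_enumerations(self):
        # K=2, n=2, N=4: one of C(4,2)=6 draws contains both members
        assert hypergeom_upper_tail(2, 2, 2, 4) == pytest.approx(1 / 6)
        assert hypergeom_upper_tail(1, 2, 2, 4) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("N", range(2, 13))
    def test_matches_enumeration_all_margins(self, N):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(n, K) + 1):
                    assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                        hypergeom_oracle(k, K, n, N), abs=1e-12
                    ), (k, K, n, N)

    def test_bounds_violations(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 5, 10)

    def test_large_margins_stay_finite_and_monotone(self):
        # log-space evaluation keeps big backgrounds stable
        previous = 1.0
        for k in range(0, 50, 5):
            p = hypergeom_upper_tail(k, 400, 120, 100_000)
            assert 0.0 <= p <= previous
            previous = p


class TestEaseScore:
    def test_single_gene_overlap_is_uninformative(self):
        assert ease_score(1, 5, 3, 20) == 1.0

    def test_equals_tail_at_k_minus_one(self):
        assert ease_score(2, 2, 2, 4) == pytest.approx(5 / 6)
        assert ease_score(3, 4, 5, 12) == pytest.approx(hypergeom_upper_tail(2, 4, 5, 12))

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError):
            ease_score(0, 2, 2, 4)

    @given(st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_never_less_than_plain_tail(self, data):
        N = data.draw(st.integers(2, 40))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(1, min(n, K)))
        assert ease_score(k, K, n, N) >= hypergeom_upper_tail(k, K, n, N) - 1e-12


class TestBinomialTail:
    def test_degenerate_cases(self):
        assert binomial_upper_tail(0, 5, 0.3) == 1.0
        assert binomial_upper_tail(5, 5, 1.0) == 1.0

    def test_symmetric_half(self):
        # 4 of 8 equiprobable length-3 outcomes have >= 2 successes
        assert binomial_upper_tail(2, 3, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", range(1, 13))
    @pytest.mark.parametrize("q", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_matches_exact_sum(self, n, q):
        for k in range(0, n + 1):
            assert binomial_upper_tail(k, n, q) == pytest.approx(
                binomial_oracle(k, n, q), abs=1e-12
            )

    def test_bounds(self):
        with pytest.raises(ValueError):
            binomial_upper_tail(4, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_upper_tail(1, 3, 1.5)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_computed_step_up(self):
        # sorted p: .01, .03, .04 -> p*m/j: .03, .045, .04 -> running min from the
        # top: .03, .04, .04; reported in input order
        assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_clipped_at_one(self):
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_empty(self):
        assert bh_adjust([]) == []

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=5))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_step_up_definition(self, ps):
        """adjusted_(i) = min_{j>=i} p_(j) * m / j, in input order."""
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        expected = [0.0] * m
        running = math.inf
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, ps[idx] * m / rank)
            expected[idx] = min(1.0, running)
        got = bh_adjust(ps)
        assert got == pytest.approx(expected, abs=1e-12)
        assert all(g >= p - 1e-12 for g, p in zip(got, ps))


class TestReadGmt:
    def test_parse_and_set_semantics(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text(
            "GO:0005576\textracellular\tCALR\tSOD1\n"
            "GO:0000001\tdup members\tCALR\tCALR\n"
        )
        coll = read_gmt(path)
        assert coll.terms["GO:0005576"][1] == {"CALR", "SOD1"}
        assert coll.terms["GO:0000001"][1] == {"CALR"}
        assert coll.background == {"CALR", "SOD1"}

    def test_two_field_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GO:1\tonly description\n")
        with pytest.raises(ValueError, match=">= 3 fields"):
            read_gmt(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            read_gmt(path)

    def test_explicit_background_restricts_terms(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\td\tA\tB\tC\n")
        coll = read_gmt(path, background=["A", "B", "D"])
        assert coll.terms["T1"][1] == {"A", "B"}
        assert coll.background == {"A", "B", "D"}


class TestEnrich:
    def collection(self):
        background = frozenset(f"G{i}" for i in range(20)) | {"CALR", "SOD1", "VIM"}
        terms = {
            "T_HIT": ("query-loaded term", frozenset({"CALR", "SOD1", "VIM", "G0"})),
            "T_TINY": ("overlaps in two", frozenset({"CALR", "SOD1", "G1", "G2"})),
            "T_BG": ("background term", frozenset(f"G{i}" for i in range(15))),
        }
        return GeneSetCollection(name="toy", terms=terms, background=background)

    def test_full_containment_k_equals_n(self, tmp_path):
        symbols = ["CALR", "SOD1", "VIM", "ALDOA", "GAPDH"]
        gmt = tmp_path / "ev.gmt"
        gmt.write_text(
            "EV\textracellular vesicle\t" + "\t".join(symbols + ["OTHER1", "OTHER2"]) + "\n"
            "BG\tbackground filler\t" + "\t".join(f"B{i}" for i in range(30)) + "\n"
        )
        coll = read_gmt(gmt)
        records = enrich(symbols, coll, method="hypergeometric", min_term_overlap=3)
        (rec,) = records
        assert rec.term_id == "EV" and rec.k == rec.n == len(symbols)

    def test_min_overlap_gate_excludes_term_from_testing(self):
        records = enrich(
            ["CALR", "SOD1", "G5"], self.collection(),
            min_term_overlap=3, alpha=1.0,
        )
        assert "T_TINY" not in {r.term_id for r in records}  # k=2 < 3, never tested

    def test_bh_runs_across_tested_terms_only(self):
        records = enrich(["CALR", "SOD1", "VIM", "G0"], self.collection(),
                         min_term_overlap=3, alpha=1.0)
        assert {r.term_id for r in records} == {"T_HIT"}
        (rec,) = records
        assert rec.p_adjusted == pytest.approx(rec.p_raw)  # m = 1

    def test_query_outside_background_warns_then_errors_when_empty(self):
        with pytest.warns(UserWarning):
            enrich(["CALR", "NOT_A_GENE"], self.collection(), alpha=1.0, min_term_overlap=1)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            enrich(["NOT_A_GENE"], self.collection())

    def test_binomial_mode_filters_on_adjusted(self):
        coll = self.collection()
        raw_filtered = enrich(["CALR", "SOD1", "VIM"], coll, method="binomial",
                              min_term_overlap=3, alpha=1.0)
        for rec in raw_filtered:
            assert rec.method == "binomial"
            assert rec.p_adjusted >= rec.p_raw - 1e-15

    def test_empty_collection_like_query_gives_empty_result(self):
        records = enrich(["G0", "G1"], self.collection(), min_term_overlap=3)
        assert records == []


class TestMergeRedundantTerms:
    def rec(self, term_id, name, p, overlap):
        return EnrichmentRecord(
            term_id=term_id, term_name=name, k=len(overlap), n=5, K=10, N=100,
            p_raw=p, p_adjusted=p, method="hypergeometric",
            overlap_symbols=sorted(overlap),
        )

    def test_identical_overlaps_merge_keeping_smallest_p(self):
        a = self.rec("T1", "response to oxidative stress", 0.02, {"SOD1", "PRDX2", "CALR"})
        b = self.rec("T2", "removal of superoxide radicals", 0.01, {"SOD1", "PRDX2", "CALR"})
        merged = merge_redundant_terms([a, b])
        assert len(merged) == 1
        assert merged[0].p_raw == 0.01 and merged[0].term_id == "T2"
        assert merged[0].term_name == (
            "response to oxidative stress / removal of superoxide radicals"
        )

    def test_same_p_different_overlaps_not_merged(self):
        a = self.rec("T1", "a", 0.01, {"X", "Y", "Z"})
        b = self.rec("T2", "b", 0.01, {"X", "Y", "W"})
        assert len(merge_redundant_terms([a, b])) == 2

    def test_empty_input(self):
        assert merge_redundant_terms([]) == []
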