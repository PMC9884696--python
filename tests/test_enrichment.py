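"""GMT parsing, hypergeometric tails, BH adjustment and the ORA contract."""

from __future__ import annotations

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from comorbnet import (
    AnnotationTerm,
    bh_adjust,
    hypergeom_tail,
    read_gmt,
    run_ora,
)
from oracles import exact_hypergeom_tails, stepup_bh


class TestReadGmt:
    def test_duplicate_genes_deduplicated(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tdesc\tA\tB\tA\n")
        (term,) = read_gmt(p, "BP")
        assert term.genes == {"A", "B"}
        assert term.category == "BP"

    def test_short_lines_rejected_and_logged(self, tmp_path, caplog):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tdesc\n T2\tdesc\tA\n")
        with caplog.at_level("WARNING"):
            terms = read_gmt(p, "BP")
        assert [t.term_id for t in terms] == ["T2"]
        assert "line 1" in caplog.text

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "t.gmt"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_gmt(p, "BP") == []
        assert "no terms" in caplog.text

    def test_duplicate_term_id_keeps_first(self, tmp_path, caplog):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tdesc\tA\nT1\tdesc\tB\n")
        with caplog.at_level("WARNING"):
            (term,) = read_gmt(p, "BP")
        assert term.genes == {"A"}


class TestHypergeomTail:
    def test_saturated_overlap_worked_value(self):
        # drawing all 5 special genes in 5 draws from 10: 1/C(10,5)
        assert hypergeom_tail(5, 5, 5, 10) == pytest.approx(
            1 / 252, abs=1e-15
        )

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 5, 5, 10) == 1.0

    def test_complement_worked_value(self):
        assert hypergeom_tail(1, 2, 2, 4) == pytest.approx(5 / 6, abs=1e-12)

    def test_exact_agreement_small_sweep(self):
        """Exhaustive agreement with rational enumeration for N <= 25
        (the full N <= 60 sweep runs in the acceptance suite)."""
        worst = 0.0
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k, exact in enumerate(exact_hypergeom_tails(K, n, N)):
                        worst = max(
                            worst,
                            abs(hypergeom_tail(k, K, n, N) - float(exact)),
                        )
        assert worst <= 1e-12

    @pytest.mark.parametrize(
        "K,n,N", [(10, 20, 60), (5, 5, 10), (30, 30, 60)]
    )
    def test_tail_monotone_in_k(self, K, n, N):
        tails = [hypergeom_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert all(b <= a for a, b in zip(tails, tails[1:]))

    def test_matches_scipy_survival_function(self):
        # independent library cross-check at a deep tail
        assert hypergeom_tail(40, 200, 459, 3000) == pytest.approx(
            scipy.stats.hypergeom.sf(39, 3000, 200, 459), rel=1e-9
        )

    @pytest.mark.parametrize(
        "args", [(3, 2, 5, 10), (1, 11, 5, 10), (-1, 2, 2, 4), (1, 2, 11, 10)]
    )
    def test_parameter_inequalities_enforced(self, args):
        with pytest.raises(ValueError):
            hypergeom_tail(*args)


class TestBHAdjust:
    def test_hand_computed_triple(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_matches_literal_stepup_formula(self):
        ps = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.21, 0.5]
        assert bh_adjust(ps) == pytest.approx(stepup_bh(ps), abs=1e-15)

    @given(
        st.lists(
            st.floats(1e-8, 1.0, allow_nan=False, exclude_min=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200)
    def test_properties_and_statsmodels_agreement(self, ps):
        adj = bh_adjust(ps)
        # elementwise >= input, in (0, 1], rank-preserving
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(0 < a <= 1 for a in adj)
        order = sorted(range(len(ps)), key=lambda i: ps[i])
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-15
            for i in range(len(ps) - 1)
        )
        sm = multipletests(ps, method="fdr_bh")[1]
        assert adj == pytest.approx(list(sm), abs=1e-12)

    def test_order_invariance(self):
        ps = [0.04, 0.001, 0.3, 0.02]
        adj = bh_adjust(ps)
        rev = bh_adjust(ps[::-1])
        assert adj == rev[::-1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def term(tid, genes, category="BP"):
    return AnnotationTerm(tid, tid, category, frozenset(genes))


UNIVERSE = [f"G{i}" for i in range(10)]


class TestRunOra:
    def test_saturated_term_worked_value(self):
        res = run_ora(
            UNIVERSE[:5], [term("T1", UNIVERSE[:5])], UNIVERSE
        )
        (r,) = res
        assert (r.k, r.K, r.n, r.N) == (5, 5, 5, 10)
        assert r.p_value == pytest.approx(1 / 252)
        assert r.p_adjusted >= r.p_value
        assert r.significant

    def test_disjoint_term_never_flagged(self):
        res = run_ora(
            UNIVERSE[:5],
            [term("T1", UNIVERSE[5:])],
            UNIVERSE,
            min_term_size=1,
        )
        (r,) = res
        assert r.k == 0 and r.p_value == 1.0 and not r.significant

    def test_saturated_query_p_one(self):
        res = run_ora(UNIVERSE, [term("T1", UNIVERSE[:4])], UNIVERSE)
        (r,) = res
        assert r.k == r.K and r.p_value == pytest.approx(1.0)

    def test_results_sorted_by_p_then_term_id(self):
        terms = [
            term("T_b", UNIVERSE[:5]),
            term("T_a", UNIVERSE[:5]),
            term("T_weak", UNIVERSE[2:8]),
        ]
        res = run_ora(UNIVERSE[:5], terms, UNIVERSE)
        assert [r.term.term_id for r in res] == ["T_a", "T_b", "T_weak"]

    def test_adjustment_within_category(self):
        terms = [
            term("B1", UNIVERSE[:5], "BP"),
            term("P1", UNIVERSE[:5], "pathway"),
        ]
        res = run_ora(UNIVERSE[:5], terms, UNIVERSE)
        # each category holds one term, so adjusted == raw in both
        for r in res:
            assert r.p_adjusted == pytest.approx(r.p_value)

    def test_flag_count_monotone_in_alpha(self):
        terms = [term(f"T{i}", UNIVERSE[i : i + 5]) for i in range(5)]
        loose = run_ora(UNIVERSE[:5], terms, UNIVERSE, alpha=0.2)
        tight = run_ora(UNIVERSE[:5], terms, UNIVERSE, alpha=0.01)
        assert sum(r.significant for r in tight) <= sum(
            r.significant for r in loose
        )

    def test_small_terms_filtered_by_size(self):
        res = run_ora(
            UNIVERSE[:5],
            [term("tiny", UNIVERSE[:2]), term("ok", UNIVERSE[:5])],
            UNIVERSE,
        )
        assert [r.term.term_id for r in res] == ["ok"]

    def test_universe_defaults_to_term_union(self):
        terms = [term("T1", UNIVERSE[:4]), term("T2", UNIVERSE[2:6])]
        res = run_ora(UNIVERSE[:4], terms)
        assert all(r.N == 6 for r in res)

    def test_empty_query_after_restriction_rejected(self):
        with pytest.raises(ValueError):
            run_ora(["ZZZ"], [term("T1", UNIVERSE[:5])], UNIVERSE)
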