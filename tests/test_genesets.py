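"""Catalog ingestion, score filtering, union and disease intersection."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbnet import (
    GeneRecord,
    apply_source_filter,
    intersect_diseases,
    read_catalog,
    union_sources,
)
from comorbnet.genesets import CatalogParseError, write_risk_genes


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadCatalog:
    def test_symbols_are_case_normalized(self, tmp_path):
        p = write_tsv(
            tmp_path / "c.tsv",
            ["gene_symbol"],
            [["mmp2"], ["HGF"], ["il13"]],
        )
        records = read_catalog(p, "omim")
        assert [r.symbol for r in records] == ["MMP2", "HGF", "IL13"]
        assert all(r.source == "omim" for r in records)

    def test_blank_symbol_rows_are_skipped(self, tmp_path, caplog):
        rows = [["A"], ["   "], ["B"], ["C"], ["D"]]
        p = write_tsv(tmp_path / "c.tsv", ["gene_symbol"], rows)
        with caplog.at_level("INFO"):
            records = read_catalog(p, "ttd")
        assert len(records) == 4
        assert "skipped 1" in caplog.text

    def test_scores_pass_through(self, tmp_path):
        p = write_tsv(
            tmp_path / "c.tsv",
            ["gene_symbol", "relevance_score"],
            [["A", "10.5"], ["B", "3.2"]],
        )
        records = read_catalog(p, "genecards", score_column="relevance_score")
        assert [r.relevance_score for r in records] == [10.5, 3.2]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_catalog(tmp_path / "absent.tsv", "omim")

    def test_missing_symbol_column_raises(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", ["gene"], [["A"]])
        with pytest.raises(CatalogParseError, match="gene_symbol"):
            read_catalog(p, "omim")

    def test_non_numeric_score_names_line(self, tmp_path):
        p = write_tsv(
            tmp_path / "c.tsv",
            ["gene_symbol", "relevance_score"],
            [["A", "1.0"], ["B", "high"]],
        )
        with pytest.raises(CatalogParseError, match="line 3"):
            read_catalog(p, "genecards", score_column="relevance_score")


class TestSourceFilter:
    def test_boundary_is_strictly_greater(self):
        records = [
            GeneRecord("A", "gc", 10.0),
            GeneRecord("B", "gc", 10.1),
            GeneRecord("C", "gc", 25.0),
        ]
        kept = apply_source_filter(records, 10.0)
        assert [r.symbol for r in kept] == ["B", "C"]

    def test_scoreless_records_pass_unfiltered(self):
        records = [GeneRecord("A", "omim"), GeneRecord("B", "omim")]
        assert apply_source_filter(records, 10.0) == records

    def test_empty_input(self):
        assert apply_source_filter([], 10.0) == []

    @given(
        st.lists(
            st.one_of(
                st.none(), st.floats(min_value=0, max_value=100, allow_nan=False)
            ),
            max_size=20,
        )
    )
    def test_filter_is_idempotent(self, scores):
        records = [
            GeneRecord(f"G{i}", "src", s) for i, s in enumerate(scores)
        ]
        once = apply_source_filter(records, 10.0)
        assert apply_source_filter(once, 10.0) == once


class TestUnionAndIntersection:
    def test_union_records_provenance(self):
        s1 = [GeneRecord("A", "s1"), GeneRecord("B", "s1")]
        s2 = [GeneRecord("B", "s2"), GeneRecord("C", "s2")]
        ds = union_sources([("s1", s1), ("s2", s2)], "DKD")
        assert ds.genes == {"A", "B", "C"}
        assert ds.provenance["B"] == {"s1", "s2"}
        assert ds.source_counts() == {"s1": 2, "s2": 2}

    def test_empty_source_tolerated(self):
        ds = union_sources([("s1", []), ("s2", [GeneRecord("X", "s2")])], "d")
        assert ds.genes == {"X"}

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            union_sources([], "d")

    def test_intersection_counts(self):
        a = union_sources(
            [("s", [GeneRecord(g, "s") for g in ("MMP2", "HGF", "X")])], "DKD"
        )
        b = union_sources(
            [("s", [GeneRecord(g, "s") for g in ("MMP2", "HGF", "Y")])], "IBD"
        )
        risk = intersect_diseases(a, b)
        assert risk.genes == {"MMP2", "HGF"}
        assert risk.venn_counts == {
            "size_a": 3,
            "size_b": 3,
            "shared": 2,
            "only_a": 1,
            "only_b": 1,
        }
        for g in risk.genes:
            src_a, src_b = risk.per_disease_provenance[g]
            assert src_a and src_b

    def test_disjoint_sets_warn(self, caplog):
        a = union_sources([("s", [GeneRecord("A", "s")])], "d1")
        b = union_sources([("s", [GeneRecord("B", "s")])], "d2")
        with caplog.at_level("WARNING"):
            risk = intersect_diseases(a, b)
        assert risk.genes == set()
        assert "no shared genes" in caplog.text

    def test_identical_sets(self):
        a = union_sources([("s", [GeneRecord("A", "s")])], "d1")
        b = union_sources([("s", [GeneRecord("A", "s")])], "d2")
        assert intersect_diseases(a, b).genes == a.genes

    symbols = st.sets(st.sampled_from([f"G{i}" for i in range(12)]), max_size=12)

    @given(symbols, symbols)
    @settings(max_examples=200)
    def test_venn_partition_conservation_and_symmetry(self, ga, gb):
        a = union_sources([("s", [GeneRecord(g, "s") for g in ga])], "A") if ga else None
        b = union_sources([("s", [GeneRecord(g, "s") for g in gb])], "B") if gb else None
        a = a or union_sources([("s", [])], "A")
        b = b or union_sources([("s", [])], "B")
        risk = intersect_diseases(a, b)
        v = risk.venn_counts
        assert v["shared"] + v["only_a"] + v["only_b"] == len(ga | gb)
        flipped = intersect_diseases(b, a)
        assert flipped.genes == risk.genes
        assert flipped.venn_counts["size_a"] == v["size_b"]

    def test_risk_gene_tsv_round_trip(self, tmp_path):
        a = union_sources([("s1", [GeneRecord("B", "s1"), GeneRecord("A", "s1")])], "d1")
        b = union_sources([("s2", [GeneRecord("A", "s2"), GeneRecord("B", "s2")])], "d2")
        risk = intersect_diseases(a, b)
        out = tmp_path / "risk.tsv"
        write_risk_genes(risk, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "gene_symbol\tsources_disease_a\tsources_disease_b"
        assert [ln.split("\t")[0] for ln in lines[1:]] == ["A", "B"]


class TestGeneRecordInvariants:
    @pytest.mark.parametrize("bad", ["", "  ", "A B"])
    def test_invalid_symbols_rejected(self, bad):
        with pytest.raises(ValueError):
            GeneRecord(bad, "src")

    @pytest.mark.parametrize("score", [-1.0, float("nan"), float("inf")])
    def test_invalid_scores_rejected(self, score):
        with pytest.raises(ValueError):
            GeneRecord("A", "src", score)
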