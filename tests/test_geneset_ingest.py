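"""Gene-set extraction, merging and filtering."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from isovuln.geneset_ingest import (
    BiopaxParseError,
    GeneSet,
    GeneSetCatalog,
    GmtFormatError,
    filter_catalog,
    merge_catalogs,
    parse_biopax_isoenzymes,
    parse_ec_table,
    read_gmt,
    write_gmt,
)

RDF = 'xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"'
BP = 'xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#"'


def biopax(body: str) -> bytes:
    return f'<?xml version="1.0"?>\n<rdf:RDF {RDF} {BP}>\n{body}\n</rdf:RDF>'.encode()


def protein(pid: str, symbol: str) -> str:
    return f"""
  <bp:Protein rdf:ID="{pid}">
    <bp:entityReference rdf:resource="#{pid}_ref"/>
  </bp:Protein>
  <bp:ProteinReference rdf:ID="{pid}_ref">
    <bp:xref rdf:resource="#{pid}_x"/>
  </bp:ProteinReference>
  <bp:RelationshipXref rdf:ID="{pid}_x">
    <bp:db>HGNC Symbol</bp:db>
    <bp:id>{symbol}</bp:id>
  </bp:RelationshipXref>"""


def catalysis(cid: str, reaction: str, controller: str) -> str:
    return f"""
  <bp:Catalysis rdf:ID="{cid}">
    <bp:controlled rdf:resource="#{reaction}"/>
    <bp:controller rdf:resource="#{controller}"/>
  </bp:Catalysis>"""


ENOLASE_DOC = biopax(
    """
  <bp:BiochemicalReaction rdf:ID="rxn_eno">
    <bp:displayName>phosphopyruvate hydratase</bp:displayName>
  </bp:BiochemicalReaction>"""
    + "".join(protein(f"p{i}", s) for i, s in enumerate(["ENO1", "ENO2", "ENO3"]))
    + "".join(catalysis(f"c{i}", "rxn_eno", f"p{i}") for i in range(3))
)


class TestBiopax:
    def test_enolase_reaction_yields_one_three_gene_set(self):
        sets = parse_biopax_isoenzymes(ENOLASE_DOC, resource_label="REACTOME")
        assert len(sets) == 1
        assert sets[0].genes == ("ENO1", "ENO2", "ENO3")
        assert sets[0].reaction_name == "phosphopyruvate hydratase"
        assert sets[0].source == "REACTOME"

    def test_reaction_without_controller_is_skipped(self):
        doc = biopax('<bp:BiochemicalReaction rdf:ID="lonely"/>')
        assert parse_biopax_isoenzymes(doc) == []

    def test_complex_controller_contributes_member_symbols(self):
        doc = biopax(
            '<bp:BiochemicalReaction rdf:ID="rxn"/>'
            + protein("pa", "A2M")
            + protein("pb", "BMP1")
            + """
  <bp:Complex rdf:ID="cx">
    <bp:component rdf:resource="#pa"/>
    <bp:component rdf:resource="#pb"/>
  </bp:Complex>"""
            + catalysis("c0", "rxn", "cx")
        )
        sets = parse_biopax_isoenzymes(doc)
        assert len(sets) == 1
        assert set(sets[0].genes) == {"A2M", "BMP1"}

    def test_malformed_xml_reports_byte_offset(self):
        with pytest.raises(BiopaxParseError, match="byte offset"):
            parse_biopax_isoenzymes(b"<rdf:RDF><unclosed>")

    def test_dangling_reference_skipped_with_warning(self, caplog):
        doc = biopax(
            '<bp:BiochemicalReaction rdf:ID="rxn"/>'
            + protein("p0", "ENO1")
            + catalysis("c0", "rxn", "p0")
            + catalysis("c1", "rxn", "ghost_protein")
        )
        with caplog.at_level("WARNING"):
            sets = parse_biopax_isoenzymes(doc)
        assert len(sets) == 1 and sets[0].genes == ("ENO1",)
        assert any("dangling" in r.message for r in caplog.records)

    def test_non_hgnc_xrefs_are_ignored(self):
        doc = biopax(
            '<bp:BiochemicalReaction rdf:ID="rxn"/>'
            + """
  <bp:Protein rdf:ID="p0">
    <bp:xref rdf:resource="#x0"/>
  </bp:Protein>
  <bp:UnificationXref rdf:ID="x0">
    <bp:db>UniProt</bp:db>
    <bp:id>P06733</bp:id>
  </bp:UnificationXref>"""
            + catalysis("c0", "rxn", "p0")
        )
        assert parse_biopax_isoenzymes(doc) == []

    def test_matches_hand_enumerated_walk(self):
        # two reactions sharing one enzyme; expected compositions traced by
        # hand through reaction -> catalysis -> protein -> xref
        doc = biopax(
            '<bp:BiochemicalReaction rdf:ID="r1"/>'
            '<bp:BiochemicalReaction rdf:ID="r2"/>'
            + protein("pa", "GCK")
            + protein("pb", "HK1")
            + protein("pc", "HK2")
            + catalysis("c1", "r1", "pa")
            + catalysis("c2", "r1", "pb")
            + catalysis("c3", "r2", "pb")
            + catalysis("c4", "r2", "pc")
        )
        sets = {s.set_id.split(":")[1]: set(s.genes) for s in parse_biopax_isoenzymes(doc)}
        assert sets == {"r1": {"GCK", "HK1"}, "r2": {"HK1", "HK2"}}


class TestEcTable:
    def test_groups_rows_by_ec_number(self, tmp_path):
        p = tmp_path / "ec.tsv"
        p.write_text(
            "ec_number\tgene_symbol\tenzyme_name\n"
            "4.2.1.11\tENO1\tphosphopyruvate hydratase\n"
            "4.2.1.11\tENO2\t\n4.2.1.11\tENO3\t\n"
        )
        sets = parse_ec_table(p)
        assert len(sets) == 1
        assert sets[0].genes == ("ENO1", "ENO2", "ENO3")
        assert sets[0].reaction_name == "phosphopyruvate hydratase"
        assert sets[0].source == "KEGG"

    def test_empty_table_yields_no_sets(self, tmp_path):
        p = tmp_path / "ec.tsv"
        p.write_text("ec_number\tgene_symbol\n")
        assert parse_ec_table(p) == []

    def test_shared_gene_appears_in_multiple_sets(self, tmp_path):
        rows = ["1.1.1.1\tGA\n", "1.1.1.1\tSHARED\n", "2.2.2.2\tGB\n",
                "2.2.2.2\tSHARED\n", "3.3.3.3\tGC\n", "3.3.3.3\tGD\n",
                "4.4.4.4\tGE\n", "4.4.4.4\tGF\n"]
        p = tmp_path / "ec.tsv"
        p.write_text("ec_number\tgene_symbol\n" + "".join(rows))
        sets = parse_ec_table(p)
        assert len(sets) == 4
        assert sum("SHARED" in s.genes for s in sets) == 2

    def test_empty_symbol_row_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "ec.tsv"
        p.write_text("ec_number\tgene_symbol\n1.1.1.1\tGA\n1.1.1.1\t\n")
        with caplog.at_level("WARNING"):
            sets = parse_ec_table(p)
        assert sets[0].genes == ("GA",)
        assert any("dropped" in r.message for r in caplog.records)


class TestGmt:
    def test_minimal_line(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tKEGG|rxn|path\tGA\tGB\n")
        (s,) = read_gmt(p)
        assert s.genes == ("GA", "GB")
        assert (s.source, s.reaction_name, s.pathway_name) == ("KEGG", "rxn", "path")

    def test_round_trip_identity(self, tmp_path):
        sets = [
            GeneSet(f"S{i}", tuple(f"G{i}{j}" for j in range(2 + i % 3)),
                    "KEGG" if i % 2 else "REACTOME", f"rxn {i}", f"pw{i}")
            for i in range(10)
        ]
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        write_gmt(sets, p1)
        again = read_gmt(p1)
        write_gmt(again, p2)
        assert again == sets
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_gene_on_line_deduplicated_order_preserved(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\td\tGB\tGA\tGB\tGC\n")
        (s,) = read_gmt(p)
        assert s.genes == ("GB", "GA", "GC")

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S1\tdesc\tGA\nS2\tonlydesc\n")
        with pytest.raises(GmtFormatError, match=":2"):
            read_gmt(p)


class TestMergeFilter:
    def test_duplicate_composition_keeps_highest_priority_source(self):
        kegg = GeneSet("K1", ("ENO1", "ENO2", "ENO3"), "KEGG", "enolase")
        reactome = GeneSet("R1", ("ENO3", "ENO1", "ENO2"), "REACTOME", "other name")
        merged = merge_catalogs([[reactome], [kegg]])
        assert len(merged) == 1
        assert merged.sets[0].source == "KEGG"
        assert merged.sets[0].reaction_name == "enolase"

    def test_single_catalog_is_identity(self):
        sets = [GeneSet("A", ("G1", "G2"), "KEGG"), GeneSet("B", ("G3",), "KEGG")]
        assert merge_catalogs([sets]).sets == sets

    def test_five_compositions_two_duplicated(self):
        c1 = [GeneSet("a", ("G1", "G2"), "HUMANCYC"), GeneSet("b", ("G3",), "HUMANCYC")]
        c2 = [GeneSet("c", ("G2", "G1"), "REACTOME"), GeneSet("d", ("G4", "G5"), "REACTOME"),
              GeneSet("g", ("G7", "G8"), "REACTOME")]
        c3 = [GeneSet("e", ("G3",), "KEGG"), GeneSet("f", ("G6",), "KEGG")]
        merged = merge_catalogs([c1, c2, c3])
        assert len(merged) == 5
        by_comp = {s.composition: s.source for s in merged.sets}
        assert by_comp[frozenset({"G1", "G2"})] == "REACTOME"
        assert by_comp[frozenset({"G3"})] == "KEGG"

    def test_unknown_source_rejected(self):
        s = GeneSet("A", ("G1",), "USER")
        with pytest.raises(ValueError, match="priority"):
            merge_catalogs([[s]], priority=("KEGG",))

    @pytest.mark.parametrize(
        "genes,targetable,kept",
        [
            (tuple(f"G{i}" for i in range(6)), {"G0"}, False),  # size 6: out
            (("G1", "G2"), set(), False),  # nothing targetable: out
            (tuple(f"G{i}" for i in range(5)), {"G3"}, True),  # boundary 5: in
        ],
    )
    def test_size_and_targetability_filters(self, genes, targetable, kept):
        cat = GeneSetCatalog([GeneSet("S", genes, "KEGG")])
        out = filter_catalog(cat, targetable, max_set_size=5)
        assert (len(out) == 1) is kept

    @given(
        st.lists(
            st.builds(
                GeneSet,
                set_id=st.uuids().map(str),
                genes=st.lists(
                    st.sampled_from([f"G{i}" for i in range(8)]),
                    min_size=1, max_size=6, unique=True,
                ).map(tuple),
                source=st.sampled_from(["KEGG", "REACTOME", "HUMANCYC"]),
            ),
            max_size=12,
        )
    )
    def test_merge_is_idempotent_and_composition_unique(self, sets):
        merged = merge_catalogs([sets])
        comps = [s.composition for s in merged.sets]
        assert len(comps) == len(set(comps))
        assert merge_catalogs([merged.sets]).sets == merged.sets

    @given(
        st.lists(
            st.builds(
                GeneSet,
                set_id=st.uuids().map(str),
                genes=st.lists(
                    st.sampled_from([f"G{i}" for i in range(8)]),
                    min_size=1, max_size=7, unique=True,
                ).map(tuple),
                source=st.just("KEGG"),
            ),
            max_size=10,
        ),
        st.sets(st.sampled_from([f"G{i}" for i in range(8)])),
    )
    def test_filter_contract(self, sets, targetable):
        merged = merge_catalogs([sets])
        out = filter_catalog(merged, targetable, max_set_size=5)
        assert len(out) <= len(merged)
        for s in out.sets:
            assert len(s.genes) <= 5
            assert any(g in targetable for g in s.genes)
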