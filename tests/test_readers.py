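"""Parsers: GFF3+FASTA, OBO, GAF, declarative tables, publications and
the minimal reviewed-protein dialect — small inline examples plus tallies
against the synthetic bundle's manifest."""

import io
import textwrap

import pytest

from gsknet.errors import ParseError
from gsknet.graph import GenomicLocation
from gsknet.readers import (
    TableSpec,
    parse_fasta_gff3,
    parse_gaf,
    parse_obo,
    parse_publications,
    parse_tabular,
    parse_uniprot_min,
)

GFF1 = textwrap.dedent("""\
    ##gff-version 3
    chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1;Name=GENE1
    chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=g1.1;Parent=g1
    chr1\tsrc\tCDS\t100\t500\t.\t+\t0\tID=c1;Parent=g1.1
    """)


class TestFastaGff3:
    def test_single_gene_protein_encodes(self):
        g = parse_fasta_gff3(io.StringIO(GFF1),
                             io.StringIO(">g1.1\nMKV\n"), taxid="4565")
        mg = g.metagraph()
        assert mg.nodes == {"Gene": 1, "Protein": 1}
        assert mg.edges == {("Gene", "encodes", "Protein"): 1}
        gene = g.find_by_accession("g1", "ENSEMBL")[0]
        assert gene.attributes["Chromosome"] == "chr1"
        assert gene.attributes["BEGIN"] == 100
        assert gene.attributes["END"] == 500
        assert gene.attributes["TAXID"] == "4565"
        assert gene.attributes["Location"] == GenomicLocation(
            "chr1", 100, 500, "bp", "4565")
        protein = g.find_by_accession("g1.1", "ENSEMBL")[0]
        assert protein.attributes["AA"] == "MKV"
        assert protein.attributes["TAXID"] == "4565"

    def test_two_transcripts_give_two_proteins(self):
        gff = GFF1 + (
            "chr1\tsrc\tmRNA\t100\t400\t.\t+\t.\tID=g1.2;Parent=g1\n")
        fasta = ">g1.1\nMKV\n>g1.2\nMKW\n"
        g = parse_fasta_gff3(io.StringIO(gff), io.StringIO(fasta), "4565")
        mg = g.metagraph()
        assert mg.nodes == {"Gene": 1, "Protein": 2}
        assert mg.edges[("Gene", "encodes", "Protein")] == 2

    def test_orphan_fasta_id_warns_and_creates_orphan(self, caplog):
        fasta = ">g1.1\nMKV\n>lost.1\nMM\n"
        with caplog.at_level("WARNING", logger="gsknet.readers"):
            g = parse_fasta_gff3(io.StringIO(GFF1), io.StringIO(fasta),
                                 "4565")
        assert any("lost.1" in m for m in caplog.messages)
        assert g.metagraph().nodes["Protein"] == 2
        assert g.metagraph().edges[("Gene", "encodes", "Protein")] == 1

    def test_malformed_line_reports_line_number(self):
        bad = GFF1 + "chr1\tonly\tthree\n"
        with pytest.raises(ParseError, match="line 5"):
            parse_fasta_gff3(io.StringIO(bad), io.StringIO(""), "4565")

    def test_fixture_tallies(self, bundle):
        out, manifest = bundle
        g = parse_fasta_gff3(out / "genome.gff3", out / "proteins.fasta",
                             "112509")
        mg = g.metagraph()
        assert mg.nodes["Gene"] == manifest.tallies["genes"]
        assert mg.nodes["Protein"] == manifest.tallies["transcripts"]
        assert mg.edges[("Gene", "encodes", "Protein")] == \
            manifest.tallies["encodes"]


MINI_OBO = textwrap.dedent("""\
    format-version: 1.2
    ontology: test

    [Term]
    id: TO:0000001
    name: root trait

    [Term]
    id: TO:0000002
    name: leaf trait
    synonym: "foliage trait" EXACT []
    is_a: TO:0000001

    [Term]
    id: TO:0000003
    name: gone
    is_obsolete: true
    """)


class TestObo:
    def test_terms_relations_and_synonyms(self):
        g = parse_obo(io.StringIO(MINI_OBO), concept_class="TO")
        assert len(g) == 2  # obsolete excluded
        mg = g.metagraph()
        assert mg.edges == {("TO", "is_a", "TO"): 1}
        leaf = g.find_by_accession("TO:0000002", "TO")[0]
        assert leaf.names == {"leaf trait": True, "foliage trait": False}

    def test_go_namespaces_select_classes(self, bundle):
        out, manifest = bundle
        g = parse_obo(out / "mini-go.obo")
        mg = g.metagraph()
        for cls, n in manifest.tallies["go_terms"].items():
            assert mg.nodes[cls] == n
        counts = {"is_a": 0, "part_of": 0, "regulates": 0}
        for (_, t, _), n in mg.edges.items():
            counts[t] += n
        assert counts["is_a"] == manifest.tallies["go_is_a"]
        assert counts["part_of"] == manifest.tallies["go_part_of"]
        assert counts["regulates"] == manifest.tallies["go_regulates"]


GAF_ROW = ("ENSEMBL\tp1\tP1\t{qual}\tGO:0000001\tREF\tIEA\t\t{aspect}\t\t\t"
           "protein\ttaxon:4565\t20160601\tGOA\t\t")


class TestGaf:
    def test_aspect_selects_relation_type(self):
        text = "!gaf-version: 2.0\n" + GAF_ROW.format(qual="", aspect="P")
        g = parse_gaf(io.StringIO(text))
        mg = g.metagraph()
        assert mg.edges == {("Protein", "participates_in", "BioProc"): 1}
        rel = next(iter(g.relations.values()))
        assert "IEA" in rel.evidence

    def test_not_qualifier_skipped(self):
        text = "!x\n" + GAF_ROW.format(qual="NOT", aspect="P")
        g = parse_gaf(io.StringIO(text))
        assert g.num_relations == 0

    def test_unknown_aspect_is_parse_error(self):
        text = GAF_ROW.format(qual="", aspect="Z")
        with pytest.raises(ParseError, match="aspect"):
            parse_gaf(io.StringIO(text))

    def test_fixture_per_aspect_tallies(self, bundle):
        out, manifest = bundle
        g = parse_gaf(out / "annotations.gaf")
        mg = g.metagraph()
        per_aspect = {"P": 0, "F": 0, "C": 0}
        rev = {"participates_in": "P", "has_function": "F",
               "located_in": "C"}
        for (_, t, _), n in mg.edges.items():
            per_aspect[rev[t]] += n
        assert per_aspect == manifest.tallies["gaf_relations"]


SNP_SPEC = TableSpec.from_dict({
    "source_id": "ENSEMBL",
    "subject": {
        "class": "Gene",
        "accessions": [{"namespace": "ENSEMBL", "column": "gene_id"}],
    },
    "object": {
        "class": "SNP",
        "accessions": [{"namespace": "ENSEMBL", "column": "snp_id"}],
        "attributes": {"chrom": "Chromosome", "pos": "BEGIN"},
    },
    "relation": {"type": "has_variance"},
})


class TestTabular:
    def test_gene_snp_has_variance_network(self):
        table = ("gene_id\tsnp_id\tchrom\tpos\n"
                 "g1\ts1\tchr1\t100\n"
                 "g1\ts2\tchr1\t200\n"
                 "g1\ts3\tchr2\t300\n")
        g = parse_tabular(io.StringIO(table), SNP_SPEC)
        mg = g.metagraph()
        assert mg.nodes == {"Gene": 1, "SNP": 3}  # subject merged on accession
        assert mg.edges == {("Gene", "has_variance", "SNP"): 3}
        snp = g.find_by_accession("s2", "ENSEMBL")[0]
        assert snp.attributes["BEGIN"] == 200

    def test_popseq_style_cm_attribute(self):
        spec = TableSpec.from_dict({
            "source_id": "POPSEQ",
            "taxid": "4565",
            "subject": {
                "class": "Gene",
                "accessions": [{"namespace": "ENSEMBL", "column": "gene_id"}],
                "locations": [{
                    "attribute": "Location_cM",
                    "chromosome": {"column": "chromosome"},
                    "begin": {"column": "cm"},
                    "unit": {"const": "cM"},
                }],
            },
        })
        table = "gene_id\tchromosome\tcm\ng1\t5H\t48.2\n"
        g = parse_tabular(io.StringIO(table), spec)
        gene = g.find_by_accession("g1", "ENSEMBL")[0]
        assert gene.attributes["Location_cM"] == GenomicLocation(
            "5H", 48.2, 48.2, "cM", "4565")

    def test_empty_accession_cell_skips_row(self, caplog):
        table = "gene_id\tsnp_id\tchrom\tpos\n\ts1\tchr1\t1\ng2\ts2\tchr1\t2\n"
        with caplog.at_level("WARNING", logger="gsknet.readers"):
            g = parse_tabular(io.StringIO(table), SNP_SPEC)
        assert g.metagraph().nodes["Gene"] == 1
        assert any("skipped" in m for m in caplog.messages)


class TestPublications:
    def test_xml_record(self):
        xml = ("<PubmedArticleSet><PubmedArticle><MedlineCitation>"
               "<PMID>22251317</PMID><Article>"
               "<ArticleTitle>T</ArticleTitle>"
               "<Abstract><AbstractText>Some text.</AbstractText></Abstract>"
               "</Article></MedlineCitation></PubmedArticle>"
               "</PubmedArticleSet>")
        g = parse_publications(io.StringIO(xml))
        pub = g.find_by_accession("22251317", "PMID")[0]
        assert pub.attributes["Abstract"] == "Some text."

    def test_tsv_and_empty_abstract(self):
        tsv = "pmid\ttitle\tabstract\n1\tT1\t\n1\tT1\t\n"
        g = parse_publications(io.StringIO(tsv))
        assert len(g) == 1  # duplicate PMID merged
        assert "Abstract" not in g.concepts[1].attributes

    def test_fixture_count(self, bundle):
        out, manifest = bundle
        g = parse_publications(out / "abstracts.xml")
        assert len(g) == manifest.tallies["publications"]


class TestUniprotMin:
    def test_phenotype_and_publications(self):
        tsv = ("accession\tname\ttaxid\tsequence\tgo_terms\tpmids\tphenotype\n"
               "Q1\tTTG2\t3702\tMKV\tF:GO:0003700\t22251317;15598800\t"
               "smaller seeds\n")
        g = parse_uniprot_min(io.StringIO(tsv))
        mg = g.metagraph()
        assert mg.edges[("Protein", "published_in", "Publication")] == 2
        assert mg.edges[("Protein", "has_observed_phenotype", "Phenotype")] == 1
        assert mg.edges[("Protein", "has_function", "MolFunc")] == 1
        phen = next(iter(g.concepts_of_class("Phenotype")))
        assert phen.preferred_name == "smaller seeds"

    def test_malformed_go_entry_warned_and_skipped(self, caplog):
        tsv = ("accession\tname\ttaxid\tsequence\tgo_terms\tpmids\tphenotype\n"
               "Q1\tX\t3702\tMKV\tQ:GO:1;F:GO:0003700\t\t\n")
        with caplog.at_level("WARNING", logger="gsknet.readers"):
            g = parse_uniprot_min(io.StringIO(tsv))
        assert g.num_relations == 1
        assert any("malformed GO" in m for m in caplog.messages)

    def test_fixture_go_link_tally(self, bundle):
        out, manifest = bundle
        g = parse_uniprot_min(out / "uniprot_min.tsv")
        go_links = sum(
            n for (_, t, _), n in g.metagraph().edges.items()
            if t in ("participates_in", "has_function", "located_in"))
        assert go_links == manifest.tallies["uniprot_go_links"]
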