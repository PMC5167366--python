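"""Mapping operators against brute-force oracles, and collapsing against
a union-find oracle."""

import random
from collections import Counter

import pytest

from gsknet.errors import MetaModelError
from gsknet.graph import Accession, GenomicLocation, new_graph
from gsknet.integrate import (
    accession_map,
    collapse_equal,
    colocation_map,
    external2go_map,
    name_map,
    proximity_map,
)

from conftest import random_equal_graph


def equal_pairs(g):
    return {
        tuple(sorted((r.source, r.target)))
        for r in g.relations.values() if r.relation_type == "equal"
    }


class TestAccessionMap:
    def test_shared_uniprot_accession_links_proteins(self):
        g = new_graph()
        a = g.upsert_concept("Protein", [("UNIPROT", "P0XXX1")],
                             source="ENSEMBL", merge=False)
        b = g.upsert_concept("Protein", [("UNIPROT", "P0XXX1")],
                             source="UNIPROT", merge=False)
        assert accession_map(g) == 1
        assert equal_pairs(g) == {(a, b)}

    def test_class_mismatch_is_not_mapped(self):
        g = new_graph()
        g.upsert_concept("Gene", [("ENSEMBL", "X")], source="ENSEMBL")
        g.upsert_concept("Protein", [("ENSEMBL", "X")], source="ENSEMBL")
        assert accession_map(g) == 0

    def test_ambiguous_accessions_excluded(self):
        g = new_graph()
        g.upsert_concept("Gene", [Accession("ENSEMBL", "X", True)],
                         source="ENSEMBL", merge=False)
        g.upsert_concept("Gene", [Accession("ENSEMBL", "X", True)],
                         source="ENSEMBL", merge=False)
        assert accession_map(g) == 0

    def test_random_graphs_match_all_pairs_oracle(self):
        rng = random.Random(31)
        for _ in range(20):
            g = new_graph()
            for _ in range(rng.randint(5, 30)):
                accs = [("ENSEMBL", f"A{rng.randint(1, 10)}",
                         rng.random() < 0.2)
                        for _ in range(rng.randint(0, 2))]
                g.upsert_concept(rng.choice(["Gene", "Protein"]),
                                 accessions=accs, source="ENSEMBL",
                                 merge=False)
            accession_map(g)
            # O(n^2) oracle
            expected = set()
            concepts = list(g.concepts.values())
            for i, a in enumerate(concepts):
                for b in concepts[i + 1:]:
                    if a.concept_class != b.concept_class:
                        continue
                    shared = {x.key for x in a.accessions if not x.ambiguous} \
                        & {x.key for x in b.accessions if not x.ambiguous}
                    if shared:
                        expected.add(tuple(sorted((a.id, b.id))))
            assert equal_pairs(g) == expected


class TestNameMap:
    def test_case_folding_and_min_length(self):
        g = new_graph()
        a = g.upsert_concept("Gene", names=["TTG2"], source="ENSEMBL")
        b = g.upsert_concept("Gene", names=["ttg2"], source="TAIR")
        g.upsert_concept("Gene", names=["at"], source="TAIR")
        g.upsert_concept("Gene", names=["AT"], source="ENSEMBL")
        assert name_map(g) == 1
        assert equal_pairs(g) == {(a, b)}

    def test_random_names_match_pairwise_oracle(self):
        rng = random.Random(13)
        for _ in range(15):
            g = new_graph()
            for _ in range(rng.randint(4, 25)):
                names = [f"N{rng.randint(1, 8)}{'x' * rng.randint(0, 2)}"
                         for _ in range(rng.randint(0, 3))]
                g.upsert_concept(rng.choice(["Gene", "Trait"]),
                                 names=names, source="ENSEMBL", merge=False)
            name_map(g, min_len=3)
            expected = set()
            concepts = list(g.concepts.values())
            for i, a in enumerate(concepts):
                for b in concepts[i + 1:]:
                    if a.concept_class != b.concept_class:
                        continue
                    na = {n.casefold() for n in a.names if len(n) >= 3}
                    nb = {n.casefold() for n in b.names if len(n) >= 3}
                    if na & nb:
                        expected.add(tuple(sorted((a.id, b.id))))
            assert equal_pairs(g) == expected


def _loc_concept(g, cls, chrom, begin, end, unit="bp", taxid="4565"):
    return g.upsert_concept(
        cls, attributes={"Location": GenomicLocation(chrom, begin, end,
                                                     unit, taxid)},
        source="ENSEMBL", merge=False)


class TestColocation:
    def test_contained_gene_links_to_qtl(self):
        g = new_graph()
        gene = _loc_concept(g, "Gene", "chr5", 150, 200)
        qtl = _loc_concept(g, "QTL", "chr5", 100, 300)
        assert colocation_map(g) == 1
        r = next(iter(g.relations.values()))
        assert (r.source, r.target, r.relation_type) == (gene, qtl, "colocated")

    def test_genetic_map_point_in_interval(self):
        g = new_graph()
        _loc_concept(g, "Gene", "5H", 48.2, 48.2, unit="cM")
        _loc_concept(g, "QTL", "5H", 40, 55, unit="cM")
        assert colocation_map(g) == 1

    def test_unit_mismatch_never_matches(self):
        g = new_graph()
        _loc_concept(g, "Gene", "5H", 45, 50, unit="bp")
        _loc_concept(g, "QTL", "5H", 40, 55, unit="cM")
        assert colocation_map(g) == 0

    def test_unknown_unit_is_a_validation_error(self):
        g = new_graph()
        _loc_concept(g, "Gene", "5H", 45, 50, unit="furlong")
        _loc_concept(g, "QTL", "5H", 40, 55, unit="cM")
        with pytest.raises(MetaModelError, match="unit"):
            colocation_map(g)

    def test_random_intervals_match_overlap_oracle(self):
        rng = random.Random(77)
        for _ in range(20):
            g = new_graph()
            genes, qtls = [], []
            for _ in range(rng.randint(2, 15)):
                b = rng.randint(1, 300)
                genes.append(_loc_concept(
                    g, "Gene", f"c{rng.randint(1, 3)}", b,
                    b + rng.randint(0, 60), rng.choice(["bp", "cM"])))
            for _ in range(rng.randint(1, 8)):
                b = rng.randint(1, 300)
                qtls.append(_loc_concept(
                    g, "QTL", f"c{rng.randint(1, 3)}", b,
                    b + rng.randint(10, 120), rng.choice(["bp", "cM"])))
            colocation_map(g)
            expected = set()
            for gid in genes:  # O(n*m) oracle
                gl = g.concepts[gid].attributes["Location"]
                for qid in qtls:
                    ql = g.concepts[qid].attributes["Location"]
                    if (gl.chromosome == ql.chromosome and gl.unit == ql.unit
                            and gl.taxid == ql.taxid
                            and gl.begin <= ql.end and ql.begin <= gl.end):
                        expected.add((gid, qid))
            got = {(r.source, r.target) for r in g.relations.values()
                   if r.relation_type == "colocated"}
            assert got == expected


class TestProximity:
    def test_inside_and_boundary_window(self):
        g = new_graph()
        snp = _loc_concept(g, "SNP", "chr1", 500, 500)
        _loc_concept(g, "Gene", "chr1", 400, 600)
        assert proximity_map(g, window=0) == 1
        g2 = new_graph()
        _loc_concept(g2, "SNP", "chr1", 399, 399)
        _loc_concept(g2, "Gene", "chr1", 400, 600)
        assert proximity_map(g2, window=0) == 0
        g3 = new_graph()
        _loc_concept(g3, "SNP", "chr1", 399, 399)
        _loc_concept(g3, "Gene", "chr1", 400, 600)
        assert proximity_map(g3, window=1) == 1

    def test_random_placements_match_oracle(self):
        rng = random.Random(99)
        for _ in range(20):
            g = new_graph()
            window = rng.choice([0, 5, 50])
            snps, genes = [], []
            for _ in range(rng.randint(2, 20)):
                p = rng.randint(1, 500)
                snps.append(_loc_concept(
                    g, "SNP", f"c{rng.randint(1, 3)}", p, p,
                    rng.choice(["bp", "cM"])))
            for _ in range(rng.randint(1, 10)):
                b = rng.randint(1, 500)
                genes.append(_loc_concept(
                    g, "Gene", f"c{rng.randint(1, 3)}", b,
                    b + rng.randint(10, 100), rng.choice(["bp", "cM"])))
            proximity_map(g, window=window)
            expected = set()
            for sid in snps:
                sl = g.concepts[sid].attributes["Location"]
                for gid in genes:
                    gl = g.concepts[gid].attributes["Location"]
                    if (sl.chromosome == gl.chromosome and sl.unit == gl.unit
                            and sl.taxid == gl.taxid
                            and gl.begin - window <= sl.begin <= gl.end + window):
                        expected.add((sid, gid))
            got = {(r.source, r.target) for r in g.relations.values()
                   if r.relation_type == "in_proximity"}
            assert got == expected


class TestExternal2Go:
    def test_present_and_absent_ends(self):
        g = new_graph()
        dom = g.upsert_concept("ProtDomain", [("INTERPRO", "IPR003657")],
                               source="INTERPRO")
        go = g.upsert_concept("MolFunc", [("GO", "GO:0003700")], source="GO")
        text = (
            "!comment\n"
            "InterPro:IPR003657 WRKY > GO:tf activity ; GO:0003700\n"
            "InterPro:IPR999999 Missing > GO:x ; GO:0003700\n"
            "InterPro:IPR003657 WRKY > GO:absent term ; GO:0001234\n"
            "garbled line without the arrow\n"
        )
        import io
        report = external2go_map(g, io.StringIO(text))
        assert report.relations_added == 1
        assert report.unmatched_lines == 2
        assert report.malformed_lines == 1
        r = next(iter(g.relations.values()))
        assert (r.source, r.target, r.relation_type) == (
            dom, go, "cross_reference")


class TestCollapse:
    def test_chain_collapses_to_one_with_provenance_summary(self):
        g = new_graph()
        ids = [
            g.upsert_concept("Protein", [("UNIPROT", f"P{i}")], source=s,
                             merge=False)
            for i, s in enumerate(["ENSEMBL", "UNIPROT", "TAIR"])
        ]
        g.add_relation(ids[0], ids[1], "equal")
        g.add_relation(ids[1], ids[2], "equal")
        report = collapse_equal(g)
        assert report.merged_groups == 1
        assert len(g) == 1
        rep = next(iter(g.concepts.values()))
        assert rep.provenance == {"ENSEMBL", "UNIPROT", "TAIR"}
        assert {a.value for a in rep.accessions} == {"P0", "P1", "P2"}

    def test_idempotent(self):
        rng = random.Random(55)
        g, _ = random_equal_graph(rng)
        collapse_equal(g)
        before = (len(g), g.num_relations)
        report = collapse_equal(g)
        assert report.merged_groups == 0
        assert (len(g), g.num_relations) == before

    def test_cross_class_component_rejected(self):
        g = new_graph()
        a = g.upsert_concept("Gene", source="ENSEMBL")
        b = g.upsert_concept("Protein", source="ENSEMBL")
        g.add_relation(a, b, "equal")
        report = collapse_equal(g)
        assert report.rejected_components == 1
        assert len(g) == 2  # left unmerged

    def test_partition_matches_union_find_oracle(self):
        rng = random.Random(2)
        for _ in range(20):
            g, pairs = random_equal_graph(rng)
            accessions_before = Counter(
                acc.key for c in g.concepts.values() for acc in c.accessions)
            provenance_before = {
                s for c in g.concepts.values() for s in c.provenance}
            members = set(g.concepts)
            collapse_equal(g)
            # independent union-find oracle over the logged equal pairs
            parent = {m: m for m in members}
            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x
            for a, b in pairs:
                parent[find(a)] = find(b)
            roots = {m: find(m) for m in members}
            n_groups = len(set(roots.values()))
            assert len(g) == n_groups
            # representative = smallest member of each component
            expected_ids = {min(m for m in members if roots[m] == r)
                            for r in set(roots.values())}
            assert set(g.concepts) == expected_ids
            # accession multiset conservation (values, not holders)
            accessions_after = Counter(
                acc.key for c in g.concepts.values() for acc in c.accessions)
            assert set(accessions_after) == set(accessions_before)
            # provenance entries survive as a set union
            provenance_after = {
                s for c in g.concepts.values() for s in c.provenance}
            assert provenance_after == provenance_before
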