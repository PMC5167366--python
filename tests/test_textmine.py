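"""Sentence segmentation, dictionaries and same-sentence co-occurrence
mining against a naive cross-product oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from gsknet.graph import new_graph
from gsknet.textmine import (
    TermDictionary,
    build_dictionary,
    cooccurrence_map,
    find_comentions,
    split_sentences,
    tokenize,
)


class TestSplitSentences:
    def test_basic_split(self):
        assert split_sentences("One. Two.") == ["One. ", "Two."]

    def test_abbreviation_guard(self):
        sents = split_sentences("A. thaliana grows. It flowers.")
        assert len(sents) == 2
        assert sents[0].startswith("A. thaliana")

    def test_custom_guard(self):
        assert len(split_sentences("A. B.", guards=("a.",))) == 1
        assert len(split_sentences("e.g. seeds were small. Then more.")) == 2

    @given(st.text(alphabet="abcZ .!?\n", max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_concatenation_reconstructs_text(self, text):
        assert "".join(split_sentences(text)) == text


class TestDictionary:
    def test_names_and_synonyms_enumerated(self):
        g = new_graph()
        g.upsert_concept("Gene", names=[("TTG2", True), "WRKY44"],
                         source="TAIR")
        d = build_dictionary(g, "Gene", min_len=3)
        assert set(d.entries) == {"TTG2", "WRKY44"}

    def test_min_length_filter(self):
        g = new_graph()
        g.upsert_concept("Gene", names=["at", "ABC1"], source="TAIR")
        d = build_dictionary(g, "Gene", min_len=3)
        assert set(d.entries) == {"ABC1"}

    def test_entries_match_brute_force_enumeration(self):
        rng = random.Random(4)
        g = new_graph()
        for _ in range(30):
            names = [f"n{rng.randint(1, 30):02d}{'q' * rng.randint(0, 3)}"
                     for _ in range(rng.randint(0, 3))]
            g.upsert_concept("Gene", names=names, source="TAIR", merge=False)
        d = build_dictionary(g, "Gene", min_len=4)
        expected = {}
        for c in g.concepts.values():
            for n in c.names:
                if len(n) >= 4:
                    expected.setdefault(n, set()).add(c.id)
        assert d.entries == expected

    def test_tsv_export(self):
        d = TermDictionary()
        d.add("seed width", 3)
        assert "seed width\t3" in d.to_tsv()


def _corpus_graph(records):
    """records: list of (pmid, abstract)."""
    g = new_graph()
    for pmid, abstract in records:
        g.upsert_concept("Publication", [("PMID", pmid)],
                         attributes={"Abstract": abstract}, source="PMID")
    return g


def _gene(g, name):
    return g.upsert_concept("Gene", names=[(name, True)], source="TAIR",
                            merge=False)


def _term(g, name):
    return g.upsert_concept("TO", names=[(name, True)], source="TO",
                            merge=False)


class TestCooccurrence:
    def test_same_sentence_pair_yields_one_relation(self):
        g = _corpus_graph([("1", "TTG2 controls seed size.")])
        gid, tid = _gene(g, "TTG2"), _term(g, "seed size")
        n = cooccurrence_map(g, build_dictionary(g, "Gene"),
                             build_dictionary(g, "TO", case_sensitive=False))
        assert n == 1
        rel = next(r for r in g.relations.values()
                   if r.relation_type == "cooccurs_with")
        assert (rel.source, rel.target) == (gid, tid)
        assert rel.attributes["CoCitations"] == 1
        assert rel.attributes["PMIDs"] == "1"

    def test_cross_sentence_pair_is_ignored(self):
        g = _corpus_graph([("1", "TTG2 was studied. Seed size varied.")])
        _gene(g, "TTG2"), _term(g, "seed size")
        assert cooccurrence_map(g, build_dictionary(g, "Gene"),
                                build_dictionary(g, "TO",
                                                 case_sensitive=False)) == 0

    def test_whole_token_matching(self):
        g = _corpus_graph([("1", "TTG20 affects seed size.")])
        _gene(g, "TTG2"), _term(g, "seed size")
        assert cooccurrence_map(g, build_dictionary(g, "Gene"),
                                build_dictionary(g, "TO",
                                                 case_sensitive=False)) == 0
        assert "TTG2" not in tokenize("TTG20")

    def test_gene_matching_is_case_sensitive(self):
        g = _corpus_graph([("1", "ttg2 affects seed size.")])
        _gene(g, "TTG2"), _term(g, "seed size")
        assert cooccurrence_map(g, build_dictionary(g, "Gene"),
                                build_dictionary(g, "TO",
                                                 case_sensitive=False)) == 0

    def test_cocitation_count_equals_distinct_publications(self):
        g = _corpus_graph([
            ("10", "TTG2 alters seed size."),
            ("11", "placeholder record"),  # merged into pmid 11 below
            ("11", "TTG2 reduces seed size."),
        ])
        _gene(g, "TTG2"), _term(g, "seed size")
        cooccurrence_map(g, build_dictionary(g, "Gene"),
                         build_dictionary(g, "TO", case_sensitive=False))
        rel = next(r for r in g.relations.values()
                   if r.relation_type == "cooccurs_with")
        assert rel.attributes["CoCitations"] == 2
        assert rel.attributes["PMIDs"] == "10,11"

    def test_removing_a_publication_never_increases_counts(self):
        records = [("1", "TTG2 alters seed size."),
                   ("2", "TTG2 reduces seed size."),
                   ("3", "TTG2 and seed size again.")]
        def counts(recs):
            g = _corpus_graph(recs)
            _gene(g, "TTG2"), _term(g, "seed size")
            cooccurrence_map(g, build_dictionary(g, "Gene"),
                             build_dictionary(g, "TO", case_sensitive=False))
            return {r.attributes["CoCitations"]
                    for r in g.relations.values()
                    if r.relation_type == "cooccurs_with"} or {0}
        assert max(counts(records[:-1])) <= max(counts(records))

    def test_empty_dictionary_is_noop(self):
        g = _corpus_graph([("1", "Anything at all.")])
        assert cooccurrence_map(g, TermDictionary(), TermDictionary()) == 0


def oracle_pairs(sentence_lists, genes, terms):
    """Naive per-sentence cross-product oracle over known sentences.

    genes/terms: name -> concept id.  Gene matching is case-sensitive,
    term matching casefolded; both whole-token over space-split tokens.
    """
    found = {}
    for pmid, sentences in sentence_lists:
        for sent in sentences:
            toks = [t.strip(".,;") for t in sent.split()]
            low = [t.casefold() for t in toks]
            hit_genes = [gid for name, gid in genes.items() if name in toks]
            hit_terms = []
            for name, tid in terms.items():
                ntoks = [t.casefold() for t in name.split()]
                k = len(ntoks)
                if any(low[i:i + k] == ntoks
                       for i in range(len(low) - k + 1)):
                    hit_terms.append(tid)
            for gid in hit_genes:
                for tid in hit_terms:
                    found.setdefault((gid, tid), set()).add(pmid)
    return found


def test_random_corpus_matches_cross_product_oracle():
    rng = random.Random(1234)
    fillers = ["the", "observed", "variation", "was", "consistent",
               "across", "replicates", "during", "development"]
    gene_names = [f"GENE{i}" for i in range(1, 6)]
    term_names = ["alpha beta", "gamma", "delta trait"]
    records = []
    for pmid in range(1, 41):
        sentences = []
        for _ in range(rng.randint(1, 4)):
            words = [rng.choice(fillers) for _ in range(rng.randint(3, 8))]
            if rng.random() < 0.5:
                words.insert(rng.randrange(len(words)), rng.choice(gene_names))
            if rng.random() < 0.5:
                words.insert(rng.randrange(len(words)), rng.choice(term_names))
            sentences.append(" ".join(words) + ".")
        records.append((str(pmid), sentences))
    g = _corpus_graph([(p, " ".join(s)) for p, s in records])
    genes = {n: _gene(g, n) for n in gene_names}
    terms = {n: _term(g, n) for n in term_names}
    cooccurrence_map(g, build_dictionary(g, "Gene"),
                     build_dictionary(g, "TO", case_sensitive=False))
    expected = oracle_pairs(records, genes, terms)
    got = {
        (r.source, r.target): r.attributes["CoCitations"]
        for r in g.relations.values() if r.relation_type == "cooccurs_with"
    }
    assert set(got) == set(expected)
    for pair, pubs in expected.items():
        assert got[pair] == len(pubs)
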