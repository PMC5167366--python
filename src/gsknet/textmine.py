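"""Gene-trait co-occurrence text mining over publication abstracts.

Links Gene concepts to Trait Ontology terms when a gene name and a term
surface form occur in the *same sentence* of an abstract.  Matching is
whole-token and exact (no stemming or fuzzy matching): a dictionary of
surface forms is built from concept names/synonyms, abstracts are split
into sentences by a deterministic rule-based segmenter, and every
same-sentence (gene, term) pair becomes a co-mention.  One relation per
distinct pair is created, carrying the number of distinct supporting
publications (co-citations) and their PMIDs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .graph import KnowledgeGraph

log = logging.getLogger("gsknet.textmine")

#: Abbreviations that do not end a sentence.
DEFAULT_GUARDS = (
    "e.g.", "i.e.", "cf.", "et al.", "sp.", "spp.", "subsp.", "var.",
    "fig.", "figs.", "no.", "vs.", "ca.", "approx.", "dr.", "prof.",
)

_BOUNDARY = re.compile(r"[.!?]+[)\"']*\s+")
_TOKEN = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


def split_sentences(text: str, guards: tuple[str, ...] = DEFAULT_GUARDS) -> list[str]:
    """Rule-based sentence segmentation.

    Splits after sentence-final punctuation followed by whitespace,
    unless the punctuation terminates a known abbreviation or a single
    capital initial ("A. thaliana").  The concatenation of the returned
    strings reproduces *text* exactly (separators stay attached to the
    preceding sentence).
    """
    if not text:
        return []
    sentences = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        prefix = text[start:m.end()]
        head = text[:m.start() + 1]  # up to and including the punctuation
        lowered = head.lower()
        if any(lowered.endswith(g.lower()) for g in guards):
            continue
        # single-letter initial like "A." (species abbreviations)
        if re.search(r"(?:^|\s)[A-Z]\.$", head):
            continue
        sentences.append(prefix)
        start = m.end()
    if start < len(text):
        sentences.append(text[start:])
    return sentences


def tokenize(text: str) -> list[str]:
    """Tokens are alphanumeric runs; internal hyphens kept intact."""
    return _TOKEN.findall(text)


@dataclass
class TermDictionary:
    """Surface form -> concept ids, for whole-token matching.

    Case-sensitive dictionaries match forms verbatim; case-insensitive
    ones match on the casefolded form.  Multi-word forms match as a
    contiguous token subsequence.
    """

    entries: dict[str, set[int]] = field(default_factory=dict)
    min_length: int = 3
    case_sensitive: bool = True

    def add(self, surface: str, concept_id: int) -> None:
        if len(surface) < self.min_length:
            return
        key = surface if self.case_sensitive else surface.casefold()
        self.entries.setdefault(key, set()).add(concept_id)

    def __len__(self) -> int:
        return len(self.entries)

    def match_sentence(self, sentence: str) -> Iterator[tuple[str, set[int]]]:
        """Yield (surface form, concept ids) for every entry whose token
        sequence occurs contiguously in the sentence."""
        tokens = tokenize(sentence)
        if not self.case_sensitive:
            tokens = [t.casefold() for t in tokens]
        joined = {i: tokens[i] for i in range(len(tokens))}
        for surface, cids in self.entries.items():
            stoks = tokenize(surface)
            if not stoks:
                continue
            k = len(stoks)
            for i in range(len(tokens) - k + 1):
                if tokens[i:i + k] == stoks:
                    yield surface, cids
                    break

    def to_tsv(self) -> str:
        lines = ["surface\tconcept_ids"]
        for surface in sorted(self.entries):
            ids = ",".join(str(i) for i in sorted(self.entries[surface]))
            lines.append(f"{surface}\t{ids}")
        return "\n".join(lines) + "\n"


def build_dictionary(
    g: KnowledgeGraph,
    concept_class: str,
    min_len: int = 3,
    case_sensitive: bool = True,
) -> TermDictionary:
    """Dictionary of every name/synonym of every concept of a class."""
    d = TermDictionary(min_length=min_len, case_sensitive=case_sensitive)
    for c in sorted(g.concepts_of_class(concept_class), key=lambda c: c.id):
        for name in c.names:
            d.add(name, c.id)
    return d


@dataclass(frozen=True)
class CoMention:
    gene: int
    term: int
    publication: int
    sentence_index: int


def find_comentions(
    g: KnowledgeGraph,
    gene_dict: TermDictionary,
    term_dict: TermDictionary,
    abstract_attribute: str = "Abstract",
) -> list[CoMention]:
    """All same-sentence gene/term co-mentions across publication
    abstracts, in deterministic order."""
    out: list[CoMention] = []
    for pub in sorted(g.concepts_of_class("Publication"), key=lambda c: c.id):
        abstract = pub.attributes.get(abstract_attribute)
        if not abstract:
            continue
        for si, sentence in enumerate(split_sentences(abstract)):
            genes: set[int] = set()
            for _, cids in gene_dict.match_sentence(sentence):
                genes |= cids
            if not genes:
                continue
            terms: set[int] = set()
            for _, cids in term_dict.match_sentence(sentence):
                terms |= cids
            for gid in sorted(genes):
                for tid in sorted(terms):
                    out.append(CoMention(gid, tid, pub.id, si))
    return out


def cooccurrence_map(
    g: KnowledgeGraph,
    gene_dict: TermDictionary,
    term_dict: TermDictionary,
    relation_type: str = "cooccurs_with",
) -> int:
    """Create one Gene-TO relation per distinct same-sentence co-mention
    pair, with text-mining evidence, a CoCitations attribute (number of
    distinct supporting publications) and the supporting PMIDs.

    Returns the number of relations added; empty dictionaries are a
    warned no-op.
    """
    if not gene_dict.entries or not term_dict.entries:
        log.warning("cooccurrence_map: empty dictionary; nothing to do")
        return 0
    pairs: dict[tuple[int, int], set[int]] = {}
    for cm in find_comentions(g, gene_dict, term_dict):
        pairs.setdefault((cm.gene, cm.term), set()).add(cm.publication)
    before = g.num_relations
    for (gid, tid), pubs in sorted(pairs.items()):
        pmids = sorted(
            a.value
            for pub in pubs
            for a in g.concepts[pub].accessions
            if a.namespace == "PMID"
        )
        g.add_relation(
            gid, tid, relation_type,
            attributes={"CoCitations": len(pubs), "PMIDs": ",".join(pmids)},
            data_source="INTEGRATOR", evidence=("TM",),
        )
    return g.num_relations - before
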