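# Methods

## Data model

A knowledge graph is a typed, labelled, directed multigraph.  Every
concept (node) and relation (edge) is typed against a **meta-model**: a
controlled vocabulary of concept classes, relation types, data sources,
attribute names (with value kinds `text`, `integer`, `decimal`,
`location`, `sequence`) and evidence types.  Class and relation-type
hierarchies are single-parent and acyclic; the packaged default
vocabulary (`gsknet/data/metamodel.yaml`) covers the standard
crop/reference schema — Gene, Protein, RNA, SNP, QTL, Trait, Trait
Ontology (TO), the three GO aspects, Protein Domain, Publication,
Phenotype, pathway-related classes, and relation types from `encodes`
and `ortholog` to `has_variance` and `published_in`.  Readers may extend
the vocabulary at run time with dataset-specific data sources and
evidence codes (e.g. GAF evidence codes); extensions are adopted on
graph union.

Concepts carry namespaced **accessions** (the merge keys of entity
resolution; an accession may be flagged *ambiguous*, in which case it is
annotation only and never drives merging), names (at most one
preferred), attributes, and provenance/evidence sets.  Relations are
deduplicated on the (source, target, type) triple; for relation types
declared symmetric (`equal`, `ortholog`, `paralog`,
`has_similar_sequence`, `interacts_with`) the endpoint order is
canonicalised, so (a, b) and (b, a) are one edge.  Parallel edges
between the same concepts are allowed only with distinct types.

**Upsert merging.**  Adding a concept whose non-ambiguous accession is
already held by a same-class concept enriches that concept instead of
creating a duplicate.  If the incoming accession set matches several
existing concepts, all are folded into the lowest-id one (relations
rewired) — otherwise the invariant *no two same-class concepts share a
non-ambiguous accession* could not be maintained.  Attribute conflicts
resolve last-writer-wins, with the superseded value retained in a
per-concept audit list, so merging is order-insensitive up to which
conflicting value wins, and never silently loses data.  Each parser
builds its own fresh graph, so automatic merging is scoped to one parsed
dataset; cross-dataset merging always goes through the explicit
map-and-collapse path below (`upsert_concept(..., merge=False)` opts out
entirely).

**Locations.**  Genomic locations are (chromosome, begin, end, unit,
taxid) with 1-based inclusive coordinates (GFF3 convention) and unit
`bp` or `cM`.  A concept may hold several location attributes on
different maps — e.g. a physical interval from the genome annotation
(`Location`) plus a genetic-map position from a mapping population
(`Location_cM`).  Location-based operators compare every pair of
locations and require identical (chromosome, unit, taxid): physical and
genetic coordinates never match each other, which encodes the rule that
co-location is only meaningful on a common map.  Strand is stored as an
attribute but ignored by the location operators.  No genetic↔physical
projection is attempted; QTLs mapped in cM only ever co-locate with
genes that also have cM positions.

## Integration operators

* **accession_map** — one `equal` edge per same-class pair sharing a
  non-ambiguous accession (optionally restricted to selected classes /
  namespaces).  **name_map** — the same on names normalised by
  case-folding and whitespace collapsing; names shorter than `min_len`
  (default 3) never match, because short gene symbols are too
  promiscuous.
* **sequence_map** — Smith–Waterman local alignment with affine gaps
  (BLOSUM62; gap of length L costs 10 + L, i.e. 11 to open).  Scores are
  integers.  Each query keeps at most `top_k` (default 10) subjects with
  score ≥ `min_score` (default 50); hits carry Score and Identity
  (identical / aligned columns from the traceback).  Self-hits are
  excluded; query and subject pools can be restricted by TAXID so a crop
  proteome is aligned against reference proteins only.  A raw-score
  threshold is used rather than an E-value: E-values require
  database-size calibration that adds nothing on bounded, known-size
  collections; 50 was chosen as a level random same-length peptides
  (≤ ~100 aa) essentially never reach, while a conserved ~30-residue
  block scores ≥ 140.
* **colocation_map** — Gene→QTL `colocated` edges for closed-interval
  overlap on a common map.  The relation type `colocated` is a dedicated
  vocabulary entry: QTL–Trait links use `control`, and overloading
  `control` for gene/QTL adjacency would conflate statistical control of
  a trait with physical overlap.
* **proximity_map** — SNP→Gene `in_proximity` edges when the point
  position falls within the gene interval extended by `window` (default
  0, i.e. within the gene) on both sides.
* **external2go_map** — `cross_reference` edges from a standard
  external2go file (`InterPro:IPR… name > GO:name ; GO:nnnnnnn`) between
  Protein Domain and GO concepts *already present* in the graph; lines
  with an absent end are counted as unmatched, malformed lines warned
  and skipped.
* **collapse_equal** — connected components of the `equal` subgraph
  collapse to their lowest-id member; accessions, names, attributes,
  evidence are unions, provenance becomes the union of all contributing
  data sources (the "summary of provenances"), non-`equal` relations are
  rewired to the representative and deduplicated, `equal` edges are
  removed.  The operation is idempotent and confluent (the union-find
  partition is order-independent).  A component mixing concept classes
  is rejected — reported and left unmerged — because equivalence is only
  defined within a class.  Conservation: the set of (namespace, value)
  accession pairs and the set of provenance entries in the graph are
  invariant under collapse.  (Union semantics make the per-concept
  *multiset* of provenance entries intentionally non-conserved: two
  merged concepts from the same source yield one entry.)

## Text mining

Gene–TO links are mined by same-sentence co-occurrence only — no
stemming, no fuzzy matching, no relation extraction.  Sentences are
segmented by a deterministic rule (split after `.!?` + whitespace,
guarded by a fixed abbreviation list and single-capital initials such as
"A. thaliana"); the concatenation of segments reproduces the input
exactly.  Tokens are alphanumeric runs with internal hyphens kept.
Dictionaries are built from concept names/synonyms of a class; gene
matching is case-sensitive by default (symbol case is informative: *ttg2*
the allele vs TTG2 the symbol), term matching case-insensitive.
Matching is whole-token ("TTG2" never matches inside "TTG20");
multi-word terms match as contiguous token subsequences.  One relation
(`cooccurs_with`, evidence `TM`) is created per distinct (gene, term)
pair, carrying the number of distinct supporting publications
(co-citations) and their PMIDs.  Only co-citation counting is
implemented; no further relevance scoring.

## Search

Evidence chains routinely cross relation directions (a QTL *controls* a
trait, but a gene is *colocated with* the QTL), so path queries default
to the undirected view; a per-filter direction override exists.
`neighborhood` is a bounded BFS through allowed classes/types (seeds
always included).  `shortest_path` returns the minimum-length path with
a deterministic tie-break — the lexicographically smallest concept-id
sequence, smallest relation id per hop — so results are reproducible.
`evidence_network` unions all instances of configurable meta-path
templates anchored at a gene; the defaults cover genetics
(Gene–colocated–QTL–control–Trait), annotation
(Gene–encodes–Protein–has_domain–Domain–cross_reference–GO and direct
GO annotation), homology (ortholog / similar-sequence proteins, their
phenotypes and publications), variation (in_proximity SNPs) and
text-mined TO links.  Partial template instances are included, so the
result is always a connected subgraph containing the anchor.

## Exchange formats

The XML exchange dialect is the package's own documented schema in the
spirit of graph exchange formats for this kind of tool: it embeds the
full meta-model, every concept/relation with kind-tagged attribute
values (locations as chromosome/begin/end/unit/taxid tuples), and
preserves numeric types (`48` vs `48.2`) via repr/parse round-tripping.
Element order is deterministic (ids ascending, sets sorted), so equal
graphs export byte-identically and `read(write(g))` reproduces `g`
exactly, ids included.  No compatibility with any historical tool
version is claimed.  The JSON export is plain node-link
(`nodes`/`edges`) for generic viewers and is intentionally lossy.

## Workflows

Workflows are ordered step lists (YAML primary; an XML form is accepted)
naming a plugin per step with a parameter map and named input/output
graph labels.  Validation happens before execution: unknown plugins,
missing required parameters and labels used before definition are all
rejected up front.  Execution records, per step, the concept/relation
counts before and after, the duration, the operator's return value and
any warnings (captured from the package's loggers) — the integration
log, available as text and JSON.  Builds are from-scratch by design:
re-running a workflow rebuilds the network rather than patching it,
avoiding accumulation of stale entities.  Relative paths resolve against
the workflow file's directory.  There is no incremental update mode and
no network access; inputs are local files.

## Synthetic data generator

`make_crop_fixture(seed, n_genes=30, n_qtl=6, n_snp=40, n_pubs=12)`
writes a complete miniature input bundle plus `truth.json`.  Defaults
are chosen to be the smallest sizes at which every operator has
non-trivial work (multiple chromosomes, multi-transcript genes, QTLs on
several maps, SNPs both inside and outside genes) while a full build
runs in seconds.  All randomness comes from one seeded generator, so a
seed reproduces every file byte-for-byte.

The generator emulates: a 7-chromosome crop genome with 1–2 transcripts
per gene; genetic-map (cM) positions for two-thirds of genes and all
QTLs, physical (bp) positions for genes and SNPs — exercising the
same-map rule; mini GO/TO ontologies with is_a/part_of/regulates and an
obsolete term; GAF rows over the three aspects plus a NOT-qualified row;
ortholog/domain tables; a reviewed-protein table with GO links, PMIDs
and phenotype texts; and Medline-style abstracts.  A full evidence chain
is planted: seed gene (cM 48.2 on 5H) inside two QTL intervals
(seed width, leaf water potential), encoding a protein with a WRKY
domain cross-referenced to a GO term, orthologous to a reference protein
(sharing a planted identical 30-residue block, so sequence mapping also
recovers the link) with phenotype "smaller seeds" and two publications.
One abstract contains the seed gene name and a TO term in one sentence
(positive), another separates a second gene and another term across
sentences (negative control); a third pair appears in two abstracts to
exercise co-citation counting.

Every tally in `truth.json` is known by construction (counts of written
records; overlap counts by direct arithmetic over the planted
coordinates).  Post-collapse totals that would require running the
pipeline at generation time are deliberately *not* in the manifest —
that would make the oracle circular; the planted sequence-similarity
link is asserted by membership rather than an exact hit count for the
same reason.

What the generator does **not** emulate: realistic genome statistics,
ontology topology or literature language; sequence families beyond the
single planted block; noisy or conflicting accessions; genetic↔physical
map incongruence.  Passing tests therefore demonstrate the correctness
of the integration machinery, not robustness to the messiness of real
database releases — real builds depend on release-specific identifier
hygiene that must be validated per dataset.

## Numerical and degenerate-input choices

Integer alignment scores; location overlap uses closed intervals
(adjacent intervals sharing an endpoint overlap); point features have
begin = end; empty sequences align with score 0; empty text-mining
dictionaries are a warned no-op; concept ids are opaque integers in
insertion order, making every operation deterministic under a fixed
input order.  Tie-breaks (collapse representative, shortest-path
ordering, top-k hit ordering at equal score by subject id) always prefer
the smallest id.

## Known limitations

No native parsers for UniProt XML, PSI-MI, BioPAX/KEGG or OrthoXML —
such content enters through the declarative tabular importer.  No RDF
export.  No orthology inference (ortholog tables are imported
pre-computed) and no genetic↔physical coordinate projection.  No ranked
candidate-gene scoring: searches return evidence subgraphs, not ranked
gene lists.  Text mining is co-occurrence only, with no negation
handling.  Single-writer in-memory graphs; no transactions.
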