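# gsknet — genome-scale knowledge networks for candidate-gene discovery

Most genes in crop species are poorly characterised: the evidence that
links a gene to an agronomic trait is scattered across genome
annotation, genetics databases (QTL, SNP), ontologies, homology
resources, curated protein databases and the literature.  `gsknet`
builds a **genome-scale knowledge network (GSKN)** — a typed, labelled,
directed multigraph whose nodes (*concepts*: Gene, Protein, SNP, QTL,
Trait, Trait Ontology term, Protein Domain, Publication, Phenotype, …)
and edges (*relations*: `encodes`, `ortholog`, `has_domain`, `control`,
`colocated`, `published_in`, …) are typed against a controlled
vocabulary — and mines it for gene → trait evidence chains.

The pipeline follows the classic parse / map / collapse pattern:

1. **Parse** each dataset into an independent typed network: GFF3 +
   protein FASTA (Gene–`encodes`–Protein), OBO ontologies (GO, Trait
   Ontology), GAF annotation, declarative TSV imports (QTL, SNP,
   orthologs, protein domains, genetic-map positions), Medline-style
   abstracts and a reviewed-protein table.  Concepts sharing an
   accession within one parse merge automatically.
2. **Map** equivalent or related concepts across networks:
   - *accession-based mapping* adds `equal` edges between same-class
     concepts sharing a non-ambiguous identifier;
   - *name-based mapping* does the same on normalised names/synonyms;
   - *sequence-based mapping* links proteins by Smith–Waterman local
     alignment (affine gaps, BLOSUM62, top-*k* hits per query above a
     score threshold);
   - *co-location* links a gene to every QTL whose interval overlaps it
     on the same map (chromosome, unit bp/cM and taxon must agree);
   - *proximity* links SNP positions to genes within a window;
   - *external2go* cross-references protein domains to GO terms;
   - *co-occurrence text mining* links genes to Trait Ontology terms
     that appear in the **same sentence** of an abstract.
3. **Collapse** every `equal`-connected component into one
   representative concept whose accessions, names, attributes and
   provenance are unions — no entity occurs twice, and every merged
   concept remembers all its data sources.

Querying then extracts bounded neighbourhoods, shortest evidence paths,
and meta-path based *gene-evidence networks*
(Trait–QTL–Gene–Protein–Domain–GO plus ortholog phenotypes and
publications) for any gene of interest.

Everything is reproducible: integration runs are declarative workflows
(YAML or XML) with per-step integration logs, graphs round-trip through
a lossless XML exchange format, and a deterministic synthetic-data
generator produces a complete miniature input bundle with a ground-truth
manifest — including a planted gene→trait chain modelled on the barley
seed-width discovery — so the whole pipeline is testable offline.

## Worked example

Generate the synthetic bundle, build the network, and extract the
evidence network of the planted seed gene:

```sh
$ gsknet fixture --seed 7 --out demo
wrote 15 files to demo
$ gsknet build demo/workflow.yaml --log-file demo/build.log
built graph: 154 concepts, 122 relations
$ gsknet search demo/graph.oxl --gene MLOC_10687
```

The 20-step workflow parses eleven files, merges them (220 raw
concepts), adds 78 `equal` edges by accession mapping, collapses 55
redundant groups down to 154 unique concepts, then adds 3 gene–QTL
co-location edges, 24 SNP–gene proximity edges, 1 sequence-similarity
edge, 2 domain–GO cross-references and 2 text-mined gene–trait
relations (the build log records every step).  The search prints a
17-node, 18-edge evidence network containing, among others:

```
Gene    - HvWRKY44
Protein - MLOC_10687
QTL     - AQDE021            Trait - seed width
QTL     - AQGZ019            Trait - leaf water potential
ProtDomain - WRKY domain     MolFunc - DNA-binding transcription factor activity
Protein - TTG2 (ortholog)    Phenotype - smaller seeds
Publication - 22251317       Publication - 15598800
```

i.e. the gene is co-located with two genetic-map QTLs, encodes a
WRKY-domain protein orthologous to a reference transcription factor
whose mutants have smaller seeds — a complete trait-to-gene evidence
chain, with the shortest Trait→Gene path (`seed width` ← `control` —
QTL — `colocated` ← Gene) of length 2.

The same operations are available as a library
(`gsknet.readers`, `gsknet.integrate`, `gsknet.textmine`,
`gsknet.search`, `gsknet.workflow`, `gsknet.fixtures`) and on
exchange files via `gsknet map | collapse | search | export`.

## Documentation

`docs/methods.md` describes the data model, each operator's exact
semantics and defaults, the synthetic generator, and known limitations.
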