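"""Deterministic synthetic crop + reference dataset generator.

Emits a miniature input bundle — genome annotation, protein sequences,
mini ontologies, GO annotation, genetics tables, homology/domain tables,
a reviewed-protein table, publication abstracts, an external2go mapping
and a ready-to-run workflow — together with a ground-truth manifest
(``truth.json``) whose tallies are known *by construction*, so every
pipeline stage can be verified without downloading anything.

A gene-to-trait evidence chain is planted throughout the bundle,
emulating the classic barley seed-size discovery: a seed gene on
chromosome 5H co-locates (genetic map, cM) with a seed-width QTL, encodes
a WRKY-domain protein, is orthologous to a reference transcription
factor whose mutants have smaller seeds, and co-occurs with the trait
term "seed width" in one abstract sentence.  A negative control places a
second gene and another trait term in *different* sentences of one
abstract, which same-sentence mining must ignore.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

TAXID_CROP = "112509"   # barley-like crop
TAXID_REF = "3702"      # Arabidopsis-like reference species

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Planted evidence-chain identifiers
SEED_GENE = "MLOC_10687"
SEED_TRANSCRIPT = "MLOC_10687.2"
SEED_GENE_NAME = "HvWRKY44"
SEED_ORTHOLOG = "Q0TTG2"
SEED_ORTHOLOG_NAME = "TTG2"
SEED_DOMAIN = "IPR003657"
SEED_GO = "GO:0003700"
SEED_PHENOTYPE = "smaller seeds"
SEED_PMIDS = ("22251317", "15598800")
SEED_QTL = ("AQDE021", "TR_SEED_WIDTH", "seed width", "5H", 40.0, 55.0)
SECOND_QTL = ("AQGZ019", "TR_LEAF_WP", "leaf water potential", "5H", 44.0, 60.0)
SEED_TO_TERM = "TO:0000140"

NEG_GENE_NAME = "HvDEP1"
COCIT_GENE_NAME = "HvNAM1"

#: filler vocabulary for random abstract sentences; deliberately avoids
#: every token of the planted gene names and trait-ontology terms
_FILLER = (
    "the analysis of cereal genomes revealed conserved regulatory modules",
    "transcript abundance differed between tissues under controlled conditions",
    "field experiments were replicated across three consecutive seasons",
    "marker assisted selection accelerated the breeding programme",
    "comparative mapping identified syntenic regions in related species",
    "expression profiles clustered by developmental stage",
    "candidate loci were validated in an independent mapping population",
    "the assembly was anchored to the reference using genetic markers",
)

_OTHER_TRAITS = (
    ("TR_PLANT_HEIGHT", "plant height"),
    ("TR_GRAIN_YIELD", "grain yield"),
    ("TR_DISEASE_RES", "disease resistance"),
    ("TR_FLOWERING", "flowering time"),
)

_OTHER_DOMAINS = (
    ("IPR001245", "Protein kinase domain"),
    ("IPR013083", "Zinc finger"),
)

_GO_TERMS = [
    # (id, name, namespace)
    ("GO:0048316", "seed development", "biological_process"),
    ("GO:0010214", "seed coat development", "biological_process"),
    ("GO:0009908", "flower development", "biological_process"),
    ("GO:0048580", "regulation of post-embryonic development", "biological_process"),
    ("GO:0003674", "molecular_function", "molecular_function"),
    ("GO:0003700", "DNA-binding transcription factor activity", "molecular_function"),
    ("GO:0003677", "DNA binding", "molecular_function"),
    ("GO:0005575", "cellular_component", "cellular_component"),
    ("GO:0005634", "nucleus", "cellular_component"),
]
# (child, relation, parent)
_GO_EDGES = [
    ("GO:0010214", "is_a", "GO:0048316"),
    ("GO:0009908", "is_a", "GO:0048316"),
    ("GO:0003700", "is_a", "GO:0003674"),
    ("GO:0003677", "is_a", "GO:0003674"),
    ("GO:0005634", "is_a", "GO:0005575"),
    ("GO:0010214", "part_of", "GO:0048316"),
    ("GO:0048580", "regulates", "GO:0048316"),
]

_TO_TERMS = [
    ("TO:0000001", "plant trait", None, []),
    ("TO:0000002", "seed morphology trait", "TO:0000001", []),
    ("TO:0000140", "seed width", "TO:0000002", []),
    ("TO:0000141", "seed size", "TO:0000002", []),
    ("TO:0000276", "leaf water potential", "TO:0000001", []),
    ("TO:0000207", "plant height", "TO:0000001", ["stature"]),
    ("TO:0000211", "grain yield", "TO:0000001", []),
]


@dataclass
class FixtureManifest:
    """Ground truth for the generated bundle; every tally is known by
    construction and must be reproduced by the pipeline."""

    seed: int
    parameters: dict
    tallies: dict
    planted_chain: dict
    textmine: dict
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _random_peptide(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA_ALPHABET) for _ in range(length))


def _random_pmid(rng: random.Random, taken: set[str]) -> str:
    while True:
        pmid = str(rng.randint(10_000_000, 39_999_999))
        if pmid not in taken:
            taken.add(pmid)
            return pmid


def make_crop_fixture(
    seed: int,
    n_genes: int = 30,
    n_qtl: int = 6,
    n_snp: int = 40,
    n_pubs: int = 12,
    out_dir=".",
) -> FixtureManifest:
    """Write the synthetic bundle into *out_dir* and return its manifest.

    Sizes are lower-bounded (``n_genes >= 10``, ``n_qtl >= 2``,
    ``n_pubs >= 10``) so the planted evidence chain always fits.  The
    same seed reproduces byte-identical files.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_qtl < 2:
        raise ValueError("n_qtl must be >= 2")
    if n_pubs < 10:
        raise ValueError("n_pubs must be >= 10")
    rng = random.Random(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- genes, transcripts, proteins ---------------------------------
    seed_idx = 4
    genes = []  # (gene_id, name, chrom, begin, end, [transcripts])
    cursors = {c: 1000 for c in range(1, 8)}
    multi = {1, 7} - {seed_idx}
    for i in range(n_genes):
        if i == seed_idx:
            gid, name, chrom = SEED_GENE, SEED_GENE_NAME, 5
        elif i == 2:
            gid, name, chrom = f"MLOC_{20000 + i}", NEG_GENE_NAME, rng.randint(1, 7)
        elif i == 3:
            gid, name, chrom = f"MLOC_{20000 + i}", COCIT_GENE_NAME, rng.randint(1, 7)
        else:
            gid, name, chrom = f"MLOC_{20000 + i}", f"HvG{i:03d}", rng.randint(1, 7)
        length = rng.randint(900, 3000)
        begin = cursors[chrom] + rng.randint(200, 2000)
        end = begin + length
        cursors[chrom] = end
        if i == seed_idx:
            transcripts = [SEED_TRANSCRIPT]
        else:
            k = 2 if i in multi else 1
            transcripts = [f"{gid}.{t + 1}" for t in range(k)]
        genes.append((gid, name, f"chr{chrom}H", begin, end, transcripts))

    gff_lines = ["##gff-version 3"]
    for gid, name, chrom, begin, end, transcripts in genes:
        gff_lines.append(
            f"{chrom}\tsynthetic\tgene\t{begin}\t{end}\t.\t+\t.\t"
            f"ID={gid};Name={name}"
        )
        for tid in transcripts:
            gff_lines.append(
                f"{chrom}\tsynthetic\tmRNA\t{begin}\t{end}\t.\t+\t.\t"
                f"ID={tid};Parent={gid}"
            )
            gff_lines.append(
                f"{chrom}\tsynthetic\tCDS\t{begin}\t{end}\t.\t+\t0\t"
                f"ID=cds-{tid};Parent={tid}"
            )
    (out / "genome.gff3").write_text("\n".join(gff_lines) + "\n")

    planted_block = _random_peptide(rng, 30)
    proteins: dict[str, str] = {}
    for gid, _, _, _, _, transcripts in genes:
        for tid in transcripts:
            if tid == SEED_TRANSCRIPT:
                seq = (_random_peptide(rng, 25) + planted_block
                       + _random_peptide(rng, 25))
            else:
                seq = _random_peptide(rng, rng.randint(60, 90))
            proteins[tid] = seq
    fasta = []
    for tid, seq in proteins.items():
        fasta.append(f">{tid}")
        fasta.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    (out / "proteins.fasta").write_text("\n".join(fasta) + "\n")

    # ---- POPSEQ-style genetic map positions (cM) ----------------------
    popseq = ["gene_id\tchromosome\tposition_cm"]
    gene_cm: dict[str, tuple[str, float]] = {}
    for i, (gid, _, chrom, _, _, _) in enumerate(genes):
        if i != seed_idx and i % 3 == 0:
            continue  # genes with no genetic-map position
        if i == seed_idx:
            cchrom, pos = "5H", 48.2
        else:
            cchrom = chrom[3:]  # "chr5H" -> "5H"
            pos = round(rng.uniform(0, 150), 1)
        gene_cm[gid] = (cchrom, pos)
        popseq.append(f"{gid}\t{cchrom}\t{pos}")
    (out / "popseq.tsv").write_text("\n".join(popseq) + "\n")

    # ---- QTLs and traits ----------------------------------------------
    qtls = [SEED_QTL, SECOND_QTL]
    for i in range(n_qtl - 2):
        trait_id, trait_name = _OTHER_TRAITS[i % len(_OTHER_TRAITS)]
        chrom = f"{rng.randint(1, 7)}H"
        begin = round(rng.uniform(0, 130), 1)
        end = round(begin + rng.uniform(5, 25), 1)
        qtls.append((f"AQ{rng.randint(100, 999)}X{i}", trait_id, trait_name,
                     chrom, begin, end))
    qtl_lines = ["qtl_id\ttrait_id\ttrait_name\tchromosome\tbegin\tend\tunit"]
    for qid, tid, tname, chrom, begin, end in qtls:
        qtl_lines.append(f"{qid}\t{tid}\t{tname}\t{chrom}\t{begin}\t{end}\tcM")
    (out / "qtl.tsv").write_text("\n".join(qtl_lines) + "\n")

    colocated = sum(
        1
        for gchrom, gpos in gene_cm.values()
        for _, _, _, qchrom, qbegin, qend in qtls
        if gchrom == qchrom and qbegin <= gpos <= qend
    )

    # ---- SNPs (physical bp positions) ---------------------------------
    snp_lines = ["snp_id\tchromosome\tposition"]
    snp_positions = []
    inside = n_snp // 3
    for i in range(n_snp):
        if i < inside:
            gid, _, chrom, begin, end, _ = genes[rng.randrange(n_genes)]
            pos = rng.randint(begin, end)
        else:
            chrom = f"chr{rng.randint(1, 7)}H"
            pos = rng.randint(1, max(cursors.values()) + 5000)
        snp_positions.append((chrom, pos))
        snp_lines.append(f"SNP{i + 1:04d}\t{chrom}\t{pos}")
    (out / "snp.tsv").write_text("\n".join(snp_lines) + "\n")
    in_proximity = sum(
        1
        for schrom, spos in snp_positions
        for _, _, gchrom, gbegin, gend, _ in genes
        if schrom == gchrom and gbegin <= spos <= gend
    )

    # ---- mini ontologies ----------------------------------------------
    go_lines = ["format-version: 1.2", "ontology: mini-go", ""]
    for go_id, name, ns in _GO_TERMS:
        go_lines += ["[Term]", f"id: {go_id}", f"name: {name}",
                     f"namespace: {ns}"]
        for child, rel, parent in _GO_EDGES:
            if child == go_id:
                if rel == "is_a":
                    go_lines.append(f"is_a: {parent}")
                else:
                    go_lines.append(f"relationship: {rel} {parent}")
        go_lines.append("")
    go_lines += ["[Term]", "id: GO:0000001", "name: obsolete example",
                 "namespace: biological_process", "is_obsolete: true", ""]
    (out / "mini-go.obo").write_text("\n".join(go_lines))

    to_lines = ["format-version: 1.2", "ontology: mini-to", ""]
    for to_id, name, parent, synonyms in _TO_TERMS:
        to_lines += ["[Term]", f"id: {to_id}", f"name: {name}"]
        if parent:
            to_lines.append(f"is_a: {parent}")
        for syn in synonyms:
            to_lines.append(f'synonym: "{syn}" EXACT []')
        to_lines.append("")
    (out / "mini-to.obo").write_text("\n".join(to_lines))

    go_ns_counts = {"BioProc": 0, "MolFunc": 0, "CelComp": 0}
    for _, _, ns in _GO_TERMS:
        key = {"biological_process": "BioProc",
               "molecular_function": "MolFunc",
               "cellular_component": "CelComp"}[ns]
        go_ns_counts[key] += 1

    # ---- GAF annotation -----------------------------------------------
    aspect_of = {"biological_process": "P", "molecular_function": "F",
                 "cellular_component": "C"}
    go_by_ns = {"P": [], "F": [], "C": []}
    for go_id, _, ns in _GO_TERMS:
        go_by_ns[aspect_of[ns]].append(go_id)
    gaf_rows = []  # (db_id, symbol, go_id, aspect, type)
    used_pairs = set()
    protein_ids = list(proteins)
    for i in range(min(12, len(protein_ids))):
        tid = protein_ids[(i * 3) % len(protein_ids)]
        aspect = "PFC"[i % 3]
        go_id = go_by_ns[aspect][i % len(go_by_ns[aspect])]
        if (tid, go_id) in used_pairs:
            continue
        used_pairs.add((tid, go_id))
        gaf_rows.append((tid, tid.split(".")[0], go_id, aspect, "protein"))
    # two gene-level annotations
    for i, aspect in ((0, "P"), (5, "C")):
        gid = genes[i][0]
        go_id = go_by_ns[aspect][0]
        if (gid, go_id) not in used_pairs:
            used_pairs.add((gid, go_id))
            gaf_rows.append((gid, genes[i][1], go_id, aspect, "gene"))
    # guarantee the planted protein -> SEED_GO annotation is present
    if (SEED_TRANSCRIPT, SEED_GO) not in used_pairs:
        used_pairs.add((SEED_TRANSCRIPT, SEED_GO))
        gaf_rows.append((SEED_TRANSCRIPT, SEED_GENE, SEED_GO, "F", "protein"))

    gaf_lines = ["!gaf-version: 2.0"]
    for db_id, symbol, go_id, aspect, obj_type in gaf_rows:
        gaf_lines.append(
            "\t".join([
                "ENSEMBL", db_id, symbol, "", go_id, "GO_REF:0000002", "IEA",
                "", aspect, "", "", obj_type, f"taxon:{TAXID_CROP}",
                "20160601", "GOA", "", "",
            ])
        )
    # negated annotation, must be skipped by the parser
    gaf_lines.append(
        "\t".join([
            "ENSEMBL", protein_ids[0], protein_ids[0].split(".")[0], "NOT",
            go_by_ns["P"][1], "GO_REF:0000002", "IEA", "", "P", "", "",
            "protein", f"taxon:{TAXID_CROP}", "20160601", "GOA", "", "",
        ])
    )
    (out / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")
    gaf_aspect_counts = {
        a: sum(1 for r in gaf_rows if r[3] == a) for a in "PFC"
    }

    # ---- publications --------------------------------------------------
    taken_pmids = set(SEED_PMIDS)
    pmids = list(SEED_PMIDS)
    while len(pmids) < n_pubs:
        pmids.append(_random_pmid(rng, taken_pmids))
    positive_sentence = (
        f"{SEED_GENE_NAME} controls seed width in developing grains."
    )
    cocit_sentence = f"{COCIT_GENE_NAME} modulates plant height."
    negative_abstract = (
        f"We characterised {NEG_GENE_NAME} in several cultivars. "
        "Differences in leaf water potential were recorded across lines."
    )
    abstracts: dict[str, str] = {}
    abstracts[pmids[0]] = (
        f"{positive_sentence} "
        "Mutant lines produced measurably narrower kernels."
    )
    abstracts[pmids[1]] = (
        "Epidermal cell fate specification requires a conserved regulator. "
        f"{cocit_sentence}"
    )
    abstracts[pmids[2]] = negative_abstract
    abstracts[pmids[3]] = (
        f"{cocit_sentence} "
        "These observations were consistent across environments."
    )
    for pmid in pmids[4:]:
        k = rng.randint(2, 3)
        abstracts[pmid] = " ".join(
            rng.choice(_FILLER).capitalize() + "." for _ in range(k)
        )
    xml = ["<?xml version=\"1.0\" encoding=\"utf-8\"?>", "<PubmedArticleSet>"]
    for pmid in pmids:
        xml += [
            "  <PubmedArticle>", "    <MedlineCitation>",
            f"      <PMID>{pmid}</PMID>",
            "      <Article>",
            f"        <ArticleTitle>Synthetic record {pmid}</ArticleTitle>",
            "        <Abstract>",
            f"          <AbstractText>{abstracts[pmid]}</AbstractText>",
            "        </Abstract>",
            "      </Article>",
            "    </MedlineCitation>", "  </PubmedArticle>",
        ]
    xml.append("</PubmedArticleSet>")
    (out / "abstracts.xml").write_text("\n".join(xml) + "\n")

    # ---- orthologs, domains, external2go ------------------------------
    ref_accessions = [SEED_ORTHOLOG] + [f"Q{10000 + i}" for i in range(5)]
    ortho_lines = ["protein_id\tortholog_accession"]
    ortho_pairs = [(SEED_TRANSCRIPT, SEED_ORTHOLOG)]
    others = [t for t in protein_ids if t != SEED_TRANSCRIPT]
    for i, acc in enumerate(ref_accessions[1:4]):
        ortho_pairs.append((others[i * 2], acc))
    for a, b in ortho_pairs:
        ortho_lines.append(f"{a}\t{b}")
    (out / "orthologs.tsv").write_text("\n".join(ortho_lines) + "\n")

    domain_lines = ["protein_id\tinterpro_id\tdomain_name"]
    domain_pairs = [(SEED_TRANSCRIPT, SEED_DOMAIN, "WRKY domain")]
    for i, (ipr, dname) in enumerate(_OTHER_DOMAINS):
        domain_pairs.append((others[i * 3 + 1], ipr, dname))
    for tid, ipr, dname in domain_pairs:
        domain_lines.append(f"{tid}\t{ipr}\t{dname}")
    (out / "domains.tsv").write_text("\n".join(domain_lines) + "\n")

    x2go_lines = [
        "!external2go mapping (synthetic)",
        f"InterPro:{SEED_DOMAIN} WRKY domain > "
        f"GO:DNA-binding transcription factor activity ; {SEED_GO}",
        "InterPro:IPR013083 Zinc finger > GO:DNA binding ; GO:0003677",
        "InterPro:IPR001245 Protein kinase domain > "
        "GO:protein kinase activity ; GO:0004672",
    ]
    (out / "external2go.txt").write_text("\n".join(x2go_lines) + "\n")
    x2go_matched = 2   # SEED_DOMAIN->GO:0003700, IPR013083->GO:0003677
    x2go_unmatched = 1  # GO:0004672 absent from mini-go

    # ---- reviewed reference proteins ----------------------------------
    uni_lines = ["accession\tname\ttaxid\tsequence\tgo_terms\tpmids\tphenotype"]
    seed_ref_seq = (_random_peptide(rng, 20) + planted_block
                    + _random_peptide(rng, 30))
    uni_rows = [(
        SEED_ORTHOLOG, SEED_ORTHOLOG_NAME, TAXID_REF, seed_ref_seq,
        f"F:{SEED_GO};P:GO:0010214", ";".join(SEED_PMIDS), SEED_PHENOTYPE,
    )]
    ref_phenotypes = ["", "pale leaf pigmentation", "", "late flowering", ""]
    for i, acc in enumerate(ref_accessions[1:]):
        go = ["P:GO:0009908", "C:GO:0005634", "F:GO:0003677",
              "P:GO:0048316", "C:GO:0005634"][i]
        uni_rows.append((
            acc, f"REF{i + 1}", TAXID_REF, _random_peptide(rng, rng.randint(60, 90)),
            go, pmids[5 + i], ref_phenotypes[i],
        ))
    for row in uni_rows:
        uni_lines.append("\t".join(row))
    (out / "uniprot_min.tsv").write_text("\n".join(uni_lines) + "\n")
    uniprot_go_links = sum(len(r[4].split(";")) for r in uni_rows if r[4])
    uniprot_published_in = sum(len(r[5].split(";")) for r in uni_rows if r[5])
    uniprot_phenotypes = sum(1 for r in uni_rows if r[6])

    # ---- workflow ------------------------------------------------------
    (out / "workflow.yaml").write_text(_workflow_yaml(seed))

    transcripts_total = len(proteins)
    manifest = FixtureManifest(
        seed=seed,
        parameters={"n_genes": n_genes, "n_qtl": n_qtl, "n_snp": n_snp,
                    "n_pubs": n_pubs, "taxid_crop": TAXID_CROP,
                    "taxid_ref": TAXID_REF},
        tallies={
            "genes": n_genes,
            "transcripts": transcripts_total,
            "encodes": transcripts_total,
            "popseq_rows": len(gene_cm),
            "go_terms": go_ns_counts,
            "go_is_a": sum(1 for e in _GO_EDGES if e[1] == "is_a"),
            "go_part_of": sum(1 for e in _GO_EDGES if e[1] == "part_of"),
            "go_regulates": sum(1 for e in _GO_EDGES if e[1] == "regulates"),
            "to_terms": len(_TO_TERMS),
            "to_is_a": sum(1 for t in _TO_TERMS if t[2]),
            "gaf_relations": gaf_aspect_counts,
            "qtl": len(qtls),
            "traits": len({q[1] for q in qtls}),
            "control": len({(q[0], q[1]) for q in qtls}),
            "snp": n_snp,
            "colocated": colocated,
            "in_proximity": in_proximity,
            "ortholog": len(ortho_pairs),
            "has_domain": len(domain_pairs),
            "protein_domains": len({d[1] for d in domain_pairs}),
            "cross_references": x2go_matched,
            "x2go_unmatched": x2go_unmatched,
            "uniprot_proteins": len(uni_rows),
            "uniprot_go_links": uniprot_go_links,
            "uniprot_published_in": uniprot_published_in,
            "phenotypes": uniprot_phenotypes,
            "publications": n_pubs,
            "textmine_relations": 2,
            "sequence_hits_min": 1,
        },
        planted_chain={
            "trait_accession": SEED_QTL[1],
            "trait_name": SEED_QTL[2],
            "qtl_accessions": [SEED_QTL[0], SECOND_QTL[0]],
            "gene_accession": SEED_GENE,
            "gene_name": SEED_GENE_NAME,
            "protein_accession": SEED_TRANSCRIPT,
            "domain_accession": SEED_DOMAIN,
            "go_accession": SEED_GO,
            "ortholog_accession": SEED_ORTHOLOG,
            "ortholog_name": SEED_ORTHOLOG_NAME,
            "phenotype": SEED_PHENOTYPE,
            "pmids": list(SEED_PMIDS),
            "to_accession": SEED_TO_TERM,
            "path_classes": ["Trait", "QTL", "Gene", "Protein",
                             "ProtDomain", "BioProc|MolFunc|CelComp"],
            "path_types": ["control", "colocated", "encodes", "has_domain",
                           "cross_reference"],
        },
        textmine={
            "positive_pairs": {
                f"{SEED_GENE_NAME}|seed width": 1,
                f"{COCIT_GENE_NAME}|plant height": 2,
            },
            "negative_pair": [NEG_GENE_NAME, "leaf water potential"],
        },
        files=sorted([
            "genome.gff3", "proteins.fasta", "popseq.tsv", "mini-go.obo",
            "mini-to.obo", "annotations.gaf", "qtl.tsv", "snp.tsv",
            "orthologs.tsv", "domains.tsv", "external2go.txt",
            "uniprot_min.tsv", "abstracts.xml", "workflow.yaml",
        ]),
    )
    (out / "truth.json").write_text(manifest.to_json() + "\n")
    return manifest


def _workflow_yaml(seed: int) -> str:
    """The end-to-end integration workflow shipped with the bundle."""
    return f"""\
# Synthetic crop + reference integration workflow.
seed: {seed}
steps:
  - plugin: parse_fasta_gff3
    output: crop
    params: {{gff3_source: genome.gff3, fasta_source: proteins.fasta, taxid: "{TAXID_CROP}"}}
  - plugin: parse_tabular
    output: popseq
    params:
      source: popseq.tsv
      spec:
        source_id: POPSEQ
        taxid: "{TAXID_CROP}"
        subject:
          class: Gene
          accessions: [{{namespace: ENSEMBL, column: gene_id}}]
          locations:
            - {{attribute: Location_cM, chromosome: {{column: chromosome}}, begin: {{column: position_cm}}, unit: {{const: cM}}}}
  - plugin: parse_obo
    output: go
    params: {{source: mini-go.obo}}
  - plugin: parse_obo
    output: to
    params: {{source: mini-to.obo, concept_class: TO}}
  - plugin: parse_gaf
    output: gaf
    params: {{source: annotations.gaf}}
  - plugin: parse_tabular
    output: qtl
    params:
      source: qtl.tsv
      spec:
        source_id: GRAMENE
        taxid: "{TAXID_CROP}"
        subject:
          class: QTL
          accessions: [{{namespace: GRAMENE, column: qtl_id}}]
          names: [{{column: qtl_id, preferred: true}}]
          locations:
            - {{attribute: Location, chromosome: {{column: chromosome}}, begin: {{column: begin}}, end: {{column: end}}, unit: {{column: unit}}}}
        object:
          class: Trait
          accessions: [{{namespace: GRAMENE, column: trait_id}}]
          names: [{{column: trait_name, preferred: true}}]
        relation: {{type: control}}
  - plugin: parse_tabular
    output: snp
    params:
      source: snp.tsv
      spec:
        source_id: ENSEMBL
        taxid: "{TAXID_CROP}"
        subject:
          class: SNP
          accessions: [{{namespace: ENSEMBL, column: snp_id}}]
          locations:
            - {{attribute: Location, chromosome: {{column: chromosome}}, begin: {{column: position}}, unit: {{const: bp}}}}
  - plugin: parse_tabular
    output: orthologs
    params:
      source: orthologs.tsv
      spec:
        source_id: ENSEMBL
        subject:
          class: Protein
          accessions: [{{namespace: ENSEMBL, column: protein_id}}]
        object:
          class: Protein
          accessions: [{{namespace: UNIPROT, column: ortholog_accession}}]
        relation: {{type: ortholog}}
  - plugin: parse_tabular
    output: domains
    params:
      source: domains.tsv
      spec:
        source_id: ENSEMBL
        subject:
          class: Protein
          accessions: [{{namespace: ENSEMBL, column: protein_id}}]
        object:
          class: ProtDomain
          accessions: [{{namespace: INTERPRO, column: interpro_id}}]
          names: [{{column: domain_name, preferred: true}}]
        relation: {{type: has_domain}}
  - plugin: parse_uniprot_min
    output: refnet
    params: {{source: uniprot_min.tsv}}
  - plugin: parse_publications
    output: pubs
    params: {{source: abstracts.xml}}
  - plugin: merge
    inputs: [crop, popseq, go, to, gaf, qtl, snp, orthologs, domains, refnet, pubs]
    output: main
  - plugin: accession_map
    graph: main
  - plugin: collapse_equal
    graph: main
  - plugin: colocation_map
    graph: main
    params: {{subject_class: Gene, region_class: QTL}}
  - plugin: proximity_map
    graph: main
    params: {{subject_class: SNP, target_class: Gene, window: 0}}
  - plugin: sequence_map
    graph: main
    params: {{query_taxid: "{TAXID_CROP}", subject_taxid: "{TAXID_REF}", top_k: 10, min_score: 50}}
  - plugin: external2go_map
    graph: main
    params: {{mapping_source: external2go.txt}}
  - plugin: textmine_cooccurrence
    graph: main
    params: {{gene_class: Gene, term_class: TO, gene_min_len: 3, term_min_len: 4}}
  - plugin: write_oxl
    graph: main
    params: {{destination: graph.oxl}}
"""
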