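# Default controlled vocabulary for gsknet knowledge graphs.
# Concept classes and relation types cover the standard crop/reference
# network schema (genes, proteins, variation, genetics, ontology terms,
# pathways, literature) plus the operator-generated types (equal,
# colocated, cooccurs_with, cross_reference, has_similar_sequence).
concept_classes:
  - {id: Thing, label: Thing}
  - {id: Gene, label: Gene, parent: Thing}
  - {id: Protein, label: Protein, parent: Thing}
  - {id: Enzyme, label: Enzyme, parent: Protein}
  - {id: RNA, label: RNA, parent: Thing}
  - {id: SNP, label: SNP, parent: Thing}
  - {id: QTL, label: QTL, parent: Thing}
  - {id: Trait, label: Trait, parent: Thing}
  - {id: QuantTrait, label: Quantitative trait, parent: Trait}
  - {id: TO, label: Trait Ontology, parent: Thing}
  - {id: BioProc, label: Biological Process, parent: Thing}
  - {id: MolFunc, label: Molecular Function, parent: Thing}
  - {id: CelComp, label: Cellular Component, parent: Thing}
  - {id: ProtDomain, label: Protein Domain, parent: Thing}
  - {id: Publication, label: Publication, parent: Thing}
  - {id: Phenotype, label: Phenotype, parent: Thing}
  - {id: Compound, label: Compound, parent: Thing}
  - {id: Reaction, label: Reaction, parent: Thing}
  - {id: Transport, label: Transport, parent: Thing}
  - {id: Pathway, label: Pathway, parent: Thing}
  - {id: ProtComplex, label: Protein Complex, parent: Thing}
  - {id: EC, label: Enzyme Classification, parent: Thing}
relation_types:
  - {id: is_a, label: is a}
  - {id: part_of, label: part of}
  - {id: regulates, label: regulates}
  - {id: encodes, label: encodes}
  - {id: equal, label: equal, symmetric: true}
  - {id: ortholog, label: ortholog, symmetric: true}
  - {id: paralog, label: paralog, symmetric: true}
  - {id: has_similar_sequence, label: has similar sequence, symmetric: true}
  - {id: interacts_with, label: interacts with, symmetric: true}
  - {id: has_domain, label: has domain}
  - {id: in_proximity, label: in proximity}
  - {id: associated_with, label: associated with}
  - {id: control, label: control}
  - {id: colocated, label: co-located with}
  - {id: cross_reference, label: cross reference}
  - {id: participates_in, label: participates in}
  - {id: has_function, label: has function}
  - {id: located_in, label: located in}
  - {id: has_observed_phenotype, label: has observed phenotype}
  - {id: published_in, label: published in}
  - {id: has_variance, label: has variance}
  - {id: cooccurs_with, label: co-occurs with}
  - {id: catalysed_by, label: catalysed by}
  - {id: consumed_by, label: consumed by}
  - {id: produced_by, label: produced by}
  - {id: activated_by, label: activated by}
  - {id: inhibited_by, label: inhibited by}
data_sources:
  - {id: ENSEMBL, label: Ensembl}
  - {id: UNIPROT, label: UniProt}
  - {id: GO, label: Gene Ontology}
  - {id: TO, label: Gramene Trait Ontology}
  - {id: GRAMENE, label: Gramene}
  - {id: TAIR, label: TAIR}
  - {id: PMID, label: PubMed}
  - {id: INTERPRO, label: InterPro}
  - {id: GOA, label: GO annotation}
  - {id: POPSEQ, label: POPSEQ genetic map}
  - {id: INTEGRATOR, label: derived by integration operators}
attribute_names:
  - {id: TAXID, kind: text}
  - {id: Chromosome, kind: text}
  - {id: BEGIN, kind: integer}
  - {id: END, kind: integer}
  - {id: Strand, kind: text}
  - {id: Location, kind: location}
  - {id: Location_cM, kind: location}
  - {id: AA, kind: sequence}
  - {id: NA, kind: sequence}
  - {id: Title, kind: text}
  - {id: Abstract, kind: text}
  - {id: Description, kind: text}
  - {id: Score, kind: decimal}
  - {id: Identity, kind: decimal}
  - {id: CoCitations, kind: integer}
  - {id: PMIDs, kind: text}
evidence_types:
  - {id: IMPD, label: imported from database}
  - {id: TM, label: text mining co-occurrence}
  - {id: ACC, label: accession-based mapping}
  - {id: NAM, label: name-based mapping}
  - {id: SSA, label: sequence similarity alignment}
  - {id: COLOC, label: genomic co-location}
  - {id: PROX, label: genomic proximity}
  - {id: X2GO, label: external-to-GO mapping}
  - {id: IEA, label: inferred from electronic annotation}
  - {id: IDA, label: inferred from direct assay}
  - {id: IMP, label: inferred from mutant phenotype}
  - {id: IGI, label: inferred from genetic interaction}
  - {id: IPI, label: inferred from physical interaction}
  - {id: IEP, label: inferred from expression pattern}
  - {id: EXP, label: inferred from experiment}
  - {id: TAS, label: traceable author statement}
  - {id: NAS, label: non-traceable author statement}
  - {id: ISS, label: inferred from sequence similarity}
  - {id: IBA, label: inferred from biological ancestor}
  - {id: IC, label: inferred by curator}
  - {id: ND, label: no data}
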