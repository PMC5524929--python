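# Curated gene-panel lookup tables for the DNMT3b target-gene study
# (mouse enteric precursor cell ChIP-seq panel and its human expression panel).
#
# shared_genes:            mouse genes selected by both consensus routes
# method_exclusive_genes:  mouse genes selected by exactly one route
# curated_functional_genes: mouse genes added by literature review (functional
#                          role in neural development; not selected by voting)
# ortholog_map:            mouse symbol -> human symbol for genes whose human
#                          ortholog is not the uppercase symbol; similarity is
#                          the BLAST percent identity where the ortholog was
#                          found by sequence similarity only
# excluded_pseudogenes:    human symbols removed from the panel (pseudogenes)
# related_genes:           human interactor genes added from a curated
#                          interaction-network analysis

shared_genes:
  - Rn45s
  - Dpp9
  - Mydgf
  - Myo7a
  - Ano2
  - Gm17644

method_exclusive_genes:
  - Sulf1
  - 2210408I21Rik
  - Ly75
  - Kpna1
  - 4933422A05Rik
  - Chl1
  - Cyr61
  - Gphn
  - Bbx

curated_functional_genes:
  - Rab10os
  - Drg1
  - Eif4enif1
  - Sfi1
  - Ppp2r2b
  - Dopey2
  - Smo
  - Litaf
  - Cdk5rap2
  - Limd1
  - 4921504E06Rik
  - Tmem125

ortholog_map:
  Rn45s:          {human: RNA45S5}
  Gm17644:        {human: LINC01603, similarity: 79.27}
  2210408I21Rik:  {human: KIAA0825}
  Rab10os:        {human: RAB10, similarity: 96.28}
  4933422A05Rik:  {human: RP11-220D10.1, similarity: 82.44}
  4921504E06Rik:  {human: C10ORF67}

excluded_pseudogenes:
  - RP11-220D10.1

related_genes:
  - EED
  - STAT3
  - NEUROG1
  - ADAM8
  - NEDD4
  - NEDD4L
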