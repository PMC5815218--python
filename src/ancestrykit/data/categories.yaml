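# Controlled ancestry-category vocabulary: 17 distinct regional population
# groupings. Order of records is the canonical display order. Synonyms come
# from the category definitions (author-used labels such as "Caucasian");
# sub-population descriptors ("Han Chinese", "Yoruban", ...) live in
# lexicon.yaml instead. Reference populations are 1000 Genomes / HapMap
# phase-3 cohort codes; admixed marks categories defined by known admixture.
categories:
  - name: Aboriginal Australian
    definition: >
      Individuals who self-report or are described as Australian Aboriginal,
      descendants of the early human migration into Australia from eastern
      Asia, distinguishable from other Asian populations by mtDNA and
      Y-chromosome variation.
    synonyms: [Australian Aboriginal]
    reference_populations: []
    example_descriptors: [Martu Australian Aboriginal]
    admixed: false

  - name: African American or Afro-Caribbean
    definition: >
      Individuals who self-report or are described as African American or
      Afro-Caribbean, or who genetically cluster with reference populations
      from this group; significant admixture with European ancestry
      populations is expected.
    synonyms: [African American, Afro-Caribbean, African Caribbean]
    reference_populations: [ACB, ASW]
    example_descriptors: [African American, African Caribbean]
    admixed: true

  - name: African unspecified
    definition: >
      Individuals described as African without sufficient information to
      classify as African American, Afro-Caribbean or Sub-Saharan African.
    synonyms: [African]
    reference_populations: []
    example_descriptors: [African, non-Hispanic black]
    admixed: false

  - name: Asian unspecified
    definition: >
      Individuals described as Asian without sufficient information to
      classify as East, Central, South or South-East Asian.
    synonyms: [Asian]
    reference_populations: []
    example_descriptors: [Asian, Asian American]
    admixed: false

  - name: Central Asian
    definition: >
      Individuals who self-report or are described as Central Asian. No
      suitable reference population is currently available.
    synonyms: []
    reference_populations: []
    example_descriptors: [Silk Road]
    admixed: false

  - name: East Asian
    definition: >
      Individuals who self-report or are described as East Asian or one of
      the sub-populations from this region (e.g. Chinese), or who genetically
      cluster with the CDX, CHB, CHS or JPT reference populations.
    synonyms: []
    reference_populations: [CDX, CHB, CHS, JPT]
    example_descriptors: [Chinese, Japanese, Korean]
    admixed: false

  - name: European
    definition: >
      Individuals who self-report or are described as European, Caucasian,
      white, or one of the sub-populations from this region (e.g. Dutch), or
      who genetically cluster with the CEU, FIN, GBR, IBS or TSI reference
      populations.
    synonyms: [Caucasian, white]
    reference_populations: [CEU, FIN, GBR, IBS, TSI]
    example_descriptors: [Spanish, Swedish]
    admixed: false

  - name: Greater Middle Eastern (Middle Eastern, North African, or Persian)
    definition: >
      Individuals who self-report or are described as Middle Eastern, North
      African, Persian, or one of the sub-populations from this region (e.g.
      Saudi Arabian); heterogeneous, with varying degrees of admixture and
      genetic isolation, and no suitable reference population.
    synonyms: [Greater Middle Eastern, Middle Eastern, North African, Persian]
    reference_populations: []
    example_descriptors: [Tunisian, Arab, Iranian]
    admixed: false

  - name: Hispanic or Latin American
    definition: >
      Individuals who self-report or are described as Hispanic, Latino, Latin
      American, or one of the sub-populations from this region; known
      admixture of primarily European, African and Native American ancestries,
      or genetic clustering with the CLM, MXL, PEL or PUR reference
      populations.
    synonyms: [Hispanic, Latino, Latin American, Hispanic/Latino]
    reference_populations: [CLM, MXL, PEL, PUR]
    example_descriptors: [Brazilian, Mexican]
    admixed: true

  - name: Native American
    definition: >
      Indigenous individuals of North, Central and South America, descended
      from the original human migration into the Americas from Siberia. No
      suitable reference population is currently available.
    synonyms: [American Indian, Amerindian]
    reference_populations: []
    example_descriptors: [Pima Indian, Plains American Indian]
    admixed: false

  - name: Not reported
    definition: >
      Individuals for whom no ancestry or country of recruitment information
      is available.
    synonyms: [NR]
    reference_populations: []
    example_descriptors: []
    admixed: false

  - name: Oceanian
    definition: >
      Individuals who self-report or are described as Oceanian or one of the
      sub-populations from this region (e.g. Native Hawaiian). No suitable
      reference population is currently available.
    synonyms: []
    reference_populations: []
    example_descriptors: [Solomon Islander, Micronesian]
    admixed: false

  - name: Other
    definition: >
      Individuals for whom an ancestry descriptor is known but insufficient
      information is available to assign one of the other categories.
    synonyms: []
    reference_populations: []
    example_descriptors: [Surinamese, Russian]
    admixed: false

  - name: Other admixed ancestry
    definition: >
      Individuals who self-report or are described as admixed and do not fit
      the definition of the other admixed categories (African American or
      Afro-Caribbean; Hispanic or Latin American).
    synonyms: [Other admixed ancestries]
    reference_populations: []
    example_descriptors: []
    admixed: true

  - name: South Asian
    definition: >
      Individuals who self-report or are described as South Asian or one of
      the sub-populations from this region (e.g. Asian Indian), or who
      genetically cluster with the BEB, GIH, ITU, PJL or STU reference
      populations.
    synonyms: []
    reference_populations: [BEB, GIH, ITU, PJL, STU]
    example_descriptors: [Bangladeshi, Sri Lankan Sinhalese]
    admixed: false

  - name: South East Asian
    definition: >
      Individuals who self-report or are described as South East Asian or one
      of the sub-populations from this region (e.g. Vietnamese), or who
      genetically cluster with the KHV reference population; distinct genetic
      background from East Asian populations, though often conflated.
    synonyms: [South-East Asian, Southeast Asian]
    reference_populations: [KHV]
    example_descriptors: [Thai, Malay]
    admixed: false

  - name: Sub-Saharan African
    definition: >
      Individuals who self-report or are described as Sub-Saharan African or
      one of the sub-populations from this region (e.g. Yoruban), or who
      genetically cluster with the ESN, LWK, GWD, MSL, MKK or YRI reference
      populations.
    synonyms: [Sub Saharan African]
    reference_populations: [ESN, LWK, GWD, MSL, MKK, YRI]
    example_descriptors: [Yoruban, Gambian]
    admixed: false
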