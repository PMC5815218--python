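# Seed descriptor lexicon: free-text ancestry descriptors with their
# category assignments. Descriptors are matched after normalization
# (case-folded, punctuation stripped). Flags:
#   ethnocultural - socio-cultural self-identification rather than a
#                   genetic/geographic descriptor
#   isolate       - founder or genetically isolated population
# The list is a self-contained seed covering the common descriptors; users
# extend it with their own YAML via configuration.
entries:
  # East Asian
  - {descriptor: Han Chinese, category: East Asian}
  - {descriptor: Chinese, category: East Asian}
  - {descriptor: Chinese Han, category: East Asian}
  - {descriptor: Japanese, category: East Asian}
  - {descriptor: Korean, category: East Asian}
  - {descriptor: Taiwanese, category: East Asian}
  - {descriptor: Mongolian, category: East Asian}

  # European
  - {descriptor: Spanish, category: European}
  - {descriptor: Swedish, category: European}
  - {descriptor: Dutch, category: European}
  - {descriptor: British, category: European}
  - {descriptor: Irish, category: European}
  - {descriptor: German, category: European}
  - {descriptor: French, category: European}
  - {descriptor: Italian, category: European}
  - {descriptor: Finnish, category: European}
  - {descriptor: Norwegian, category: European}
  - {descriptor: Danish, category: European}
  - {descriptor: Polish, category: European}
  - {descriptor: Greek, category: European}
  - {descriptor: Icelandic, category: European, isolate: true}
  - {descriptor: Sardinian, category: European, isolate: true}
  - {descriptor: Old Order Amish, category: European, isolate: true}
  - {descriptor: Amish, category: European, isolate: true}
  - {descriptor: Hutterite, category: European, isolate: true}
  - {descriptor: Ashkenazi Jewish, category: European, ethnocultural: true, isolate: true}

  # South Asian
  - {descriptor: Punjabi Sikh, category: South Asian, ethnocultural: true}
  - {descriptor: Sikh, category: South Asian, ethnocultural: true}
  - {descriptor: Asian Indian, category: South Asian}
  - {descriptor: Indian, category: South Asian}
  - {descriptor: Bangladeshi, category: South Asian}
  - {descriptor: Pakistani, category: South Asian}
  - {descriptor: Sri Lankan Sinhalese, category: South Asian}
  - {descriptor: Gujarati, category: South Asian}

  # South East Asian
  - {descriptor: Thai, category: South East Asian}
  - {descriptor: Malay, category: South East Asian}
  - {descriptor: Vietnamese, category: South East Asian}
  - {descriptor: Filipino, category: South East Asian}
  - {descriptor: Indonesian, category: South East Asian}

  # Central Asian
  - {descriptor: Silk Road, category: Central Asian, isolate: true}
  - {descriptor: Kazakh, category: Central Asian}
  - {descriptor: Tajik, category: Central Asian}

  # Sub-Saharan African
  - {descriptor: Yoruban, category: Sub-Saharan African}
  - {descriptor: Yoruba, category: Sub-Saharan African}
  - {descriptor: Gambian, category: Sub-Saharan African}
  - {descriptor: Ghanaian, category: Sub-Saharan African}
  - {descriptor: Kenyan, category: Sub-Saharan African}
  - {descriptor: Malawian, category: Sub-Saharan African}
  - {descriptor: Ugandan, category: Sub-Saharan African}

  # African American or Afro-Caribbean
  - {descriptor: African American, category: African American or Afro-Caribbean}
  - {descriptor: African Caribbean, category: African American or Afro-Caribbean}
  - {descriptor: Afro-Caribbean, category: African American or Afro-Caribbean}
  - {descriptor: Jamaican, category: African American or Afro-Caribbean}

  # African unspecified
  - {descriptor: non-Hispanic black, category: African unspecified}
  - {descriptor: black, category: African unspecified}

  # Asian unspecified
  - {descriptor: Asian American, category: Asian unspecified}

  # Hispanic or Latin American
  - {descriptor: Brazilian, category: Hispanic or Latin American}
  - {descriptor: Mexican, category: Hispanic or Latin American}
  - {descriptor: Mexican American, category: Hispanic or Latin American}
  - {descriptor: Puerto Rican, category: Hispanic or Latin American}
  - {descriptor: Colombian, category: Hispanic or Latin American}
  - {descriptor: Peruvian, category: Hispanic or Latin American}
  - {descriptor: Costa Rican, category: Hispanic or Latin American}
  - {descriptor: Chilean, category: Hispanic or Latin American}

  # Greater Middle Eastern
  - {descriptor: Tunisian, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Arab, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Iranian, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Saudi Arabian, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Turkish, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Lebanese, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Moroccan, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Egyptian, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)"}
  - {descriptor: Bedouin, category: "Greater Middle Eastern (Middle Eastern, North African, or Persian)", ethnocultural: true}

  # Native American
  - {descriptor: Pima Indian, category: Native American}
  - {descriptor: Plains American Indian, category: Native American}
  - {descriptor: Native American, category: Native American}

  # Oceanian
  - {descriptor: Solomon Islander, category: Oceanian}
  - {descriptor: Micronesian, category: Oceanian}
  - {descriptor: Native Hawaiian, category: Oceanian}
  - {descriptor: Samoan, category: Oceanian}
  - {descriptor: Tongan, category: Oceanian}

  # Aboriginal Australian
  - {descriptor: Martu Australian Aboriginal, category: Aboriginal Australian}
  - {descriptor: Martu, category: Aboriginal Australian}

  # Other (descriptor known but not classifiable further)
  - {descriptor: Surinamese, category: Other}
  - {descriptor: Russian, category: Other}
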