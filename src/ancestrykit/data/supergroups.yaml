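# Default display supergroups used when collapsing category-level
# distributions (e.g. "Asian" aggregating its regional sub-categories).
# These are analysis-time groupings only, not vocabulary categories.
# The African aggregate includes the African-admixed category; override
# with a custom map to exclude it.
supergroups:
  Asian:
    - East Asian
    - South Asian
    - South East Asian
    - Central Asian
    - Asian unspecified
  African:
    - Sub-Saharan African
    - African unspecified
    - African American or Afro-Caribbean
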