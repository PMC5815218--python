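# Known cohort names whose geographic component must not be read as an
# ancestry statement (a UK-recruited cohort is not thereby of European
# ancestry). Matched case-insensitively as substrings of the detailed
# description. User-extensible via configuration.
cohorts:
  - TwinsUK
  - UK Biobank
  - deCODE
  - Framingham
  - ALSPAC
  - 23andMe
  - Rotterdam Study
  - Nurses' Health Study
  - EPIC
  - Women's Health Initiative
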