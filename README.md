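# ancestrykit

Standardized representation, validation and diversity analysis of ancestry
metadata in human genomics studies.

Large genomics resources describe the people they study with free-text
population descriptors ("Han Chinese", "Punjabi Sikh", "Old Order Amish
individuals of European descent"). Degrees of genetic diversity and linkage
disequilibrium differ between ancestral backgrounds, so downstream users —
curators of GWAS repositories, method developers studying transferability,
anyone auditing who is actually represented in genomic research — need those
descriptors mapped onto a controlled, hierarchical vocabulary before any
cross-study analysis is possible. ancestrykit implements that framework as a
library and command-line tool:

* **Two-form representation.** Every sample keeps its maximally granular
  *detailed description* and additionally receives an *ancestry category*
  from a controlled list of 17 regional population groupings (European, East
  Asian, Sub-Saharan African, Hispanic or Latin American, ...), each anchored
  to 1000 Genomes / HapMap phase-3 reference populations (27 cohort codes:
  CEU, YRI, JPT, PEL, ...). The hierarchy exports as an OBO ontology.
* **Deterministic classification cascade.** Evidence is used in precedence
  order: genomic clustering with a reference population ≻ author-stated
  category ≻ longest-match lexicon lookup on the detailed description ≻
  country-of-recruitment inference from demographic references ≻
  "Not reported". Every result records its evidence tier and matched terms.
  Admixed samples that fit no defined admixed category are assigned "Other
  admixed ancestry" with their contributing components recorded.
* **Catalog TSV I/O.** Reader/writer for the per-sample ancestry file and the
  per-association file in the public GWAS-catalog download dialect, with a
  round-trip guarantee, plus the display form `sample size, category,
  (country of recruitment)` — e.g. `2,000 East Asian (China)`.
* **Metadata linter.** Ten rules (R1–R10) operationalizing reporting
  recommendations for authors: granularity, country-as-ancestry,
  cohort-name-as-ancestry, unqualified ethno-cultural or isolate descriptors,
  admixture components, ascertainment method, and missing category / sample
  size / recruitment country.
* **Diversity engine.** Category distributions at the individuals, studies
  and associations levels, publication-year windows with per-category fold
  changes, supergroup aggregation (e.g. "Asian", "African"), and per-trait
  ancestry breadth.
* **Synthetic catalogs.** A seeded generator with exact ground truth, so the
  whole pipeline is testable offline.

## Worked example

```python
>>> import ancestrykit as ak
>>> ak.classify_descriptor("Han Chinese").categories
frozenset({'East Asian'})
>>> r = ak.classify_sample(description="admixed individuals of European and East Asian descent")
>>> r.categories, r.admixture_components
(frozenset({'Other admixed ancestry'}), ('East Asian', 'European'))
>>> ak.classify_sample(population_codes=["CEU"]).tier
'reference-population'
>>> ak.category_for_population_code("YRI").name
'Sub-Saharan African'
```

From the shell, generate a synthetic catalog and analyze it:

```console
$ ancestrykit simulate --n-studies 30 --seed 4 --outdir demo
$ ancestrykit analyze demo/ancestry.tsv --associations demo/associations.tsv --level studies
# level=studies N=30
label   count   percentage
African unspecified     1       3.333
East Asian      4       13.333
European        11      36.667
Greater Middle Eastern (Middle Eastern, North African, or Persian)      1       3.333
Hispanic or Latin American      3       10.000
Other   2       6.667
South Asian     3       10.000
multiple        5       16.667
```

Eleven of the 30 simulated studies analyzed exclusively European-ancestry
individuals, five spanned more than one category ("multiple"), and the rest
each analyzed a single non-European category — the study-level diversity
profile of the simulated repository. `ancestrykit validate demo/ancestry.tsv`
lints the same file (exit code 1 when any error-severity finding such as a
missing category is present), and `ancestrykit export-obo` prints the
category hierarchy as OBO.

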