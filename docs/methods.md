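# Methods

## The representation model

Every analyzed sample carries its ancestry in two forms. The *detailed
description* is free text and preserves whatever granularity the source
provides ("Sri Lankan Sinhalese", "Old Order Amish individuals of European
descent"). The *ancestry category* is one of 17 controlled labels, each
defined as a regional population grouping with characteristic patterns of
genetic variation. Three of the labels are bookkeeping rather than regions:
"Not reported" (no information), "Other" (descriptor known but not
assignable — a curator judgement), and "Other admixed ancestry" (admixture
outside the two defined admixed categories, African American or
Afro-Caribbean and Hispanic or Latin American). Seven categories are
anchored to 1000 Genomes / HapMap phase-3 reference populations; the 27
cohort codes are pairwise disjoint across categories, so a code identifies
its category uniquely.

Supergroups ("Asian", "African") are analysis-time display maps, not
vocabulary members; the packaged default places the African-admixed
category inside the African aggregate, which is configurable because the
choice is a presentation convention, not a genetic claim.

## The classification cascade

`classify_sample` consumes four evidence sources in fixed precedence:

1. **reference-population codes** — genomic clustering evidence; strongest;
2. **author-stated category** — resolved against names and synonyms;
3. **descriptor matching** — the detailed description is normalized
   (case-folded, punctuation stripped, whitespace collapsed) and scanned
   left-to-right with longest-match n-grams (≤ 4 tokens), each fragment
   looked up against the curated lexicon, then category names/synonyms,
   then population codes. Disjoint matches produce a multi-category
   result. The 4-token cap with longest-first matching is what keeps
   "African American" from being read as "African" + unmatched token;
4. **country of recruitment** — the demographic-majority category of the
   country, from a seeded table following UN M49 regions and public
   demographic compendia. Demographically heterogeneous countries (United
   States, Canada, Australia, Brazil is *not* one — it maps to Hispanic or
   Latin American as a Latin American country — but e.g. Singapore and
   Israel are) deliberately map to "Not reported": recruitment there
   carries no usable ancestry signal;
5. **"Not reported"** otherwise. The cascade never raises; unresolvable
   evidence at one tier falls through to the next.

A non-empty descriptor that matches nothing raises an error instead of
defaulting to "Other", because "Other" encodes a positive curator judgement
("descriptor known, category not assignable") that must never be assigned
silently.

Admixture keywords ("admixed", "admixture", "mixed ancestry") in the
description trigger a post-rule: a result already in a defined admixed
category is kept; any other result is reassigned to "Other admixed
ancestry" with the matched categories retained as components. The rule is
applied to author-stated and descriptor-derived results but not to
reference-population results (genomic clustering evidence is taken at face
value) nor to country inference. When author-stated and genomic evidence
conflict, genomic evidence wins and the provenance trail (`matched_terms`,
`tier`) records what happened; users who trust self-report more can reorder
by calling the tier-specific operations directly.

## Lint rules

The ten rules map the reporting recommendations onto mechanical checks.
R1 (broad-only descriptor) fires when the normalized description *is* a
category name or synonym. R2 fires when the description resolves as a
country. R4/R5 (ethno-cultural term, isolate population) fire when a
flagged lexicon term appears without any accompanying broader-ancestry
term; "Old Order Amish individuals of European descent" is clean because
"European" matches a category label. R6 fires for an admixed category with
no component categories findable anywhere in the record. R7 looks for an
ascertainment-method keyword (self-report, PCA, genomic, ...) in the
descriptions; it is informational because methods are often reported
elsewhere in a publication. R8–R10 are completeness checks; a record with
an explicit confidentiality flag suppresses them, since deliberate
non-disclosure is legitimate. The catalog-level summary reports the
fraction of studies with no ancestry information at all; it is reported,
never judged, because the acceptable level is a policy question.

## Diversity statistics

A unit's label is the single category it spans, "multiple" when it spans
more than one (ignoring "Not reported"), or "Not reported" when it spans
none. At the individuals level each sample contributes its whole
participant count to its label — no fractional splitting across the
categories of a multi-ancestry sample, which matches how a "multiple"
slice is conventionally displayed and keeps counts integral. Individuals
are summed over initial and replication stages and across studies without
deduplication; cohorts reused by many publications are therefore counted
repeatedly, a known upward bias toward heavily reused (largely European and
Asian) cohorts that the individual-level percentages inherit. Study labels
use the union of their samples' categories; associations use their own
annotation when present, else their study's label. Windows filter on
publication year, inclusive on both ends. Fold changes between windows are
ratios of percentages; a label absent from the first window reports an
undefined fold (`None`) rather than infinity.

## Synthetic catalogs

The generator emulates the analyzed repository's ancestry structure, not
its science: no genotypes, traits beyond labels, or association statistics.
Default conditions: 4% of studies carry no ancestry information, 20% are
multi-ancestry, and single-category studies draw from a mixture with a
European majority (0.55), East Asian next (0.18), and small shares across
the remaining categories; publications span 2005–2016; cohort sizes follow
a shifted negative binomial with mean ≈ 5,000 and dispersion 1 (heavy
tailed, as observed GWAS cohort sizes are); studies gain a replication
sample with probability 0.5 and a shifted-Poisson number of associations
(mean 13, the order of magnitude of associations-per-study in public GWAS
repositories). Every study type has the same expected number of samples,
individuals and associations, so the expected label shares are identical at
all three analysis levels — this is what makes the closed-form
`expected_distribution` exact and level-independent.

What the generator does **not** emulate: correlation between category and
cohort size, per-association ancestry annotations, descriptor noise
(misspellings, novel terms), multi-sample studies with more than two
categories, or cohort reuse across studies. Passing recovery tests
therefore demonstrate that the pipeline is self-consistent and unbiased
under these conditions, not that real-catalog percentages are reproduced;
reproducing published corpus figures requires the corresponding release
files and is supported through the same `read -> analyze` path.

## Statistical checks and numerical choices

Parameter-recovery tests compare analysis-recovered shares with configured
mixtures using 99% intervals. At the studies level the share of a label is
a binomial proportion and the plain binomial interval applies. At the
individuals and associations levels the recovered share is a ratio of
random sums (random cohort sizes / association counts), whose variance
exceeds the binomial by a factor (1 + CV²) of the per-study weight
distribution; the intervals are widened accordingly (delta method), with
CV² computed in closed form from the configured size and count
distributions. Because ~39 label×level comparisons are made at 99%
coverage each, the test asserts that at most 2 fall outside their
intervals — under correct coverage the probability of 3 or more excursions
is below 1% — rather than demanding zero, which would fail a calibrated
pipeline about a third of the time. Problem sizes used by the test suite
and the acceptance script: 1,000-study catalogs for recovery checks,
700-study catalogs (~1,500 samples) for round-trip checks, 50 seeded
catalogs of ≤ 10 studies for brute-force oracle equivalence.

Other numerical conventions: percentages are computed from exact integer
counts and must sum to 100 within 0.1 after rounding; OBO term identifiers
are zero-padded sequential numbers assigned in sorted-name order (stable
under re-export and insertion); category cells containing commas inside a
category name (the Greater Middle Eastern label) are resolved by greedy
re-joining of comma-separated fragments; dates parse as ISO-8601 with a
day-month-year fallback; the empty catalog is an error for linting
(fractions would be 0/0) but yields an all-zero report for distributions.

## Known limitations

The shipped lexicon and country table are seeds (~90 descriptors, ~80
countries), intentionally small and user-extensible; coverage of real
catalogs requires extending them. Classification is exact-match after
normalization — no fuzzy matching, by design, to keep assignments auditable.
The vocabulary is a pragmatic curation instrument: categories are not
claims about discrete biological races, several regions lack suitable
reference populations, and admixed groups are represented coarsely; finer
sub-categories can be layered on via the configurable hierarchy without
changing the analysis code.
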