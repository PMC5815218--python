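"""Deterministic classification of ancestry descriptors and sample metadata.

Free-text population descriptors ("Han Chinese", "Punjabi Sikh", "Old Order
Amish") are mapped onto controlled ancestry categories by longest-match
n-gram lookup against (in order) a curated descriptor lexicon, the category
names and synonyms, and the 1000 Genomes / HapMap reference-population
codes.

Whole samples are classified by an evidence-precedence cascade. Genomic
evidence (clustering with a reference population) outranks author-stated
category labels, which outrank descriptor matching, which outranks
country-of-recruitment inference; a sample with none of these is "Not
reported". Every result records the evidence tier used and the matched
terms, so downstream consumers can audit how each category was assigned.

Admixed samples are recognized by admixture keywords in the description:
when the matched category is not itself one of the defined admixed
categories, the sample is assigned "Other admixed ancestry" and the matched
component categories are retained as ``admixture_components``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

from ._text import normalize_descriptor
from .errors import (
    UnclassifiedDescriptorError,
    UnknownCodeError,
    UnknownCountryError,
    UnknownLabelError,
)
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy

__all__ = [
    "LexiconEntry",
    "CountryEntry",
    "ClassificationResult",
    "LexiconMapper",
    "DEFAULT_MAPPER",
    "normalize_descriptor",
    "classify_descriptor",
    "infer_from_country",
    "classify_sample",
    "TIER_REFERENCE",
    "TIER_AUTHOR",
    "TIER_LEXICON",
    "TIER_COUNTRY",
    "TIER_NOT_REPORTED",
    "TIER_ORDER",
]

NOT_REPORTED = "Not reported"
OTHER_ADMIXED = "Other admixed ancestry"

TIER_REFERENCE = "reference-population"
TIER_AUTHOR = "author-stated"
TIER_LEXICON = "lexicon"
TIER_COUNTRY = "country-inferred"
TIER_NOT_REPORTED = "not-reported"

#: Cascade order, strongest evidence first.
TIER_ORDER = (
    TIER_REFERENCE,
    TIER_AUTHOR,
    TIER_LEXICON,
    TIER_COUNTRY,
    TIER_NOT_REPORTED,
)

#: Substrings (of the normalized description) signalling an admixed sample.
ADMIXTURE_KEYWORDS = ("admixed", "admixture", "mixed ancestry", "mixed ancestries")

#: Longest n-gram (in tokens) considered during descriptor matching.
MAX_NGRAM = 4


@dataclass(frozen=True)
class LexiconEntry:
    """A curated descriptor with its category assignment and term flags."""

    descriptor: str
    category: str
    ethnocultural: bool = False
    isolate: bool = False
    admixture_components: tuple[str, ...] = ()


@dataclass(frozen=True)
class CountryEntry:
    """A recruitment country and the category inferred from its demography."""

    country: str
    iso: str
    un_region: str
    inferred_category: str


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of a classification: categories, evidence tier, provenance."""

    categories: frozenset[str]
    tier: str
    matched_terms: tuple[tuple[str, object], ...] = ()
    admixture_components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("a classification must carry at least one category")
        if self.tier not in TIER_ORDER:
            raise ValueError(f"unknown evidence tier: {self.tier!r}")
        is_nr = self.categories == frozenset({NOT_REPORTED})
        if (self.tier == TIER_NOT_REPORTED) != is_nr:
            raise ValueError(
                "tier 'not-reported' if and only if categories == {'Not reported'}"
            )

    @property
    def tier_rank(self) -> int:
        return TIER_ORDER.index(self.tier)


def _not_reported(matched: tuple = ()) -> ClassificationResult:
    return ClassificationResult(
        frozenset({NOT_REPORTED}), TIER_NOT_REPORTED, matched
    )


class LexiconMapper:
    """Classifier over a taxonomy, a descriptor lexicon and a country table.

    With no arguments the packaged seed lexicon (~90 descriptors) and
    country table (~80 recruitment countries) are loaded. Additional
    entries can be supplied to extend or override the seeds.
    """

    def __init__(
        self,
        taxonomy: Taxonomy | None = None,
        lexicon: Iterable[LexiconEntry] | None = None,
        countries: Iterable[CountryEntry] | None = None,
    ):
        self.taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
        if lexicon is None:
            lexicon = self._packaged_lexicon()
        if countries is None:
            countries = self._packaged_countries()

        self._lexicon: dict[str, LexiconEntry] = {}
        for entry in lexicon:
            key = normalize_descriptor(entry.descriptor)
            if key in self._lexicon:
                raise ValueError(f"duplicate lexicon descriptor: {entry.descriptor!r}")
            if entry.category not in self.taxonomy:
                raise ValueError(
                    f"lexicon entry {entry.descriptor!r} names unknown "
                    f"category {entry.category!r}"
                )
            self._lexicon[key] = entry

        self._countries: dict[str, CountryEntry] = {}
        for centry in countries:
            for key in (normalize_descriptor(centry.country), centry.iso.casefold()):
                if key in self._countries:
                    raise ValueError(f"duplicate country entry: {centry.country!r}")
                self._countries[key] = centry

        self._admixed_names = frozenset(
            c.name for c in self.taxonomy.list_categories() if c.admixed
        )

    @staticmethod
    def _packaged_lexicon() -> list[LexiconEntry]:
        text = resources.files("ancestrykit").joinpath("data", "lexicon.yaml")
        raw = yaml.safe_load(text.read_text("utf-8"))
        return [
            LexiconEntry(
                descriptor=rec["descriptor"],
                category=rec["category"],
                ethnocultural=bool(rec.get("ethnocultural", False)),
                isolate=bool(rec.get("isolate", False)),
                admixture_components=tuple(rec.get("admixture_components", ())),
            )
            for rec in raw["entries"]
        ]

    @staticmethod
    def _packaged_countries() -> list[CountryEntry]:
        text = resources.files("ancestrykit").joinpath("data", "countries.yaml")
        raw = yaml.safe_load(text.read_text("utf-8"))
        return [
            CountryEntry(
                country=rec["country"],
                iso=str(rec["iso"]),
                un_region=rec["un_region"],
                inferred_category=rec["inferred_category"],
            )
            for rec in raw["countries"]
        ]

    @property
    def lexicon_entries(self) -> tuple[LexiconEntry, ...]:
        return tuple(self._lexicon.values())

    @property
    def country_entries(self) -> tuple[CountryEntry, ...]:
        # each entry is registered under name and ISO keys; deduplicate
        seen: dict[int, CountryEntry] = {id(e): e for e in self._countries.values()}
        return tuple(seen.values())

    # ------------------------------------------------------------------
    def _lookup_fragment(self, fragment: str) -> object | None:
        """Match one normalized n-gram: lexicon, then labels, then codes."""
        entry = self._lexicon.get(fragment)
        if entry is not None:
            return entry
        try:
            return self.taxonomy.resolve_category_label(fragment)
        except UnknownLabelError:
            pass
        if " " not in fragment and len(fragment) == 3 and fragment.isalpha():
            try:
                return self.taxonomy.category_for_population_code(fragment)
            except UnknownCodeError:
                pass
        return None

    def classify_descriptor(self, text: str) -> ClassificationResult:
        """Classify a free-text descriptor by longest-match n-gram lookup.

        Scans left to right, preferring the longest matching n-gram (up to
        :data:`MAX_NGRAM` tokens) at each position; disjoint matches yield a
        multi-category result. Empty input classifies as "Not reported"; a
        non-empty input with no matches raises
        :class:`UnclassifiedDescriptorError` — never a silent "Other".
        """
        norm = normalize_descriptor(text)
        if not norm:
            return _not_reported()
        tokens = norm.split()
        matched: list[tuple[str, object]] = []
        i = 0
        while i < len(tokens):
            for n in range(min(MAX_NGRAM, len(tokens) - i), 0, -1):
                fragment = " ".join(tokens[i : i + n])
                hit = self._lookup_fragment(fragment)
                if hit is not None:
                    matched.append((fragment, hit))
                    i += n
                    break
            else:
                i += 1
        if not matched:
            raise UnclassifiedDescriptorError(text)
        categories = frozenset(
            e.category if isinstance(e, LexiconEntry) else e.name
            for _, e in matched
        )
        if categories == {NOT_REPORTED}:
            return _not_reported(tuple(matched))
        categories = categories - {NOT_REPORTED}
        components: tuple[str, ...] = ()
        for _, e in matched:
            if isinstance(e, LexiconEntry) and e.admixture_components:
                components = components + tuple(
                    c for c in e.admixture_components if c not in components
                )
        return ClassificationResult(
            categories, TIER_LEXICON, tuple(matched), components
        )

    def infer_from_country(self, country: str) -> ClassificationResult:
        """Infer a category from the recruitment country's demographic majority.

        Demographically heterogeneous countries are seeded as "Not reported"
        and yield the not-reported tier; countries absent from the table
        raise :class:`UnknownCountryError`.
        """
        entry = self._countries.get(normalize_descriptor(country))
        if entry is None:
            entry = self._countries.get(country.strip().casefold())
        if entry is None:
            raise UnknownCountryError(country)
        matched = ((country, entry),)
        if entry.inferred_category == NOT_REPORTED:
            return _not_reported(matched)
        return ClassificationResult(
            frozenset({entry.inferred_category}), TIER_COUNTRY, matched
        )

    # ------------------------------------------------------------------
    def _apply_admixture_rule(
        self, result: ClassificationResult
    ) -> ClassificationResult:
        """Reclassify a keyword-flagged sample that lacks an admixed category."""
        if result.categories & self._admixed_names:
            return result
        components = tuple(
            sorted(result.categories - {NOT_REPORTED})
        ) or result.admixture_components
        return ClassificationResult(
            frozenset({OTHER_ADMIXED}),
            result.tier,
            result.matched_terms,
            components,
        )

    def classify_sample(
        self,
        author_category: str | None = None,
        description: str = "",
        population_codes: Sequence[str] = (),
        country_of_recruitment: str | None = None,
    ) -> ClassificationResult:
        """Classify one sample through the evidence-precedence cascade.

        Order of evidence: reference-population codes (genomic), the
        author-stated category label, descriptor matching on the detailed
        description, country-of-recruitment inference, and finally "Not
        reported". The cascade never raises: unresolvable evidence at one
        tier falls through to the next.
        """
        norm_desc = normalize_descriptor(description)
        admixed_kw = any(kw in norm_desc for kw in ADMIXTURE_KEYWORDS)

        # (1) genomic evidence: clustering with reference populations
        if population_codes:
            matched = []
            for code in population_codes:
                try:
                    matched.append((code, self.taxonomy.category_for_population_code(code)))
                except UnknownCodeError:
                    continue
            if matched:
                cats = frozenset(cat.name for _, cat in matched)
                return ClassificationResult(cats, TIER_REFERENCE, tuple(matched))

        # (2) author-stated category label(s)
        if author_category and author_category.strip():
            labels = [
                part
                for chunk in author_category.split(",")
                for part in chunk.split(" and ")
            ]
            try:
                defs = [
                    (lab.strip(), self.taxonomy.resolve_category_label(lab))
                    for lab in labels
                    if lab.strip()
                ]
            except UnknownLabelError:
                defs = []
            if defs:
                cats = frozenset(d.name for _, d in defs)
                if cats == {NOT_REPORTED}:
                    return _not_reported(tuple(defs))
                result = ClassificationResult(
                    cats - {NOT_REPORTED}, TIER_AUTHOR, tuple(defs)
                )
                return self._apply_admixture_rule(result) if admixed_kw else result

        # (3) descriptor matching on the detailed description
        if norm_desc:
            try:
                result = self.classify_descriptor(description)
            except UnclassifiedDescriptorError:
                if admixed_kw:
                    # known to be admixed, components unknown
                    return ClassificationResult(
                        frozenset({OTHER_ADMIXED}), TIER_LEXICON
                    )
                result = None
            if result is not None and result.tier != TIER_NOT_REPORTED:
                return self._apply_admixture_rule(result) if admixed_kw else result

        # (4) country-of-recruitment inference
        if country_of_recruitment and country_of_recruitment.strip():
            try:
                return self.infer_from_country(country_of_recruitment)
            except UnknownCountryError:
                pass

        # (5) nothing usable
        return _not_reported()


#: Shared default classifier (packaged taxonomy, lexicon and country table).
DEFAULT_MAPPER = LexiconMapper()


def classify_descriptor(text: str) -> ClassificationResult:
    """Classify a descriptor with the default mapper."""
    return DEFAULT_MAPPER.classify_descriptor(text)


def infer_from_country(country: str) -> ClassificationResult:
    """Country-of-recruitment inference with the default mapper."""
    return DEFAULT_MAPPER.infer_from_country(country)


def classify_sample(
    author_category: str | None = None,
    description: str = "",
    population_codes: Sequence[str] = (),
    country_of_recruitment: str | None = None,
) -> ClassificationResult:
    """Cascade classification of one sample with the default mapper."""
    return DEFAULT_MAPPER.classify_sample(
        author_category, description, population_codes, country_of_recruitment
    )
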