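"""Descriptor classification and the sample evidence cascade."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ancestrykit import (
    classify_descriptor,
    classify_sample,
    infer_from_country,
    normalize_descriptor,
)
from ancestrykit.errors import UnclassifiedDescriptorError, UnknownCountryError
from ancestrykit.lexicon import (
    DEFAULT_MAPPER,
    TIER_ORDER,
    LexiconEntry,
)

GME = "Greater Middle Eastern (Middle Eastern, North African, or Persian)"


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("  Han  Chinese. ", "han chinese"),
        ("", ""),
        ("African-American", "african american"),
        ("PUNJABI   SIKH", "punjabi sikh"),
        ("Costa‐Rican", "costa rican"),  # non-ASCII hyphen
    ],
)
def test_normalize_descriptor(raw, expected):
    assert normalize_descriptor(raw) == expected
    assert normalize_descriptor(normalize_descriptor(raw)) == normalize_descriptor(raw)


@pytest.mark.parametrize(
    "text, categories",
    [
        ("Han Chinese", {"East Asian"}),
        ("Punjabi Sikh", {"South Asian"}),
        ("Yoruban", {"Sub-Saharan African"}),
        ("Surinamese", {"Other"}),
        ("Caucasian", {"European"}),
        ("Tunisian", {GME}),
        ("European and Japanese", {"European", "East Asian"}),
        ("African American", {"African American or Afro-Caribbean"}),
        ("African", {"African unspecified"}),
    ],
)
def test_classify_descriptor(text, categories):
    result = classify_descriptor(text)
    assert result.categories == frozenset(categories)
    assert result.tier == "lexicon"


def test_classify_descriptor_empty_is_not_reported():
    result = classify_descriptor("   ")
    assert result.categories == frozenset({"Not reported"})
    assert result.tier == "not-reported"


def test_unclassified_descriptor_raises_not_other():
    with pytest.raises(UnclassifiedDescriptorError):
        classify_descriptor("Klingon warrior")


def test_ethnocultural_flag_carried_in_provenance():
    result = classify_descriptor("Punjabi Sikh")
    entries = [e for _, e in result.matched_terms if isinstance(e, LexiconEntry)]
    assert entries and entries[0].ethnocultural


def _ngram_oracle(text, max_n=4):
    """Brute-force longest-match oracle: enumerate every n-gram of the
    normalized text, greedily consume from the left preferring longer
    fragments, and collect the categories matched via lexicon, vocabulary
    labels, or population codes."""
    mapper = DEFAULT_MAPPER
    tokens = normalize_descriptor(text).split()
    cats, i = set(), 0
    while i < len(tokens):
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            frag = " ".join(tokens[i : i + n])
            hit = mapper._lookup_fragment(frag)
            if hit is not None:
                cats.add(hit.category if isinstance(hit, LexiconEntry) else hit.name)
                i += n
                break
        else:
            i += 1
    return cats


@pytest.mark.parametrize(
    "text",
    [
        "European and Japanese",
        "African American and African samples",
        "Punjabi Sikh South Asian",
        "Old Order Amish individuals of European descent",
        "Sri Lankan Sinhalese and Han Chinese",
    ],
)
def test_multi_match_agrees_with_ngram_oracle(text):
    assert classify_descriptor(text).categories == frozenset(_ngram_oracle(text))


def test_lexicon_self_consistency_sweep():
    """Every shipped descriptor classifies back to exactly its own category."""
    for entry in DEFAULT_MAPPER.lexicon_entries:
        result = classify_descriptor(entry.descriptor)
        assert result.categories == frozenset({entry.category}), entry.descriptor


# ----------------------------------------------------------------------
# country inference

def test_infer_from_country():
    assert infer_from_country("Japan").categories == frozenset({"East Asian"})
    assert infer_from_country("Japan").tier == "country-inferred"
    assert infer_from_country("japan ").categories == frozenset({"East Asian"})


def test_heterogeneous_country_yields_not_reported():
    result = infer_from_country("United States")
    assert result.categories == frozenset({"Not reported"})
    assert result.tier == "not-reported"


def test_unknown_country_raises():
    with pytest.raises(UnknownCountryError):
        infer_from_country("Narnia")


# ----------------------------------------------------------------------
# cascade

def test_reference_population_outranks_everything():
    result = classify_sample(
        author_category="East Asian",
        description="Yoruban",
        population_codes=["CEU"],
        country_of_recruitment="Japan",
    )
    assert result.categories == frozenset({"European"})
    assert result.tier == "reference-population"


def test_author_category_outranks_description():
    result = classify_sample(author_category="South Asian", description="Han Chinese")
    assert result.categories == frozenset({"South Asian"})
    assert result.tier == "author-stated"


def test_description_outranks_country():
    result = classify_sample(description="Han Chinese", country_of_recruitment="Japan")
    assert result.categories == frozenset({"East Asian"})
    assert result.tier == "lexicon"


def test_country_fallback_and_final_not_reported():
    assert classify_sample(country_of_recruitment="Japan").tier == "country-inferred"
    empty = classify_sample()
    assert empty.categories == frozenset({"Not reported"})
    assert empty.tier == "not-reported"


def test_admixed_description_maps_to_other_admixed():
    result = classify_sample(
        description="admixed individuals of European and East Asian descent"
    )
    assert result.categories == frozenset({"Other admixed ancestry"})
    assert set(result.admixture_components) == {"European", "East Asian"}


def test_admixed_keyword_keeps_defined_admixed_category():
    result = classify_sample(description="admixed African American individuals")
    assert result.categories == frozenset({"African American or Afro-Caribbean"})


def test_isolate_population_classified_with_flag():
    result = classify_sample(description="Old Order Amish")
    assert result.categories == frozenset({"European"})
    assert any(
        isinstance(e, LexiconEntry) and e.isolate for _, e in result.matched_terms
    )


def test_unclassifiable_description_falls_through_to_country():
    result = classify_sample(description="Qo'noS warriors", country_of_recruitment="Japan")
    assert result.categories == frozenset({"East Asian"})
    assert result.tier == "country-inferred"


_DESCRIPTIONS = st.sampled_from(
    ["", "Han Chinese", "Yoruban", "Klingon", "Old Order Amish", "European and Japanese"]
)
_AUTHOR = st.sampled_from([None, "European", "South Asian", "nonsense label"])
_COUNTRY = st.sampled_from([None, "Japan", "United States", "Narnia"])


@settings(derandomize=True, max_examples=200)
@given(author=_AUTHOR, desc=_DESCRIPTIONS, country=_COUNTRY, code=st.sampled_from(["CEU", "YRI", "JPT"]))
def test_adding_population_code_never_lowers_tier(author, desc, country, code):
    without = classify_sample(author, desc, [], country)
    with_code = classify_sample(author, desc, [code], country)
    assert TIER_ORDER.index(with_code.tier) <= TIER_ORDER.index(without.tier)
    # and the cascade is deterministic
    assert classify_sample(author, desc, [], country) == without


def test_not_reported_iff_no_usable_evidence():
    # every single-source input that resolves to a category avoids Not reported
    assert classify_sample(author_category="European").tier == "author-stated"
    assert classify_sample(description="Yoruban").tier == "lexicon"
    assert classify_sample(population_codes=["JPT"]).tier == "reference-population"
    assert classify_sample(country_of_recruitment="Kenya").tier == "country-inferred"
    # unresolvable or empty evidence everywhere -> Not reported
    for kwargs in (
        {},
        {"author_category": "nonsense"},
        {"description": "Klingon"},
        {"country_of_recruitment": "Narnia"},
        {"author_category": "nonsense", "description": "Klingon",
         "country_of_recruitment": "Narnia"},
    ):
        assert classify_sample(**kwargs).categories == frozenset({"Not reported"})
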