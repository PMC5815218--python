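"""Diversity distributions, window comparisons and trait breadth."""

from collections import Counter

import pytest

from ancestrykit import (
    AssociationRecord,
    WindowSpec,
    compare_windows,
    distribution_by_category,
    generate_catalog,
    load_supergroup_map,
    trait_breadth,
)
from ancestrykit.diversity import MULTIPLE, label_for_categories
from ancestrykit.errors import DanglingAccessionError, UnknownTraitError
from ancestrykit.synthetic import SimulationConfig

from conftest import make_sample, make_study


def test_single_study_all_european():
    study = make_study(n=100)
    report = distribution_by_category([study], level="individuals")
    assert report.counts == {"European": 100}
    assert report.percentages["European"] == pytest.approx(100.0)


def test_toy_catalog_study_distribution():
    """Hand-counted: 3 European-only, 1 East-Asian-only, 1 two-category."""
    studies = [make_study(accession=f"E{i}") for i in range(3)]
    studies.append(
        make_study(accession="A1", description="Han Chinese",
                   categories=("East Asian",), countries=("China",))
    )
    studies.append(
        make_study(accession="M1", categories=("European", "East Asian",),
                   description="European and Japanese")
    )
    report = distribution_by_category(studies, level="studies")
    assert report.counts == {"East Asian": 1, "European": 3, MULTIPLE: 1}
    pct = report.percentages
    assert pct["European"] == pytest.approx(60.0)
    assert pct["East Asian"] == pytest.approx(20.0)
    assert pct[MULTIPLE] == pytest.approx(20.0)


def test_not_reported_does_not_trigger_multiple():
    study = make_study(samples=[
        make_sample(categories=("European",)),
        make_sample(categories=("Not reported",), description="", stage="replication"),
    ])
    report = distribution_by_category([study], level="studies")
    assert report.counts == {"European": 1}


def test_association_annotation_overrides_study_label():
    study = make_study(categories=("European",))
    assocs = [
        AssociationRecord("A1", study.study_accession, "height",
                          frozenset({"East Asian"})),
        AssociationRecord("A2", study.study_accession, "height"),
    ]
    report = distribution_by_category([study], assocs, level="associations")
    assert report.counts == {"East Asian": 1, "European": 1}


def test_dangling_accession_raises():
    study = make_study()
    assocs = [AssociationRecord("A1", "GCST_MISSING", "height")]
    with pytest.raises(DanglingAccessionError):
        distribution_by_category([study], assocs, level="associations")


def test_window_filters_by_publication_year():
    early = make_study(accession="G1", year=2007)
    late = make_study(accession="G2", year=2014,
                      description="Han Chinese", categories=("East Asian",))
    report = distribution_by_category(
        [early, late], level="studies", window=WindowSpec(2005, 2010)
    )
    assert report.counts == {"European": 1}


def test_supergroup_collapse_sums_members():
    studies = [
        make_study(accession="G1", description="Han Chinese", categories=("East Asian",)),
        make_study(accession="G2", description="Indian", categories=("South Asian",)),
        make_study(accession="G3"),
    ]
    report = distribution_by_category(
        studies, level="studies", supergroup_map=load_supergroup_map()
    )
    assert report.counts == {"European": 1, "Asian": 2}


def test_identical_windows_fold_is_one():
    studies = [make_study(accession=f"G{i}", year=2010 + i % 3) for i in range(6)]
    window = WindowSpec(2009, 2014)
    rows = compare_windows(studies, None, "studies", window, window)
    for label, (a, b, fold) in rows.items():
        if a > 0:
            assert fold == pytest.approx(1.0)


def test_fold_undefined_when_label_absent_from_first_window():
    early = make_study(accession="G1", year=2007)
    late = make_study(accession="G2", year=2014,
                      description="Yoruban", categories=("Sub-Saharan African",))
    rows = compare_windows(
        [early, late], None, "studies", WindowSpec(2005, 2010), WindowSpec(2011, 2016)
    )
    assert rows["Sub-Saharan African"][2] is None


def test_conservation_counts_sum_to_n():
    studies, assocs, _ = generate_catalog(SimulationConfig(n_studies=80, seed=3))
    for level, a in (("individuals", None), ("studies", None), ("associations", assocs)):
        report = distribution_by_category(studies, a, level)
        assert sum(report.counts.values()) == report.n
        assert sum(report.percentages.values()) == pytest.approx(100.0, abs=0.1)


def _brute_force(studies, assocs, level):
    """Independent enumeration: label every unit by first principles."""

    def unit_label(categories):
        cats = {c for c in categories if c != "Not reported"}
        if len(cats) > 1:
            return "multiple"
        return cats.pop() if cats else "Not reported"

    counts = Counter()
    if level == "individuals":
        for study in studies:
            for s in study.samples:
                counts[unit_label(s.categories)] += s.n_individuals or 0
    elif level == "studies":
        for study in studies:
            union = set()
            for s in study.samples:
                union.update(s.categories)
            counts[unit_label(union)] += 1
    else:
        labels = {}
        for study in studies:
            union = set()
            for s in study.samples:
                union.update(s.categories)
            labels[study.study_accession] = unit_label(union)
        for a in assocs:
            if a.ancestry_annotation:
                counts[unit_label(a.ancestry_annotation)] += 1
            else:
                counts[labels[a.study_accession]] += 1
    return {k: v for k, v in counts.items() if v}


def test_oracle_equivalence_on_small_catalogs():
    """Engine output equals brute-force enumeration on catalogs of <= 10
    studies across 50 random seeds."""
    for seed in range(50):
        cfg = SimulationConfig(n_studies=seed % 11, seed=seed)
        studies, assocs, _ = generate_catalog(cfg)
        for level, a in (
            ("individuals", None),
            ("studies", None),
            ("associations", assocs),
        ):
            report = distribution_by_category(studies, a, level)
            assert dict(report.counts) == _brute_force(studies, assocs, level), (
                seed,
                level,
            )


def test_adding_european_study_never_decreases_european_count():
    studies, _, _ = generate_catalog(SimulationConfig(n_studies=30, seed=5))
    before = distribution_by_category(studies, level="studies").counts.get("European", 0)
    extra = make_study(accession="EXTRA1")
    after = distribution_by_category(
        list(studies) + [extra], level="studies"
    ).counts.get("European", 0)
    assert after == before + 1


def test_trait_breadth_single_study():
    study = make_study(trait="height")
    assocs = [AssociationRecord(f"A{i}", study.study_accession, "height") for i in range(4)]
    tb = trait_breadth([study], assocs, "height")
    assert (tb.n_detailed_descriptions, tb.n_categories, tb.n_studies,
            tb.n_associations) == (1, 1, 1, 4)


def test_trait_breadth_matches_generator_bookkeeping():
    studies, assocs, truth = generate_catalog(SimulationConfig(n_studies=60, seed=11))
    for trait, expected in truth.per_trait.items():
        tb = trait_breadth(studies, assocs, trait)
        assert tb.n_studies == expected["n_studies"]
        assert tb.n_associations == expected["n_associations"]
        assert tb.n_categories == expected["n_categories"]
        assert tb.n_detailed_descriptions == expected["n_detailed_descriptions"]


def test_unknown_trait_raises():
    with pytest.raises(UnknownTraitError):
        trait_breadth([make_study()], [], "flux capacitance")


def test_label_for_categories_rules():
    assert label_for_categories({"European"}) == "European"
    assert label_for_categories({"European", "East Asian"}) == MULTIPLE
    assert label_for_categories({"European", "Not reported"}) == "European"
    assert label_for_categories({"Not reported"}) == "Not reported"
    assert label_for_categories(set()) == "Not reported"
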