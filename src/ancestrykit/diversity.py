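"""Category-level diversity statistics over a catalog.

The engine answers "who is being studied?" at three levels:

* **individuals** — every sample contributes its participant count to its
  category (to "multiple" when the sample itself spans more than one
  category);
* **studies** — a study counts toward the single category analyzed in all
  of its samples, toward "multiple" when its samples span more than one
  distinct category, and toward "Not reported" when none is known;
* **associations** — an association uses its own ancestry annotation when
  present, otherwise it inherits its study's label.

"Not reported" never triggers "multiple": a study with one real category
plus unreported samples still counts under that category. Individuals are
summed over both study stages and across studies without deduplication, so
cohorts reused across publications are counted each time (a known upward
bias toward heavily reused cohorts, documented in the methods note).

Time windows select studies by publication year (inclusive bounds), and a
supergroup map may collapse category labels (e.g. all Asian categories into
"Asian") before percentages are formed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._text import normalize_descriptor
from .catalog_io import (
    NOT_REPORTED,
    AssociationRecord,
    SampleRecord,
    StudyRecord,
)
from .errors import DanglingAccessionError, UnknownTraitError
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy

MULTIPLE = "multiple"

LEVEL_INDIVIDUALS = "individuals"
LEVEL_STUDIES = "studies"
LEVEL_ASSOCIATIONS = "associations"
LEVELS = (LEVEL_INDIVIDUALS, LEVEL_STUDIES, LEVEL_ASSOCIATIONS)


@dataclass(frozen=True)
class WindowSpec:
    """An inclusive publication-year window."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError("window start_year must not exceed end_year")

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass(frozen=True)
class DiversityReport:
    """Per-label counts and percentages at one analysis level."""

    level: str
    counts: dict[str, int]
    n: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n == 0:
            return {label: 0.0 for label in self.counts}
        return {label: 100.0 * c / self.n for label, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: label, count, percentage."""
        pct = self.percentages
        return pd.DataFrame(
            {
                "label": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [pct[k] for k in self.counts],
            }
        )


@dataclass(frozen=True)
class TraitBreadth:
    """How broadly one trait has been studied across ancestral backgrounds."""

    trait: str
    n_detailed_descriptions: int
    n_categories: int
    n_studies: int
    n_associations: int


# ----------------------------------------------------------------------
# labelling

def label_for_categories(categories: Iterable[str]) -> str:
    """Collapse a category set to one display label.

    More than one distinct category (ignoring "Not reported") is
    "multiple"; exactly one is that category; none is "Not reported".
    """
    real = set(categories) - {NOT_REPORTED}
    if len(real) > 1:
        return MULTIPLE
    if len(real) == 1:
        return next(iter(real))
    return NOT_REPORTED


def study_label(study: StudyRecord) -> str:
    """Display label of a whole study (union of its samples' categories)."""
    union: set[str] = set()
    for sample in study.samples:
        union |= sample.categories
    return label_for_categories(union)


def _collapse(label: str, member_to_group: Mapping[str, str]) -> str:
    return member_to_group.get(label, label)


def _ordered_counts(
    counter: Counter, taxonomy: Taxonomy, extra_labels: Iterable[str]
) -> dict[str, int]:
    order = list(taxonomy.names) + [MULTIPLE] + [
        lab for lab in extra_labels if lab not in taxonomy.names
    ]
    seen = {}
    for label in order:
        if label in counter and label not in seen:
            seen[label] = counter[label]
    for label in counter:  # any label outside the canonical order, stably last
        if label not in seen:
            seen[label] = counter[label]
    return seen


# ----------------------------------------------------------------------
# distributions

def distribution_by_category(
    studies: Sequence[StudyRecord],
    associations: Sequence[AssociationRecord] | None = None,
    level: str = LEVEL_INDIVIDUALS,
    window: WindowSpec | None = None,
    supergroup_map: Mapping[str, Iterable[str]] | None = None,
) -> DiversityReport:
    """Distribution of a catalog over category labels at one level.

    Parameters
    ----------
    studies
        Parsed study records (samples attached).
    associations
        Required for ``level="associations"``; each association must
        reference a known study accession.
    window
        Optional inclusive publication-year filter.
    supergroup_map
        Optional ``group -> member categories`` map applied to labels
        before counting (the "multiple" and "Not reported" labels are
        never collapsed).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    member_to_group: dict[str, str] = {}
    if supergroup_map:
        for group, members in supergroup_map.items():
            for m in members:
                member_to_group[m] = group

    if window is not None:
        studies = [s for s in studies if window.contains(s.publication_date.year)]

    counter: Counter = Counter()
    n = 0
    if level == LEVEL_INDIVIDUALS:
        for study in studies:
            for sample in study.samples:
                size = sample.n_individuals or 0
                label = _collapse(
                    label_for_categories(sample.categories), member_to_group
                )
                counter[label] += size
                n += size
    elif level == LEVEL_STUDIES:
        for study in studies:
            counter[_collapse(study_label(study), member_to_group)] += 1
            n += 1
    else:
        if associations is None:
            raise ValueError("associations records required at the associations level")
        by_accession = {s.study_accession: s for s in studies}
        kept = set(by_accession)
        for assoc in associations:
            if assoc.study_accession not in by_accession:
                if window is not None:
                    continue  # its study fell outside the window
                raise DanglingAccessionError(assoc.study_accession)
            if assoc.study_accession not in kept:
                continue
            if assoc.ancestry_annotation:
                label = label_for_categories(assoc.ancestry_annotation)
            else:
                label = study_label(by_accession[assoc.study_accession])
            counter[_collapse(label, member_to_group)] += 1
            n += 1

    taxonomy = DEFAULT_TAXONOMY
    return DiversityReport(
        level=level,
        counts=_ordered_counts(counter, taxonomy, member_to_group.values()),
        n=n,
    )


def compare_windows(
    studies: Sequence[StudyRecord],
    associations: Sequence[AssociationRecord] | None,
    level: str,
    window_a: WindowSpec,
    window_b: WindowSpec,
    supergroup_map: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, tuple[float, float, float | None]]:
    """Per-label percentage in two windows and the fold change between them.

    Returns ``label -> (pct_a, pct_b, fold)`` where ``fold = pct_b /
    pct_a``. Labels absent from window A report ``fold=None`` (undefined)
    rather than infinity. Labels appearing in either window are included.
    """
    rep_a = distribution_by_category(
        studies, associations, level, window_a, supergroup_map
    )
    rep_b = distribution_by_category(
        studies, associations, level, window_b, supergroup_map
    )
    pct_a = rep_a.percentages
    pct_b = rep_b.percentages
    out: dict[str, tuple[float, float, float | None]] = {}
    for label in list(pct_a) + [k for k in pct_b if k not in pct_a]:
        a = pct_a.get(label, 0.0)
        b = pct_b.get(label, 0.0)
        fold = (b / a) if a > 0 else None
        out[label] = (a, b, fold)
    return out


def trait_breadth(
    studies: Sequence[StudyRecord],
    associations: Sequence[AssociationRecord],
    trait: str,
) -> TraitBreadth:
    """Ancestry breadth of one trait across the catalog.

    Counts the distinct normalized detailed descriptions, distinct
    categories (excluding "Not reported"), studies and associations
    attached to the trait (matched case-insensitively).
    """
    key = normalize_descriptor(trait)
    trait_studies = [s for s in studies if normalize_descriptor(s.trait) == key]
    trait_assocs = [
        a for a in associations if normalize_descriptor(a.trait) == key
    ]
    if not trait_studies and not trait_assocs:
        raise UnknownTraitError(trait)
    accessions = {s.study_accession for s in trait_studies}
    accessions |= {a.study_accession for a in trait_assocs}
    by_accession = {s.study_accession: s for s in studies}
    descriptions: set[str] = set()
    categories: set[str] = set()
    for acc in accessions:
        study = by_accession.get(acc)
        if study is None:
            continue
        for sample in study.samples:
            d = normalize_descriptor(sample.detailed_description)
            if d:
                descriptions.add(d)
            categories |= sample.categories - {NOT_REPORTED}
    return TraitBreadth(
        trait=trait,
        n_detailed_descriptions=len(descriptions),
        n_categories=len(categories),
        n_studies=len(accessions & set(by_accession)),
        n_associations=len(trait_assocs),
    )
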