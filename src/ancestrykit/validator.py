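"""Lint engine for ancestry-metadata quality.

Ten rules operationalize the reporting recommendations for authors of
genomics studies. Each rule yields a machine-readable
:class:`LintFinding` pointing at the offending sample:

========  ========  ==========================================================
rule id   severity  checks that the sample does NOT ...
========  ========  ==========================================================
R1        info      describe ancestry only at category granularity
                    (e.g. "Sub-Saharan African" where "Yoruban" is possible)
R2        warning   use a country or citizenship as the ancestry descriptor
R3        warning   use a cohort name (e.g. "TwinsUK") as an ancestry proxy
R4        warning   use an ethno-cultural term ("Punjabi Sikh") without a
                    genetic/genealogical qualifier
R5        warning   name a founder/isolate population ("Old Order Amish")
                    without its broader ancestral background
R6        warning   declare an admixed category without naming the
                    contributing ancestral components
R7        info      omit the ancestry-ascertainment method (self-report,
                    genomic inference, ...)
R8        error     omit the ancestry category entirely
R9        error     omit the sample size
R10       info      omit the country of recruitment
========  ========  ==========================================================

A sample flagged ``confidential`` (explicit non-disclosure) suppresses
R8-R10. Linting is pure: identical input yields identical findings, ordered
by rule id then record position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import yaml

from ._text import normalize_descriptor
from .catalog_io import NOT_REPORTED, SampleRecord, StudyRecord
from .errors import EmptyCatalogError, UnclassifiedDescriptorError
from .lexicon import DEFAULT_MAPPER, LexiconEntry, LexiconMapper

SEVERITY_ERROR = "error"
SEVERITY_WARNING = "warning"
SEVERITY_INFO = "info"

#: rule id -> (severity, short description)
RULE_REGISTRY: dict[str, tuple[str, str]] = {
    "R1": (SEVERITY_INFO, "descriptor no more granular than its category"),
    "R2": (SEVERITY_WARNING, "country or citizenship used as ancestry"),
    "R3": (SEVERITY_WARNING, "cohort name used as ancestry"),
    "R4": (SEVERITY_WARNING, "ethno-cultural term without genetic qualifier"),
    "R5": (SEVERITY_WARNING, "isolate population without broader ancestry"),
    "R6": (SEVERITY_WARNING, "admixed sample without ancestral components"),
    "R7": (SEVERITY_INFO, "ancestry ascertainment method not reported"),
    "R8": (SEVERITY_ERROR, "ancestry category missing"),
    "R9": (SEVERITY_ERROR, "sample size missing"),
    "R10": (SEVERITY_INFO, "country of recruitment missing"),
}

#: additional-description keywords accepted as an ascertainment method (R7)
_METHOD_KEYWORDS = (
    "self-report",
    "self report",
    "self-identified",
    "self identified",
    "pca",
    "principal component",
    "genomic",
    "genotype",
    "inferred",
    "ancestry informative",
    "structure",
)


@dataclass(frozen=True)
class LintFinding:
    rule_id: str
    severity: str
    message: str
    study_accession: str = ""
    row: int = 0

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_REGISTRY:
            raise ValueError(f"unknown lint rule: {self.rule_id}")


@dataclass(frozen=True)
class LintReport:
    """Aggregated findings plus catalog-level completeness summaries."""

    findings: tuple[LintFinding, ...]
    per_rule_counts: dict[str, int]
    fraction_no_ancestry: float
    n_studies: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_no_ancestry <= 1.0:
            raise ValueError("fraction_no_ancestry must lie in [0, 1]")

    @property
    def n_errors(self) -> int:
        return sum(1 for f in self.findings if f.severity == SEVERITY_ERROR)


def _load_packaged_cohorts() -> tuple[str, ...]:
    text = resources.files("ancestrykit").joinpath("data", "cohorts.yaml")
    return tuple(yaml.safe_load(text.read_text("utf-8"))["cohorts"])


class Linter:
    """Applies the rule registry to sample records.

    Parameters
    ----------
    mapper
        Classifier supplying the lexicon (term flags for R1/R4/R5), the
        country table (R2) and the taxonomy.
    cohort_names
        Names whose geographic part must not be read as ancestry (R3);
        defaults to the packaged seed list.
    """

    def __init__(
        self,
        mapper: LexiconMapper | None = None,
        cohort_names: Sequence[str] | None = None,
    ):
        self.mapper = mapper if mapper is not None else DEFAULT_MAPPER
        if cohort_names is None:
            cohort_names = _load_packaged_cohorts()
        self._cohorts = tuple(normalize_descriptor(c) for c in cohort_names)
        self._category_labels = set()
        for cat in self.mapper.taxonomy.list_categories():
            self._category_labels.add(normalize_descriptor(cat.name))
            self._category_labels.update(
                normalize_descriptor(s) for s in cat.synonyms
            )
        self._admixed_names = frozenset(
            c.name for c in self.mapper.taxonomy.list_categories() if c.admixed
        )

    # ------------------------------------------------------------------
    def lint_sample(self, sample: SampleRecord, row: int = 0) -> list[LintFinding]:
        """All findings for one sample, ordered by rule id."""
        findings: list[LintFinding] = []

        def fire(rule: str, detail: str) -> None:
            severity, summary = RULE_REGISTRY[rule]
            findings.append(
                LintFinding(
                    rule, severity, f"{summary}: {detail}",
                    sample.study_accession, row,
                )
            )

        desc_norm = normalize_descriptor(sample.detailed_description)
        try:
            matched = (
                self.mapper.classify_descriptor(sample.detailed_description)
                .matched_terms
                if desc_norm
                else ()
            )
        except UnclassifiedDescriptorError:
            matched = ()
        lexicon_hits = [e for _, e in matched if isinstance(e, LexiconEntry)]
        # a category-name/synonym match inside the description counts as a
        # stated broader ancestry (qualifies isolates and ethnocultural terms)
        has_broader = any(
            not isinstance(e, LexiconEntry) for _, e in matched
        ) or any(
            not (e.ethnocultural or e.isolate) for e in lexicon_hits
        )

        # R1: description is nothing but a category label
        if desc_norm and desc_norm in self._category_labels:
            fire("R1", f"{sample.detailed_description!r}")

        # R2: description is (or contains only) a known country name
        if desc_norm:
            try:
                self.mapper.infer_from_country(sample.detailed_description)
            except Exception:
                pass
            else:
                fire("R2", f"{sample.detailed_description!r}")

        # R3: description mentions a known cohort name
        for cohort in self._cohorts:
            if cohort and cohort in desc_norm:
                fire("R3", f"mentions cohort {cohort!r}")
                break

        # R4 / R5: flagged lexicon terms without a broader ancestry statement
        for entry in lexicon_hits:
            if entry.ethnocultural and not has_broader:
                fire("R4", f"{entry.descriptor!r}")
                break
        for entry in lexicon_hits:
            if entry.isolate and not has_broader:
                fire("R5", f"{entry.descriptor!r}")
                break

        # R6: admixed category without components anywhere in the record
        if sample.categories & self._admixed_names:
            component_cats = {
                (e.category if isinstance(e, LexiconEntry) else e.name)
                for _, e in matched
            } - self._admixed_names - {NOT_REPORTED}
            if not component_cats:
                fire("R6", "no contributing ancestral backgrounds recorded")

        # R7: no ascertainment method recorded
        extra_norm = normalize_descriptor(sample.additional_description)
        blob = f"{desc_norm} {extra_norm}"
        if not any(kw in blob for kw in _METHOD_KEYWORDS):
            fire("R7", "no self-report/genomic-method statement found")

        if not sample.confidential:
            # R8: category missing
            if sample.categories == frozenset({NOT_REPORTED}):
                fire("R8", "no ancestry category assigned")
            # R9: sample size missing
            if not sample.n_individuals:
                fire("R9", "number of individuals absent or zero")
            # R10: recruitment country missing
            if not sample.country_of_recruitment:
                fire("R10", "no country of recruitment recorded")

        findings.sort(key=lambda f: (int(f.rule_id[1:]), f.row))
        return findings

    def lint_catalog(self, studies: Iterable[StudyRecord]) -> LintReport:
        """Lint every sample of every study and summarize completeness.

        ``fraction_no_ancestry`` is the share of studies whose every sample
        is "Not reported" — the studies carrying no usable ancestry
        information at all.
        """
        studies = list(studies)
        if not studies:
            raise EmptyCatalogError("cannot lint an empty catalog")
        findings: list[LintFinding] = []
        n_blank = 0
        row = 1
        for study in studies:
            if all(
                s.categories == frozenset({NOT_REPORTED}) for s in study.samples
            ):
                n_blank += 1
            for sample in study.samples:
                row += 1
                findings.extend(self.lint_sample(sample, row=row))
        findings.sort(key=lambda f: (int(f.rule_id[1:]), f.row))
        counts = {rule: 0 for rule in RULE_REGISTRY}
        for f in findings:
            counts[f.rule_id] += 1
        return LintReport(
            findings=tuple(findings),
            per_rule_counts=counts,
            fraction_no_ancestry=n_blank / len(studies),
            n_studies=len(studies),
        )


#: Shared default linter over the packaged seeds.
DEFAULT_LINTER = Linter()


def lint_sample(sample: SampleRecord, row: int = 0) -> list[LintFinding]:
    """Lint one sample with the default linter."""
    return DEFAULT_LINTER.lint_sample(sample, row)


def lint_catalog(studies: Iterable[StudyRecord]) -> LintReport:
    """Lint a catalog with the default linter."""
    return DEFAULT_LINTER.lint_catalog(studies)
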