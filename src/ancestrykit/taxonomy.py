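"""Controlled vocabulary of ancestry categories.

The vocabulary comprises 17 categories, each a distinct regional population
grouping with characteristic patterns of genetic variation (plus the
bookkeeping categories "Not reported", "Other" and "Other admixed
ancestry"). Each category carries a definition, author-used synonyms
(e.g. "Caucasian" and "white" for European), example detailed descriptors,
an admixture flag, and the 1000 Genomes / HapMap phase-3 reference
populations whose members are assigned to it (27 cohort codes in total,
pairwise disjoint across categories).

Categories can be aggregated for display into *supergroups* (e.g. "Asian"
covering the East/South/South-East/Central/unspecified Asian categories);
supergroups are analysis-time maps, not vocabulary members.

The hierarchy (root -> supergroups -> categories) can be exported as an
OBO 1.4 flat file for use in search interfaces and ontology tooling.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

from ._text import normalize_descriptor
from .errors import UnknownCodeError, UnknownLabelError

#: Prefix used for term identifiers in the OBO export.
OBO_NAMESPACE = "ANCAT"

#: Name of the synthetic root term of the exported hierarchy.
OBO_ROOT_NAME = "ancestry category"


@dataclass(frozen=True)
class CategoryDefinition:
    """One controlled ancestry category."""

    name: str
    definition: str
    synonyms: frozenset[str] = field(default_factory=frozenset)
    reference_populations: frozenset[str] = field(default_factory=frozenset)
    example_descriptors: frozenset[str] = field(default_factory=frozenset)
    admixed: bool = False
    parent: str | None = None

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return self.name


def _load_packaged_yaml(name: str) -> dict:
    text = resources.files("ancestrykit").joinpath("data", name).read_text("utf-8")
    return yaml.safe_load(text)


def load_supergroup_map(path: str | None = None) -> dict[str, tuple[str, ...]]:
    """Load a supergroup map (group label -> member category names).

    With no *path*, the packaged default is returned: Asian and African
    aggregates as used in category-distribution displays.
    """
    if path is None:
        raw = _load_packaged_yaml("supergroups.yaml")
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return {group: tuple(members) for group, members in raw["supergroups"].items()}


class Taxonomy:
    """The category vocabulary with label and reference-population lookup.

    Parameters
    ----------
    categories
        Category definitions in display order. When omitted, the packaged
        seed vocabulary (the 17 standard categories) is loaded.
    """

    def __init__(self, categories: Iterable[CategoryDefinition] | None = None):
        if categories is None:
            categories = self._packaged_categories()
        self._categories: tuple[CategoryDefinition, ...] = tuple(categories)
        self._by_label: dict[str, CategoryDefinition] = {}
        self._by_code: dict[str, CategoryDefinition] = {}
        for cat in self._categories:
            for label in (cat.name, *cat.synonyms):
                key = normalize_descriptor(label)
                existing = self._by_label.get(key)
                if existing is not None and existing is not cat:
                    raise ValueError(
                        f"label {label!r} is ambiguous between categories "
                        f"{existing.name!r} and {cat.name!r}"
                    )
                self._by_label[key] = cat
            for code in cat.reference_populations:
                key = code.upper()
                if key in self._by_code:
                    raise ValueError(f"reference population {code} assigned twice")
                self._by_code[key] = cat

    @staticmethod
    def _packaged_categories() -> list[CategoryDefinition]:
        raw = _load_packaged_yaml("categories.yaml")
        out = []
        for rec in raw["categories"]:
            out.append(
                CategoryDefinition(
                    name=rec["name"],
                    definition=rec.get("definition", "").strip(),
                    synonyms=frozenset(rec.get("synonyms", [])),
                    reference_populations=frozenset(
                        rec.get("reference_populations", [])
                    ),
                    example_descriptors=frozenset(
                        rec.get("example_descriptors", [])
                    ),
                    admixed=bool(rec.get("admixed", False)),
                    parent=rec.get("parent"),
                )
            )
        return out

    # ------------------------------------------------------------------
    def list_categories(self) -> list[CategoryDefinition]:
        """All category definitions in canonical display order."""
        return list(self._categories)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self._categories)

    def __contains__(self, name: str) -> bool:
        return normalize_descriptor(name) in self._by_label

    def resolve_category_label(self, label: str) -> CategoryDefinition:
        """Resolve a category name or synonym, case/whitespace-insensitively.

        Raises :class:`UnknownLabelError` naming the nearest candidate
        labels when nothing matches.
        """
        key = normalize_descriptor(label)
        if not key:
            raise UnknownLabelError(label)
        try:
            return self._by_label[key]
        except KeyError:
            candidates = difflib.get_close_matches(key, self._by_label, n=3)
            raise UnknownLabelError(
                label, [self._by_label[c].name for c in candidates]
            ) from None

    def category_for_population_code(self, code: str) -> CategoryDefinition:
        """Category whose reference populations include *code* (e.g. ``YRI``)."""
        try:
            return self._by_code[code.strip().upper()]
        except KeyError:
            raise UnknownCodeError(code) from None

    @property
    def population_codes(self) -> frozenset[str]:
        return frozenset(self._by_code)

    # ------------------------------------------------------------------
    def export_obo(
        self, supergroups: Mapping[str, Iterable[str]] | None = None
    ) -> str:
        """Serialize the hierarchy as an OBO 1.4 flat file.

        One ``[Term]`` stanza per category, per supergroup and for the root;
        every non-root term has exactly one ``is_a``; synonyms are emitted
        as EXACT synonyms. Identifiers are zero-padded sequential within the
        :data:`OBO_NAMESPACE` prefix, assigned in sorted-name order so the
        export is stable across runs and insertions.
        """
        if supergroups is None:
            supergroups = load_supergroup_map()
        member_to_group: dict[str, str] = {}
        for group, members in supergroups.items():
            for m in members:
                if m in member_to_group:
                    raise ValueError(f"category {m!r} appears in two supergroups")
                member_to_group[m] = group

        names = [OBO_ROOT_NAME]
        names += sorted(supergroups)
        names += sorted(c.name for c in self._categories)
        ids = {name: f"{OBO_NAMESPACE}:{i + 1:07d}" for i, name in enumerate(names)}

        lines = [
            "format-version: 1.4",
            f"ontology: {OBO_NAMESPACE.lower()}",
            "",
        ]

        def stanza(name: str, parent: str | None, syns: Iterable[str] = ()) -> None:
            lines.append("[Term]")
            lines.append(f"id: {ids[name]}")
            lines.append(f"name: {name}")
            for syn in sorted(syns):
                lines.append(f'synonym: "{syn}" EXACT []')
            if parent is not None:
                lines.append(f"is_a: {ids[parent]} ! {parent}")
            lines.append("")

        stanza(OBO_ROOT_NAME, None)
        for group in sorted(supergroups):
            stanza(group, OBO_ROOT_NAME)
        for cat in sorted(self._categories, key=lambda c: c.name):
            stanza(cat.name, member_to_group.get(cat.name, OBO_ROOT_NAME), cat.synonyms)
        return "\n".join(lines)


#: Shared default vocabulary instance (the packaged seed).
DEFAULT_TAXONOMY = Taxonomy()


def list_categories() -> list[CategoryDefinition]:
    """Categories of the default vocabulary, in display order."""
    return DEFAULT_TAXONOMY.list_categories()


def resolve_category_label(label: str) -> CategoryDefinition:
    """Resolve *label* against the default vocabulary."""
    return DEFAULT_TAXONOMY.resolve_category_label(label)


def category_for_population_code(code: str) -> CategoryDefinition:
    """Resolve a 1000 Genomes / HapMap cohort code against the default vocabulary."""
    return DEFAULT_TAXONOMY.category_for_population_code(code)


def export_obo(supergroups: Mapping[str, Iterable[str]] | None = None) -> str:
    """OBO export of the default vocabulary."""
    return DEFAULT_TAXONOMY.export_obo(supergroups)
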