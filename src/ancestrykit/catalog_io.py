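"""Catalog-style record containers and TSV I/O.

Two tab-separated dialects are supported, mirroring the public GWAS-Catalog
download files:

* the **ancestry file**: one row per analyzed sample (study accession,
  PubMed id, publication date, stage, number of individuals, detailed
  ancestry description, broad ancestral category, countries of origin and
  recruitment, additional description);
* the **associations file**: one row per reported variant-trait
  association (association id, study accession, trait, optional
  per-association ancestry annotation).

The exact header spellings are pinned in ``ANCESTRY_COLUMNS`` /
``ASSOCIATION_COLUMNS``. Multi-valued cells are comma-separated; `` and ``
is additionally accepted as a delimiter on read and normalized to commas on
write. The writer's output round-trips through the reader field-for-field.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._text import normalize_descriptor
from .errors import (
    MalformedValueError,
    MissingColumnError,
    UnknownLabelError,
)
from .taxonomy import DEFAULT_TAXONOMY, Taxonomy

NOT_REPORTED = "Not reported"

STAGE_INITIAL = "initial"
STAGE_REPLICATION = "replication"
STAGES = (STAGE_INITIAL, STAGE_REPLICATION)

#: Ancestry-file column order (fixed; the writer emits exactly these).
ANCESTRY_COLUMNS = (
    "STUDY ACCESSION",
    "PUBMED ID",
    "DATE",
    "STAGE",
    "NUMBER OF INDIVIDUALS",
    "DETAILED ANCESTRY DESCRIPTION",
    "BROAD ANCESTRAL CATEGORY",
    "COUNTRY OF ORIGIN",
    "COUNTRY OF RECRUITMENT",
    "ADDITIONAL ANCESTRY DESCRIPTION",
    "ANCESTRY CONFIDENTIAL",
)

#: Associations-file column order.
ASSOCIATION_COLUMNS = (
    "ASSOCIATION ID",
    "STUDY ACCESSION",
    "DISEASE/TRAIT",
    "ANCESTRY ANNOTATION",
)


@dataclass(frozen=True)
class SampleRecord:
    """One distinct group of samples analyzed in one stage of a study."""

    study_accession: str
    pubmed_id: str
    publication_date: dt.date
    stage: str
    n_individuals: int | None
    detailed_description: str = ""
    categories: frozenset[str] = frozenset({NOT_REPORTED})
    country_of_recruitment: tuple[str, ...] = ()
    country_of_origin: tuple[str, ...] = ()
    additional_description: str = ""
    confidential: bool = False

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.n_individuals is not None and self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        if not self.categories:
            raise ValueError("categories must be non-empty (at least 'Not reported')")


@dataclass(frozen=True)
class StudyRecord:
    """A GWA study: accession, publication metadata, trait, and its samples."""

    study_accession: str
    pubmed_id: str
    publication_date: dt.date
    trait: str = ""
    samples: tuple[SampleRecord, ...] = ()

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.study_accession != self.study_accession:
                raise ValueError(
                    f"sample accession {s.study_accession!r} does not match "
                    f"study {self.study_accession!r}"
                )


@dataclass(frozen=True)
class AssociationRecord:
    """One variant-trait association and its optional ancestry annotation."""

    association_id: str
    study_accession: str
    trait: str = ""
    ancestry_annotation: frozenset[str] = frozenset()


# ----------------------------------------------------------------------
# parsing helpers

_DATE_FORMATS = ("%Y-%m-%d", "%d-%m-%Y", "%d/%m/%Y")


def parse_date(value: str, row: int = 0, column: str = "DATE") -> dt.date:
    """ISO-8601 date, with day-month-year fallback."""
    value = value.strip()
    for fmt in _DATE_FORMATS:
        try:
            return dt.datetime.strptime(value, fmt).date()
        except ValueError:
            continue
    raise MalformedValueError(row, column, value, "not a recognized date")


def split_multivalue(cell: str) -> tuple[str, ...]:
    """Split a multi-valued cell on commas (and `` and ``), trimming items."""
    cell = cell.replace(" and ", ",")
    return tuple(item.strip() for item in cell.split(",") if item.strip())


def _parse_int(cell: str, row: int, column: str) -> int | None:
    cell = cell.strip().replace(",", "")
    if not cell:
        return None
    if not cell.isdigit():
        raise MalformedValueError(row, column, cell, "not a non-negative integer")
    return int(cell)


def resolve_category_cell(cell: str, taxonomy: Taxonomy) -> frozenset[str]:
    """Resolve a (possibly multi-valued) category cell to category names.

    Splits on commas and `` and ``, but re-joins fragments greedily so that
    category names containing commas (e.g. "Greater Middle Eastern (Middle
    Eastern, North African, or Persian)") resolve intact. Raises
    :class:`UnknownLabelError` when a fragment run cannot be resolved.
    """
    try:
        return frozenset({taxonomy.resolve_category_label(cell).name})
    except UnknownLabelError:
        pass
    parts = split_multivalue(cell)
    names: set[str] = set()
    i = 0
    while i < len(parts):
        last_err: UnknownLabelError | None = None
        for j in range(i + 1, len(parts) + 1):
            candidate = ", ".join(parts[i:j])
            try:
                names.add(taxonomy.resolve_category_label(candidate).name)
            except UnknownLabelError as err:
                last_err = err
                continue
            i = j
            break
        else:
            raise last_err if last_err is not None else UnknownLabelError(cell)
    return frozenset(names)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(missing, str(path))
    return df


# ----------------------------------------------------------------------
# ancestry file

def read_ancestry_tsv(
    path: str | Path, taxonomy: Taxonomy | None = None
) -> list[SampleRecord]:
    """Read an ancestry TSV into :class:`SampleRecord` objects.

    Category cells are resolved against *taxonomy* (names or synonyms;
    unresolvable labels raise :class:`UnknownLabelError` naming the row).
    A row with an empty category cell is read as "Not reported".
    """
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    df = _read_tsv(path, ANCESTRY_COLUMNS[:-1])  # confidential column optional
    records: list[SampleRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        cells = dict(zip(df.columns, row))
        rowno = idx  # 1-based file line (header is line 1)
        stage = cells["STAGE"].strip().lower()
        if stage not in STAGES:
            raise MalformedValueError(rowno, "STAGE", cells["STAGE"], "unknown stage")
        cat_cell = cells["BROAD ANCESTRAL CATEGORY"].strip()
        description = cells["DETAILED ANCESTRY DESCRIPTION"].strip()
        if cat_cell:
            try:
                categories = resolve_category_cell(cat_cell, taxonomy)
            except UnknownLabelError as err:
                raise UnknownLabelError(
                    f"row {rowno}: {err.label}", err.candidates
                ) from None
        else:
            # no category recorded (with or without a description): the
            # record is kept and the gap is the validator's business (R8)
            categories = frozenset({NOT_REPORTED})
        records.append(
            SampleRecord(
                study_accession=cells["STUDY ACCESSION"].strip(),
                pubmed_id=cells["PUBMED ID"].strip(),
                publication_date=parse_date(cells["DATE"], rowno),
                stage=stage,
                n_individuals=_parse_int(
                    cells["NUMBER OF INDIVIDUALS"], rowno, "NUMBER OF INDIVIDUALS"
                ),
                detailed_description=description,
                categories=categories,
                country_of_recruitment=split_multivalue(
                    cells["COUNTRY OF RECRUITMENT"]
                ),
                country_of_origin=split_multivalue(cells["COUNTRY OF ORIGIN"]),
                additional_description=cells[
                    "ADDITIONAL ANCESTRY DESCRIPTION"
                ].strip(),
                confidential=cells.get("ANCESTRY CONFIDENTIAL", "").strip().lower()
                in ("yes", "true", "1"),
            )
        )
    return records


def _category_sort_key(taxonomy: Taxonomy):
    order = {name: i for i, name in enumerate(taxonomy.names)}
    return lambda name: (order.get(name, len(order)), name)


def format_categories(
    categories: Iterable[str], taxonomy: Taxonomy | None = None
) -> str:
    """Comma-join categories in canonical vocabulary order."""
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    return ", ".join(sorted(categories, key=_category_sort_key(taxonomy)))


def write_ancestry_tsv(
    records: Iterable[SampleRecord],
    path: str | Path,
    taxonomy: Taxonomy | None = None,
) -> None:
    """Write sample records as an ancestry TSV (UTF-8, Unix newlines).

    The output is bit-stable for a given record list and round-trips
    through :func:`read_ancestry_tsv` field-for-field.
    """
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    rows = []
    for rec in records:
        rows.append(
            {
                "STUDY ACCESSION": rec.study_accession,
                "PUBMED ID": rec.pubmed_id,
                "DATE": rec.publication_date.isoformat(),
                "STAGE": rec.stage,
                "NUMBER OF INDIVIDUALS": (
                    "" if rec.n_individuals is None else str(rec.n_individuals)
                ),
                "DETAILED ANCESTRY DESCRIPTION": rec.detailed_description,
                "BROAD ANCESTRAL CATEGORY": format_categories(
                    rec.categories, taxonomy
                ),
                "COUNTRY OF ORIGIN": ", ".join(rec.country_of_origin),
                "COUNTRY OF RECRUITMENT": ", ".join(rec.country_of_recruitment),
                "ADDITIONAL ANCESTRY DESCRIPTION": rec.additional_description,
                "ANCESTRY CONFIDENTIAL": "yes" if rec.confidential else "",
            }
        )
    df = pd.DataFrame(rows, columns=list(ANCESTRY_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


# ----------------------------------------------------------------------
# associations file

def read_associations_tsv(
    path: str | Path, taxonomy: Taxonomy | None = None
) -> list[AssociationRecord]:
    """Read an associations TSV; annotation labels resolve via *taxonomy*."""
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    df = _read_tsv(path, ASSOCIATION_COLUMNS)
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        cells = dict(zip(df.columns, row))
        ann_cell = cells["ANCESTRY ANNOTATION"].strip()
        annotation: frozenset[str] = frozenset()
        if ann_cell:
            try:
                annotation = resolve_category_cell(ann_cell, taxonomy)
            except UnknownLabelError as err:
                raise UnknownLabelError(
                    f"row {idx}: {err.label}", err.candidates
                ) from None
        records.append(
            AssociationRecord(
                association_id=cells["ASSOCIATION ID"].strip(),
                study_accession=cells["STUDY ACCESSION"].strip(),
                trait=cells["DISEASE/TRAIT"].strip(),
                ancestry_annotation=annotation,
            )
        )
    return records


def write_associations_tsv(
    records: Iterable[AssociationRecord],
    path: str | Path,
    taxonomy: Taxonomy | None = None,
) -> None:
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    rows = [
        {
            "ASSOCIATION ID": rec.association_id,
            "STUDY ACCESSION": rec.study_accession,
            "DISEASE/TRAIT": rec.trait,
            "ANCESTRY ANNOTATION": format_categories(
                rec.ancestry_annotation, taxonomy
            ),
        }
        for rec in records
    ]
    df = pd.DataFrame(rows, columns=list(ASSOCIATION_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


# ----------------------------------------------------------------------
# assembly and display

def build_studies(
    samples: Iterable[SampleRecord],
    associations: Iterable[AssociationRecord] = (),
) -> list[StudyRecord]:
    """Group sample records into studies, taking traits from associations.

    Studies are ordered by first appearance in *samples*. When a study's
    associations carry more than one trait, the first is used as the study
    trait (the per-association traits remain on the association records).
    """
    traits: dict[str, str] = {}
    for assoc in associations:
        traits.setdefault(assoc.study_accession, assoc.trait)
    grouped: dict[str, list[SampleRecord]] = {}
    for sample in samples:
        grouped.setdefault(sample.study_accession, []).append(sample)
    return [
        StudyRecord(
            study_accession=acc,
            pubmed_id=group[0].pubmed_id,
            publication_date=group[0].publication_date,
            trait=traits.get(acc, ""),
            samples=tuple(group),
        )
        for acc, group in grouped.items()
    ]


def format_category_string(
    sample: SampleRecord, taxonomy: Taxonomy | None = None
) -> str:
    """Render the display form: ``size category (country of recruitment)``.

    Example: ``"2,000 East Asian (China)"``. The size is
    thousands-separated; multiple categories or countries are comma-joined;
    the parenthesized recruitment countries are omitted when unknown.
    """
    n = sample.n_individuals if sample.n_individuals is not None else 0
    out = f"{n:,} " + format_categories(sample.categories, taxonomy)
    if sample.country_of_recruitment:
        out += " (" + ", ".join(sample.country_of_recruitment) + ")"
    return out
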