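"""Exception hierarchy.

All package errors derive from :class:`AncestryKitError` so callers can
catch the package's failures with a single handler while still
distinguishing vocabulary, classification, I/O and configuration problems.
"""

from __future__ import annotations


class AncestryKitError(Exception):
    """Base class for all errors raised by ancestrykit."""


class UnknownLabelError(AncestryKitError):
    """A label matched neither a category name nor any synonym."""

    def __init__(self, label: str, candidates: list[str] | None = None):
        self.label = label
        self.candidates = candidates or []
        msg = f"unknown ancestry label: {label!r}"
        if self.candidates:
            msg += f" (nearest candidates: {', '.join(self.candidates)})"
        super().__init__(msg)


class UnknownCodeError(AncestryKitError):
    """A reference-population code is not assigned to any category."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(f"unknown reference-population code: {code!r}")


class UnclassifiedDescriptorError(AncestryKitError):
    """A non-empty descriptor matched nothing in lexicon, vocabulary or codes.

    Deliberately distinct from returning "Other": assignment to "Other"
    records a curator's judgement that a descriptor is known but
    unclassifiable, and must never happen silently.
    """

    def __init__(self, text: str):
        self.text = text
        super().__init__(f"descriptor could not be classified: {text!r}")


class UnknownCountryError(AncestryKitError):
    """A country is absent from the country-of-recruitment table."""

    def __init__(self, country: str):
        self.country = country
        super().__init__(f"unknown country: {country!r}")


class TableFormatError(AncestryKitError):
    """A TSV file violates the expected dialect (row/column named when known)."""


class MissingColumnError(TableFormatError):
    def __init__(self, columns: list[str], path: str = ""):
        self.columns = columns
        where = f" in {path}" if path else ""
        super().__init__(f"missing required column(s){where}: {', '.join(columns)}")


class MalformedValueError(TableFormatError):
    def __init__(self, row: int, column: str, value: str, reason: str):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"row {row}, column {column!r}: cannot parse {value!r} ({reason})"
        )


class UnknownTraitError(AncestryKitError):
    def __init__(self, trait: str):
        self.trait = trait
        super().__init__(f"trait not present in the catalog: {trait!r}")


class InvalidConfigError(AncestryKitError):
    """A simulation or run configuration violates its invariants."""


class EmptyCatalogError(AncestryKitError):
    """An operation that needs at least one study received none."""


class DanglingAccessionError(AncestryKitError):
    def __init__(self, accession: str):
        self.accession = accession
        super().__init__(
            f"association references unknown study accession: {accession!r}"
        )
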