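"""Synthetic catalog generator with exact ground truth.

Generates study, sample and association records that are valid under the
catalog I/O invariants and whose category structure is known by
construction, so the classification, I/O, lint and diversity modules can
be tested end-to-end without any external download.

Each simulated study is, independently:

* **not reported** with probability ``not_reported_fraction`` (no ancestry
  information at all),
* **multi-ancestry** with probability ``multi_ancestry_fraction`` (its
  samples jointly span two distinct categories),
* otherwise **single-category**, the category drawn from
  ``category_weights``.

Every study has an initial sample and, with probability
``replication_probability``, a replication sample; both carry the study's
category set, so the expected number of individuals per study is identical
across study types and the expected label shares coincide at the
individuals, studies and associations levels (see
:func:`expected_distribution`). Sample sizes follow a shifted negative
binomial — a heavy-tailed discrete distribution resembling observed GWAS
cohort sizes. Association counts are shifted-Poisson per study.

The same seed reproduces the same catalog byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .catalog_io import (
    NOT_REPORTED,
    AssociationRecord,
    SampleRecord,
    StudyRecord,
    STAGE_INITIAL,
    STAGE_REPLICATION,
    write_ancestry_tsv,
    write_associations_tsv,
)
from .diversity import MULTIPLE, label_for_categories
from .errors import InvalidConfigError
from .lexicon import DEFAULT_MAPPER
from .taxonomy import DEFAULT_TAXONOMY

#: Default per-study category mixture for single-category studies. Chosen to
#: resemble a modern GWAS repository: a European-ancestry majority, East
#: Asian the largest non-European group, and small shares elsewhere.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "European": 0.55,
    "East Asian": 0.18,
    "South Asian": 0.05,
    "African American or Afro-Caribbean": 0.05,
    "Hispanic or Latin American": 0.04,
    "Sub-Saharan African": 0.03,
    "Asian unspecified": 0.03,
    "African unspecified": 0.02,
    "Greater Middle Eastern (Middle Eastern, North African, or Persian)": 0.02,
    "South East Asian": 0.02,
    "Other": 0.01,
}

#: Representative detailed descriptor used for each generated category.
_DESCRIPTOR_FOR: dict[str, str] = {
    "European": "British",
    "East Asian": "Han Chinese",
    "South Asian": "Indian",
    "African American or Afro-Caribbean": "African American",
    "Hispanic or Latin American": "Mexican",
    "Sub-Saharan African": "Yoruban",
    "Asian unspecified": "Asian",
    "African unspecified": "African",
    "Greater Middle Eastern (Middle Eastern, North African, or Persian)": "Iranian",
    "South East Asian": "Vietnamese",
    "Other": "Surinamese",
    "Oceanian": "Samoan",
    "Central Asian": "Kazakh",
    "Native American": "Pima Indian",
    "Aboriginal Australian": "Martu Australian Aboriginal",
}

#: Recruitment country used for each generated category.
_COUNTRY_FOR: dict[str, str] = {
    "European": "United Kingdom",
    "East Asian": "China",
    "South Asian": "India",
    "African American or Afro-Caribbean": "United States",
    "Hispanic or Latin American": "Mexico",
    "Sub-Saharan African": "Nigeria",
    "Asian unspecified": "United States",
    "African unspecified": "United States",
    "Greater Middle Eastern (Middle Eastern, North African, or Persian)": "Iran",
    "South East Asian": "Vietnam",
    "Other": "Suriname",
    "Oceanian": "Samoa",
    "Central Asian": "Kazakhstan",
    "Native American": "United States",
    "Aboriginal Australian": "Australia",
}

#: Trait pool cycled over generated studies.
DEFAULT_TRAITS = (
    "type 2 diabetes",
    "height",
    "body mass index",
    "coronary artery disease",
    "rheumatoid arthritis",
    "schizophrenia",
    "blood pressure",
    "asthma",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic catalog.

    Defaults describe the emulated repository conditions: a
    European-majority category mixture, a fifth of studies multi-ancestry,
    4% of studies with no ancestry information, publications spanning
    2005-2016, heavy-tailed cohort sizes around 5,000 participants and
    about 13 associations per study.
    """

    n_studies: int = 100
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    multi_ancestry_fraction: float = 0.20
    not_reported_fraction: float = 0.04
    mean_sample_size: float = 5000.0
    sample_size_dispersion: float = 1.0
    mean_associations_per_study: float = 13.0
    replication_probability: float = 0.5
    year_range: tuple[int, int] = (2005, 2016)
    traits: tuple[str, ...] = DEFAULT_TRAITS
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 0:
            raise InvalidConfigError("n_studies must be non-negative")
        needs_weights = self.not_reported_fraction < 1.0
        if needs_weights:
            if not self.category_weights:
                raise InvalidConfigError("category_weights must not be empty")
            total = sum(self.category_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"category_weights must sum to 1 (got {total:.6f})"
                )
            if self.multi_ancestry_fraction > 0 and len(self.category_weights) < 2:
                raise InvalidConfigError(
                    "multi-ancestry studies need at least two weighted categories"
                )
        for frac, name in (
            (self.multi_ancestry_fraction, "multi_ancestry_fraction"),
            (self.not_reported_fraction, "not_reported_fraction"),
            (self.replication_probability, "replication_probability"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.multi_ancestry_fraction + self.not_reported_fraction > 1.0:
            raise InvalidConfigError(
                "multi_ancestry_fraction + not_reported_fraction must be <= 1"
            )
        if self.mean_sample_size <= 0 or self.sample_size_dispersion <= 0:
            raise InvalidConfigError("sample-size parameters must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise InvalidConfigError("year_range must be (start, end) with start <= end")
        unknown = [c for c in self.category_weights if c not in DEFAULT_TAXONOMY]
        if unknown:
            raise InvalidConfigError(f"unknown categories in weights: {unknown}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-label counts of a generated catalog, by analysis level."""

    individuals: dict[str, int]
    studies: dict[str, int]
    associations: dict[str, int]
    per_trait: dict[str, dict[str, int]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "individuals": self.individuals,
                "studies": self.studies,
                "associations": self.associations,
                "per_trait": self.per_trait,
            },
            indent=2,
        )


def _draw_size(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    k = cfg.sample_size_dispersion
    p = k / (k + cfg.mean_sample_size)
    return int(rng.negative_binomial(k, p)) + 1


def generate_catalog(
    config: SimulationConfig | None = None,
) -> tuple[list[StudyRecord], list[AssociationRecord], GroundTruth]:
    """Generate a synthetic catalog with exact bookkeeping.

    Returns study records (samples attached), association records, and the
    :class:`GroundTruth` tallies recorded during generation.
    """
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    names = list(cfg.category_weights)
    weights = np.array([cfg.category_weights[n] for n in names], dtype=float)

    studies: list[StudyRecord] = []
    associations: list[AssociationRecord] = []
    gt_individuals: Counter = Counter()
    gt_studies: Counter = Counter()
    gt_assoc: Counter = Counter()
    per_trait: dict[str, dict] = {}

    assoc_serial = 0
    for i in range(cfg.n_studies):
        accession = f"SYN{i + 1:06d}"
        pubmed = str(20000000 + i)
        year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        date = dt.date(year, month, day)
        trait = cfg.traits[i % len(cfg.traits)] if cfg.traits else ""

        u = rng.random()
        if u < cfg.not_reported_fraction:
            categories = frozenset({NOT_REPORTED})
        elif u < cfg.not_reported_fraction + cfg.multi_ancestry_fraction:
            pair = rng.choice(len(names), size=2, replace=False, p=weights)
            categories = frozenset(names[j] for j in pair)
        else:
            categories = frozenset({names[int(rng.choice(len(names), p=weights))]})
        label = label_for_categories(categories)

        if categories == {NOT_REPORTED}:
            description = ""
            countries: tuple[str, ...] = ()
        else:
            description = " and ".join(
                _DESCRIPTOR_FOR[c] for c in sorted(categories)
            )
            countries = tuple(
                dict.fromkeys(_COUNTRY_FOR[c] for c in sorted(categories))
            )

        samples = [
            SampleRecord(
                study_accession=accession,
                pubmed_id=pubmed,
                publication_date=date,
                stage=STAGE_INITIAL,
                n_individuals=_draw_size(rng, cfg),
                detailed_description=description,
                categories=categories,
                country_of_recruitment=countries,
            )
        ]
        if rng.random() < cfg.replication_probability:
            samples.append(
                SampleRecord(
                    study_accession=accession,
                    pubmed_id=pubmed,
                    publication_date=date,
                    stage=STAGE_REPLICATION,
                    n_individuals=_draw_size(rng, cfg),
                    detailed_description=description,
                    categories=categories,
                    country_of_recruitment=countries,
                )
            )
        study = StudyRecord(
            study_accession=accession,
            pubmed_id=pubmed,
            publication_date=date,
            trait=trait,
            samples=tuple(samples),
        )
        studies.append(study)

        n_assoc = int(rng.poisson(max(cfg.mean_associations_per_study - 1, 0))) + 1
        for _ in range(n_assoc):
            assoc_serial += 1
            associations.append(
                AssociationRecord(
                    association_id=f"SYNA{assoc_serial:07d}",
                    study_accession=accession,
                    trait=trait,
                )
            )

        # exact bookkeeping, independent of the analysis engine
        gt_studies[label] += 1
        for s in samples:
            gt_individuals[label] += s.n_individuals or 0
        gt_assoc[label] += n_assoc
        if trait:
            slot = per_trait.setdefault(
                trait,
                {
                    "n_studies": 0,
                    "n_associations": 0,
                    "_categories": set(),
                    "_descriptions": set(),
                },
            )
            slot["n_studies"] += 1
            slot["n_associations"] += n_assoc
            slot["_categories"] |= categories - {NOT_REPORTED}
            if description:
                slot["_descriptions"].add(description.casefold())

    per_trait_counts = {
        trait: {
            "n_studies": slot["n_studies"],
            "n_associations": slot["n_associations"],
            "n_categories": len(slot["_categories"]),
            "n_detailed_descriptions": len(slot["_descriptions"]),
        }
        for trait, slot in per_trait.items()
    }
    truth = GroundTruth(
        individuals=dict(gt_individuals),
        studies=dict(gt_studies),
        associations=dict(gt_assoc),
        per_trait=per_trait_counts,
    )
    return studies, associations, truth


def expected_distribution(
    config: SimulationConfig, level: str = "individuals"
) -> dict[str, float]:
    """Closed-form expected label percentages implied by a configuration.

    The generator gives every study the same expected number of samples,
    individuals and associations regardless of its label, so the expected
    shares are level-independent: ``not_reported_fraction`` for "Not
    reported", ``multi_ancestry_fraction`` for "multiple", and the
    remaining mass split by ``category_weights``.
    """
    config.validate()
    if level not in ("individuals", "studies", "associations"):
        raise ValueError(f"unknown level: {level!r}")
    single = 1.0 - config.multi_ancestry_fraction - config.not_reported_fraction
    out: dict[str, float] = {}
    if config.not_reported_fraction > 0:
        out[NOT_REPORTED] = 100.0 * config.not_reported_fraction
    if config.multi_ancestry_fraction > 0:
        out[MULTIPLE] = 100.0 * config.multi_ancestry_fraction
    for name, w in config.category_weights.items():
        if single * w > 0:
            out[name] = 100.0 * single * w
    return out


def write_catalog(
    studies: list[StudyRecord],
    associations: list[AssociationRecord],
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the two TSVs plus the ground-truth JSON sidecar to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ancestry": outdir / "ancestry.tsv",
        "associations": outdir / "associations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    samples = [s for study in studies for s in study.samples]
    write_ancestry_tsv(samples, paths["ancestry"])
    write_associations_tsv(associations, paths["associations"])
    paths["ground_truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths
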