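import datetime as dt

import pytest

from ancestrykit import SampleRecord, StudyRecord
from ancestrykit.lexicon import DEFAULT_MAPPER
from ancestrykit.taxonomy import DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def mapper():
    return DEFAULT_MAPPER


def make_sample(
    accession="GCST000001",
    categories=("European",),
    n=1000,
    description="British",
    stage="initial",
    countries=("United Kingdom",),
    year=2012,
    additional="self-reported",
    confidential=False,
):
    return SampleRecord(
        study_accession=accession,
        pubmed_id="12345678",
        publication_date=dt.date(year, 6, 1),
        stage=stage,
        n_individuals=n,
        detailed_description=description,
        categories=frozenset(categories),
        country_of_recruitment=tuple(countries),
        additional_description=additional,
        confidential=confidential,
    )


def make_study(accession="GCST000001", trait="height", samples=None, year=2012, **kw):
    if samples is None:
        samples = [make_sample(accession=accession, year=year, **kw)]
    s0 = samples[0]
    return StudyRecord(
        study_accession=accession,
        pubmed_id=s0.pubmed_id,
        publication_date=s0.publication_date,
        trait=trait,
        samples=tuple(samples),
    )
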