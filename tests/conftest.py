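"""Shared fixtures: small constructed datasets and the simulated presets."""

from __future__ import annotations

import pytest

from ystrkit import (
    Dataset,
    PopulationSample,
    YFILER_PANEL,
    YHaplotype,
    make_fixture,
)


def midpoint_alleles(panel=YFILER_PANEL, **overrides):
    """Complete allele mapping at panel midpoints, with keyword overrides.

    Overrides use locus names; DYS385 takes a pair, e.g. DYS385=(11, 14).
    """
    alleles = {}
    for loc in panel:
        mid = float(round((loc.allele_min + loc.allele_max) / 2.0))
        alleles[loc.name] = (mid, mid) if loc.copies == 2 else mid
    alleles.update(overrides)
    return alleles


def hap(sample_id: str, pop: str, **overrides) -> YHaplotype:
    return YHaplotype(sample_id, pop, midpoint_alleles(**overrides))


def dataset_from_haps(*pops: list[YHaplotype]) -> Dataset:
    return Dataset(
        YFILER_PANEL,
        [PopulationSample(members[0].population_id, list(members)) for members in pops],
    )


@pytest.fixture(scope="session")
def tiny():
    """3 populations x 10 donors from the 'tiny' simulation preset."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_ds(tiny):
    return tiny[0]


@pytest.fixture(scope="session")
def iran_like():
    """The 16-population, N=1353 'iran-like' preset (default seed)."""
    return make_fixture("iran-like")


@pytest.fixture(scope="session")
def iran_ds(iran_like):
    return iran_like[0]
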