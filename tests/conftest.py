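"""Shared fixtures: generated cohorts and stores (no data files on disk)."""

from __future__ import annotations

import pytest

from aacds.classifier import classify_cohort
from aacds.filters import CohortGenome, partition_known_private
from aacds.fixtures import generate, table2_plan, table4_fixture


@pytest.fixture(scope="session")
def table2_bundle():
    return generate(table2_plan(seed=1))


@pytest.fixture(scope="session")
def table2_store(table2_bundle):
    return table2_bundle.store()


@pytest.fixture(scope="session")
def table2_known_cohort(table2_bundle, table2_store):
    """The 12 genomes restricted to dbSNP-known variants."""
    cohort = []
    for genome in table2_bundle.cohort:
        known, _ = partition_known_private(genome.variants, table2_store)
        cohort.append(
            CohortGenome(genome.subject_id, genome.ethnicity, genome.sex, known)
        )
    return cohort


@pytest.fixture(scope="session")
def table2_results(table2_known_cohort, table2_store):
    return classify_cohort(table2_known_cohort, table2_store)


@pytest.fixture(scope="session")
def table4_bundle():
    return table4_fixture()


@pytest.fixture(scope="session")
def table4_store(table4_bundle):
    return table4_bundle.store()
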