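"""Shared fixtures: a small 5-species universe for unit tests and the full
20-species/18-genus mock fixture for pipeline-level tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import mtxworkbench as wb

settings.register_profile(
    "workbench",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("workbench")


@pytest.fixture(scope="session")
def small_fixture() -> wb.Fixture:
    """5 species in 4 genera (one genus with two species), small genomes."""
    return wb.build_fixture(
        n_species=5,
        n_genera=4,
        seed=7,
        genome_len=4000,
        genes_per_species=4,
        gene_len=600,
        n_contaminant_species=2,
        n_host_seqs=5,
        host_seq_len=2000,
        n_rrna=2,
        rrna_len=1000,
        n_virus=2,
        virus_len=2000,
    )


@pytest.fixture(scope="session")
def mock_fixture() -> wb.Fixture:
    """The standard 20-species/18-genus mock community universe."""
    return wb.build_fixture(seed=1)


@pytest.fixture(scope="session")
def mock_truth(mock_fixture) -> wb.GroundTruth:
    return wb.GroundTruth.from_community(mock_fixture.community)


@pytest.fixture(scope="session")
def read_pools(mock_fixture):
    """Raw microbial and host pools for read-fraction mixtures (shared by the
    heavier pipeline tests)."""
    micro = wb.simulate_sample(
        mock_fixture.ref, mock_fixture.community,
        wb.MixSpec(0.0, 120_000, 101, "cell_ratio"), id_prefix="m",
    )
    host = wb.simulate_sample(
        mock_fixture.ref, mock_fixture.community,
        wb.MixSpec(1.0, 520_000, 102, "cell_ratio"), id_prefix="h",
    )
    return micro, host
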