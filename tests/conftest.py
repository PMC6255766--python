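"""Shared fixtures: the bundled reference annotation and a seeded synthetic genome."""

import pytest

from mitocomp.datasets import nilssonia_nigricans_annotation
from mitocomp.synthetic_data import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def reference_annotation():
    """The published 37-gene softshell-turtle annotation (no sequence)."""
    return nilssonia_nigricans_annotation()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic genome under default study conditions."""
    return generate_genome(GenomeSpec(), seed=11)


@pytest.fixture(scope="session")
def synthetic_record(synthetic_genome):
    return synthetic_genome[0]


@pytest.fixture(scope="session")
def synthetic_truth(synthetic_genome):
    return synthetic_genome[1]
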