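"""Shared fixtures: the packaged feature-table genome and synthetic data.

Everything is generated programmatically at test time from fixed seeds;
no sequence data is stored in the repository.
"""

from __future__ import annotations

import pytest

from mitocomp.io import load_reference_table
from mitocomp.simulate import GenomeSpec, make_genome, make_genome_family


@pytest.fixture(scope="session")
def table1():
    """The packaged parrotfish reference feature table (no sequence)."""
    return load_reference_table()


@pytest.fixture(scope="session")
def synthetic():
    """One deterministic parrotfish-template genome plus its truth record."""
    return make_genome(GenomeSpec(seed=7))


@pytest.fixture(scope="session")
def synthetic_genome(synthetic):
    return synthetic[0]


@pytest.fixture(scope="session")
def truth(synthetic):
    return synthetic[1]


@pytest.fixture(scope="session")
def family():
    """A 6-taxon star-tree study set with a near-saturated control region."""
    return make_genome_family(GenomeSpec(seed=2), n_taxa=6,
                              d_genes=0.01, d_cr=4.0)
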