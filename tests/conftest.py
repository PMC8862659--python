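"""Shared seeded fixtures: one synthetic world reused across test modules."""

import pytest

from lcabin.binner import BinningParams
from lcabin.fixtures import FixtureConfig, generate_bundle
from lcabin.refdb import build_mapping_database


@pytest.fixture(scope="session")
def bundle():
    """Short-read synthetic world: 128 species, 160 genomes, 400 reads."""
    return generate_bundle(FixtureConfig(seed=11, n_reads=400))


@pytest.fixture(scope="session")
def mapping_db(bundle):
    return build_mapping_database(
        bundle.proteins,
        bundle.tables,
        bundle.catalog,
        bundle.taxonomy.ncbi_tree,
        bundle.taxonomy.gtdb_tree,
        seed=11,
    )


@pytest.fixture(scope="session")
def ncbi_tree(bundle):
    return bundle.taxonomy.ncbi_tree


@pytest.fixture(scope="session")
def gtdb_tree(bundle):
    return bundle.taxonomy.gtdb_tree


@pytest.fixture(scope="session")
def long_bundle():
    """Long-read synthetic world (interval-union LCA path)."""
    return generate_bundle(FixtureConfig(seed=13, n_reads=150, long_read=True))


@pytest.fixture(scope="session")
def long_mapping_db(long_bundle):
    return build_mapping_database(
        long_bundle.proteins, long_bundle.tables, long_bundle.catalog, seed=13
    )


@pytest.fixture
def default_params():
    return BinningParams()
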