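"""Shared synthetic worlds for the test suite.

Everything is generated programmatically and seeded; the heavier worlds are
session-scoped so multiple test modules can reuse them.
"""

import numpy as np
import pytest

import kmertyper as kt


@pytest.fixture(scope="session")
def toy_world():
    """Three genes x four alleles, 500 bp, no partials: classifier tests."""
    spec = kt.FixtureSpec(
        n_genes=3,
        alleles_per_gene=4,
        gene_length=500,
        partial_fraction=0.0,
        n_distractome=5,
        distractome_length=500,
        seed=42,
    )
    return kt.generate_database(spec)


@pytest.fixture(scope="session")
def toy_db(toy_world):
    cfg = kt.RunConfig(reference_read_pairs=1200, min_gene_reads=200, seed=42)
    return kt.build_database(toy_world.records, toy_world.distractome, toy_world.class_map, cfg)


@pytest.fixture(scope="session")
def micro_world():
    """Two genes x four alleles, 600 bp: cheap end-to-end pipeline tests."""
    spec = kt.FixtureSpec(
        n_genes=2,
        alleles_per_gene=4,
        gene_length=600,
        partial_fraction=0.0,
        n_distractome=5,
        distractome_length=600,
        seed=7,
    )
    return kt.generate_database(spec)


@pytest.fixture(scope="session")
def micro_db(micro_world):
    cfg = kt.RunConfig(reference_read_pairs=1500, min_gene_reads=300, seed=7)
    return kt.build_database(micro_world.records, micro_world.distractome, micro_world.class_map, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
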