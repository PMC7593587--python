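import logging

import pytest

import gcescan as g


@pytest.fixture(scope="session")
def bact11():
    return g.load_table("bact11")


@pytest.fixture(scope="session")
def pyl_table():
    return g.load_table("pyl_readthrough")


@pytest.fixture(scope="session")
def sec_table():
    return g.load_table("sec_readthrough")


@pytest.fixture(scope="session")
def specs():
    return g.load_reference_set()


@pytest.fixture(scope="session")
def specs_by_key(specs):
    return {s.key: s for s in specs}


@pytest.fixture(scope="session")
def complete_genome():
    """pyl_complete synthetic genome (seed 42) with its manifest."""
    contig, manifest = g.generate_genome({"seed": 42}, preset="pyl_complete")
    return contig, manifest


@pytest.fixture(scope="session")
def complete_inventory(complete_genome):
    contig, _ = complete_genome
    logging.getLogger("gcescan").setLevel(logging.WARNING)
    return g.pipeline.analyze_genome([contig])
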