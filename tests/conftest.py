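import pytest

from delforge.blocks import toy_block_sets
from delforge.chem import Headpiece, TagSchema, enumerate_library
from delforge.codons import CodonDesignConfig, generate_codon_set


@pytest.fixture(scope="session")
def codon_config():
    return CodonDesignConfig(length=12, min_distance=3, n_required=10, seed=0)


@pytest.fixture(scope="session")
def toy_codon_sets(codon_config):
    """Three small distance-3 codon sets (identical config per cycle)."""
    return [generate_codon_set(codon_config, cycle_id=c) for c in (1, 2, 3)]


@pytest.fixture(scope="session")
def toy_blocks():
    """5 + 2 / 5 + 2 / 4 + 2 wells — the 294-member demonstration design."""
    return toy_block_sets(5, 5, 4, controls=True)


@pytest.fixture(scope="session")
def tag_schema():
    return TagSchema(headpiece_sequence=Headpiece().dna_sequence, codon_length=12)


@pytest.fixture(scope="session")
def toy_library(toy_blocks, toy_codon_sets, tag_schema):
    """Fully enumerated 294-member toy library with structures."""
    return list(
        enumerate_library(toy_blocks, toy_codon_sets, Headpiece(), tag_schema)
    )


@pytest.fixture(scope="session")
def full_codon_set():
    """A complete 200-codon set at the default design parameters."""
    return generate_codon_set(CodonDesignConfig(), cycle_id=1)
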