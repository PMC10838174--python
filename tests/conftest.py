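import pytest

from mitocomp.simulate import (CHESPERIDUM_GENE_TABLE, chesperidum_features,
                               chesperidum_like_spec, generate_mitogenome)


@pytest.fixture(scope="session")
def published_table():
    """The C. hesperidum gene table: (name, start, end, strand, anticodon,
    start codon, stop token) per gene."""
    return CHESPERIDUM_GENE_TABLE


@pytest.fixture(scope="session")
def published_features():
    return chesperidum_features()


@pytest.fixture(scope="session")
def synthetic_genome():
    """A synthetic genome replicating the published gene order/sizes/gaps."""
    genome, truth = generate_mitogenome(chesperidum_like_spec(seed=1))
    return genome, truth
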