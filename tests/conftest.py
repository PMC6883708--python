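import pytest

from sltop.io_formats import GeneModel, GeneModelSet, GenomeSequence


@pytest.fixture
def toy_genome() -> GenomeSequence:
    #            0         1         2
    #            0123456789012345678901234567
    seq_plus = "GGAGTACGTACGTACGTACGTACGTGGG"
    return GenomeSequence({"chr1": seq_plus})


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("gA", "chr1", "+", 10, 20, 10)


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("gB", "chr1", "-", 5, 15, 14)


@pytest.fixture
def toy_models(plus_gene, minus_gene) -> GeneModelSet:
    return GeneModelSet([plus_gene, minus_gene])
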