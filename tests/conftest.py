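import pytest

from mitocomp.simulate import GenomeTemplate, generate_genome


@pytest.fixture(scope="session")
def default_genome():
    """The default synthetic moth-like mitogenome (fixed seed)."""
    return generate_genome(GenomeTemplate.default(), seed=1)


@pytest.fixture(scope="session")
def ancestral_genome():
    """Same layout but with the ancestral insect trnI-trnQ-trnM block."""
    return generate_genome(GenomeTemplate.default(rearranged=False), seed=1)
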