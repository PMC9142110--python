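import pytest

from mitoprofile import io as mio
from mitoprofile.model import genetic_code
from mitoprofile.synthetic import GenomeConfig, generate_mitogenome


@pytest.fixture(scope="session")
def ref_table():
    """Transcribed published M. flexura annotation (37 genes + CR)."""
    return mio.load_reference_features()


@pytest.fixture(scope="session")
def ref_printed():
    return mio.load_reference_printed()


@pytest.fixture(scope="session")
def code5():
    return genetic_code(5)


@pytest.fixture(scope="session")
def synthetic_genome():
    """One generated genome shared across read-only tests (seed 0)."""
    return generate_mitogenome(GenomeConfig(seed=0))
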